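region_code,population
AL,4849377
AK,736732
AZ,6731484
AR,2966369
CA,38802500
CO,5355866
CT,3596677
DE,935614
DC,658893
FL,19893297
GA,10097343
HI,1419561
ID,1634464
IL,12880580
IN,6596855
IA,3107126
KS,2904021
KY,4413457
LA,4649676
ME,1330089
MD,5976407
MA,6745408
MI,9909877
MN,5457173
MS,2994079
MO,6063589
MT,1023579
NE,1881503
NV,2839099
NH,1326813
NJ,8938175
NM,2085572
NY,19746227
NC,9943964
ND,739482
OH,11594163
OK,3878051
OR,3970239
PA,12787209
RI,1055173
SC,4832482
SD,853175
TN,6549352
TX,26956958
UT,2942902
VT,626562
VA,8326289
WA,7061530
WV,1850326
WI,5757564
WY,584153
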