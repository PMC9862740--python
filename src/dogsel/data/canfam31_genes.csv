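symbol,chrom,start,end
SSBP2,3,25616824,25900501
ACTN2,4,3348449,3415273
NID1,4,3935223,4017300
TSNAX,4,7937820,7967889
CSF1R,4,58980788,59010510
ARHGEF12,5,13522896,13669155
DYNC2H1,5,28388664,28727334
NFIA,5,48496773,49064848
RGL1,7,17041296,17235193
BAZ1A,8,13605182,13693847
HELB,10,8765617,8798092
MRPS18A,12,12096568,12122997
GABRB1,13,42992569,43349923
CORIN,13,43502665,43737813
EXOC4,14,3334220,4077411
SND1,14,8265358,8731453
CSMD2,15,8090518,8110447
AGBL4,15,11914056,12427654
DYSF,17,51011197,51228876
RELN,18,16275837,16773875
DLG2,21,13822304,15771954
KIZ,24,2174905,2305811
EPB41L1,24,24925629,25046776
XPO4,25,17230031,17348031
INTS13,27,20479932,20507538
MAP2K5,30,31664564,31920751
PEAK1,30,39134948,39207226
CCSER1,32,13355503,14697519
HGD,33,24066306,24151354
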