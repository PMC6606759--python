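name,reported_as,terminal,n,disulfides,metal1,metal2,adduct,expected_mz
(S-S)PyC2-Gly,(S-S)PyC2-Gly,Gly,2,1,,,M+H,538.1272
PyC2-Gly,PyC2-Gly,Gly,2,0,,,M+H,540.1429
PyC3-Gly,PyC3-Gly,Gly,3,0,,,M+H,772.1946
PyC4-Gly,PyC4-Gly,Gly,4,0,,,M+H,1004.2464
PyC5-Gly,PyC5-Gly,Gly,5,0,,,M+H,1236.2982
PyC6-Gly,PyC6-Gly,Gly,6,0,,,M+H,1468.35
PyC2-Ser,PyC2-Ser,Ser,2,0,,,M+H,570.1534
PyC3-Ser,PyC3-Ser,Ser,3,0,,,M+H,802.2052
PyC4-Ser,PyC4-Ser,Ser,4,0,,,M+H,1034.257
PyC2-Gln,PyC2-Gln,Gln,2,0,,,M+H,611.18
PyC3-Gln,PyC3-Gln,Gln,3,0,,,M+H,843.2318
PyC2-Glu,PyC2-Glu,Glu,2,0,,,M+H,612.164
PyC3-Glu,PyC3-Glu,Glu,3,0,,,M+H,844.2158
PyC4-Glu,PyC4-Glu,Glu,4,0,,,M+H,1076.2675
PyC2-Gly-Hg,PyC2-Gly-Hg,Gly,2,0,Hg,,M+H,740.0979
PyC3-Gly-Hg,PyC3-Gly-Hg,Gly,3,0,Hg,,M+H,972.1496
(S-S)PyC4-Gly-Hg,PyC4-Gly-Hg,Gly,4,1,Hg,,M+H,1202.1858
PyC4-Gly-Hg(2),PyC4-Gly-Hg(2),Gly,4,0,Hg,Hg,M+H,1404.1564
PyC2-Gly-Cd,PyC2-Gly-Cd,Gly,2,0,Cd,,M+H,652.0306
PyC3-Gly-Cd,PyC3-Gly-Cd,Gly,3,0,Cd,,M+H,884.0824
PyC4-Gly-Cd,PyC4-Gly-Cd,Gly,4,0,Cd,,M+H,1116.1341
PyC4-Gly-Cd(2),PyC4-Gly-Cd(2),Gly,4,0,Cd,Cd,M+H,1228.0218
PyC5-Gly-Cd,PyC5-Gly-Cd,Gly,5,0,Cd,,M+H,1348.1859
PyC2-Gly-Pb,PyC2-Pb,Gly,2,0,Pb,,M+H,746.1039
PyC3-Gly-Pb,PyC3-Pb,Gly,3,0,Pb,,M+H,978.1556
PyC4-Gly-Pb,PyC4-Pb,Gly,4,0,Pb,,M+H,1210.2074
PyC4-Gly-Pb(2),PyC4-Pb(2),Gly,4,0,Pb,Pb,M+H,1416.1684
PyC2-Gly-Zn,PyC2-Zn,Gly,2,0,Zn,,M+H,602.0564
PyC3-Gly-Zn,PyC3-Zn,Gly,3,0,Zn,,M+H,834.1081
PyC4-Gly-Zn,PyC4-Zn,Gly,4,0,Zn,,M+H,1066.1599
PyC4-Gly-Zn(2),PyC4-Zn(2),Gly,4,0,Zn,Zn,M+H,1128.0734
PyC2-Gly-Mn,PyC2-Mn,Gly,2,0,Mn,,M+H,593.0653
PyC3-Gly-Mn,PyC3-Mn,Gly,3,0,Mn,,M+H,825.1170
PyC4-Gly-Mn,PyC4-Mn,Gly,4,0,Mn,,M+H,1057.1688
PyC4-Gly-Mn(2),PyC4-Mn(2),Gly,4,0,Mn,Mn,M+H,1110.0912
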