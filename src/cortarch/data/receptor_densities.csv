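area,AMPA,AMPA_sd,kainate,kainate_sd,NMDA,NMDA_sd,GABAA,GABAA_sd,GABAB,GABAB_sd,BZ,BZ_sd,M1,M1_sd,M2,M2_sd,M3,M3_sd,alpha1,alpha1_sd,alpha2,alpha2_sd,5-HT1A,5-HT1A_sd,5-HT2,5-HT2_sd,D1,D1_sd
10d,591,161,858,116,1430,260,1697,162,1970,542,2151,829,995,230,141,35,880,117,507,75,337,68,623,169,340,75,93,20
10md,586,106,895,90,1470,177,1651,168,2095,495,2307,783,1012,274,154,45,856,112,494,48,327,48,628,151,357,60,90,20
10mv,628,130,903,66,1612,151,1680,199,2254,606,2451,839,1063,332,145,35,894,124,471,94,334,56,666,214,320,67,86,18
10o,569,76,909,50,1523,190,1723,160,2336,612,2327,774,1068,313,150,45,923,105,470,76,342,76,682,233,350,59,82,12
14r,470,81,818,107,1442,255,1427,162,2482,424,1715,542,921,385,134,35,833,118,497,109,297,95,583,119,323,44,86,15
11m,604,100,771,65,1585,139,1762,142,2476,466,1975,218,1094,200,159,64,965,132,473,50,342,40,549,167,357,60,92,27
11l,623,111,807,123,1562,113,1876,235,2644,478,2066,247,1050,228,159,54,944,101,462,46,351,45,529,116,357,51,96,29
13b,489,44,820,103,1548,223,1615,120,2311,452,1901,431,1039,263,166,57,897,104,480,73,350,75,562,206,355,57,93,22
13m,753,67,856,111,1499,122,1622,126,1908,429,1864,269,1059,121,206,94,918,130,485,21,417,21,527,138,357,50,78,11
13l,713,95,756,60,1498,187,1683,180,2057,240,2052,303,1054,148,223,78,826,108,461,15,404,26,460,107,351,43,70,4
12r,659,122,854,120,1406,121,1843,283,2412,312,1991,307,1026,301,180,72,922,96,439,38,306,52,540,88,350,51,86,9
12m,598,136,799,55,1533,175,1792,246,2222,353,1873,421,1152,262,202,74,918,108,481,48,379,71,504,103,354,45,86,22
12l,630,112,840,73,1400,126,1494,221,2010,483,1789,417,824,347,182,75,780,132,491,82,320,43,531,163,351,48,71,6
12o,670,165,817,97,1527,158,1579,267,2142,414,2102,436,888,174,209,64,832,149,484,32,401,66,541,87,384,61,89,20
9m,607,125,818,84,1224,252,1460,352,2048,235,1864,449,868,196,168,33,760,79,508,50,307,49,629,136,359,55,89,22
9d,584,154,766,72,1341,206,1633,338,2312,235,2081,478,1050,177,176,34,841,80,515,40,355,59,642,81,362,61,92,24
9l,554,151,711,56,1311,230,1582,324,2173,260,1972,464,1029,143,164,31,822,91,497,38,361,47,594,64,366,54,67,21
a46d,527,138,810,81,1247,197,1609,253,1993,189,1821,349,981,234,187,40,819,114,462,68,318,65,521,86,354,66,90,26
a46df,559,126,667,44,1348,124,1663,219,2071,170,1898,444,1083,160,176,45,860,79,478,60,384,61,466,94,355,80,94,29
a46vf,619,126,679,81,1427,102,1752,297,2291,280,1873,352,1124,161,180,47,894,94,484,47,395,39,497,88,376,76,93,30
a46v,502,67,808,61,1339,167,1614,281,2068,200,1908,406,1017,235,187,52,856,85,440,52,319,35,496,79,349,58,87,17
p46d,563,103,785,50,1187,318,1449,259,1934,231,1786,286,889,257,185,48,771,84,439,70,300,30,484,77,364,35,81,29
p46df,592,102,692,40,1305,254,1649,268,2049,177,1978,256,1000,241,176,43,812,84,453,78,388,47,478,86,373,42,85,22
p46vf,613,115,671,71,1369,225,1726,315,2295,315,2138,383,998,230,163,41,834,115,467,74,395,67,528,107,381,48,88,24
p46v,519,49,758,67,1241,207,1444,279,1956,213,1814,284,810,294,170,34,783,74,416,88,321,43,461,98,361,43,81,23
8Bm,528,136,731,128,1018,438,1216,217,1888,267,1958,236,806,173,178,31,667,87,472,70,273,49,508,80,351,32,83,27
8Bd,481,92,641,106,973,346,1195,151,1896,173,2136,385,832,131,195,41,680,92,466,73,263,70,437,89,362,47,89,28
8Bs,494,99,570,54,1047,348,1232,209,1901,389,1931,134,831,117,164,47,682,117,436,75,304,67,484,106,356,56,88,23
8Ad,528,115,694,65,1108,322,1219,200,1972,143,1795,301,870,227,158,37,685,139,438,67,272,36,450,82,359,43,82,29
8Av,440,94,591,102,1017,264,1205,202,1703,264,1807,369,708,268,163,36,603,174,347,112,257,64,262,109,323,67,79,25
45A,550,97,733,61,1235,165,1461,186,1846,280,1810,378,880,244,168,52,734,62,422,106,321,47,394,126,358,47,75,19
45B,601,150,588,54,1310,271,1472,286,1955,301,1911,249,972,317,147,29,705,120,442,65,372,75,499,166,378,58,88,30
44,595,162,592,86,1310,277,1520,220,2065,233,1756,294,957,339,154,22,697,164,475,79,402,70,638,253,385,57,93,27
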