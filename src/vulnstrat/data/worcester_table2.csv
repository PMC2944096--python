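stratum,name,town_no,scale,population,stratum_pop,h_s,a_s,h_class,a_class,mos,stratum_mos,n_block_groups,min_bg_pop,max_bg_pop,mean_bg_h_s,sd_bg_h_s,mean_bg_a_s,sd_bg_a_s
1,Athol,1,town,11299,,0.936,6.46,4,4,531,,8,1039,2092,0.150,0.155,7.40,0.364
1,Gardner,2,town,20770,,2.265,4.63,5,2,917,,12,706,2512,0.330,0.375,7.04,0.340
1,Royalston,3,town,1254,,0.005,7.11,2,5,41,,1,1254,1254,0.005,0.000,7.11,0.000
1,Winchendon,5,town,9611,42934,2.007,4.24,5,2,479,1969,7,643,2230,0.250,0.264,7.39,0.341
2,Barre,16,town,5113,,0.730,5.55,4,3,232,,4,804,1595,0.090,0.113,7.50,0.239
2,E. Brookfield,22,town,2097,,0.543,6.33,4,4,80,,2,687,1410,0.080,0.092,7.76,0.127
2,Holden,17,town,15621,,0.868,6.21,4,4,670,,13,667,1978,0.140,0.090,7.25,0.279
2,N. Brookfield,24,town,4683,,0.965,5.39,4,3,176,,5,661,1380,0.140,0.126,7.40,0.224
2,Oakham,10,town,1673,,0.030,7.49,2,5,77,,1,1673,1673,0.030,0.000,7.49,0.000
2,Rutland,19,town,6353,,0.271,6.26,3,4,339,,3,1329,2819,0.040,0.036,7.43,0.422
2,Spencer,25,town,11691,,1.338,6.15,4,4,513,,10,637,1870,0.200,0.226,7.37,0.490
2,W. Boylston,20,town,7481,54712,1.210,5.72,4,3,224,2310,8,547,2509,0.170,0.162,7.34,0.342
3,Charlton,28,town,11263,,0.659,6.68,4,4,591,,6,527,2925,0.080,0.083,7.56,0.166
3,Leicester,23,town,10471,,0.470,6.57,3,4,429,,8,914,2410,0.070,0.043,7.43,0.344
3,Oxford,29,town,13352,,1.123,7.48,4,5,580,,9,565,2882,0.150,0.108,7.68,0.349
3,Paxton,18,town,4386,,0.499,6.30,3,4,148,,4,614,1492,0.070,0.062,7.16,0.274
3,Sturbridge,30,town,7837,47309,0.550,7.76,4,5,353,2101,6,1054,1702,0.070,0.046,7.30,0.311
4,Auburn,43,town,15901,,2.238,6.29,5,4,612,,20,500,1379,0.300,0.207,7.56,0.259
4,Douglas,34,town,7045,,0.240,6.81,3,4,494,,4,798,2319,0.040,0.043,7.62,0.215
4,Millbury,44,town,12784,,1.884,5.53,5,3,539,,13,573,1523,0.240,0.186,7.66,0.340
4,Sutton,35,town,8250,43980,0.315,6.27,3,4,391,2036,6,624,3090,0.040,0.036,7.40,0.224
5,Blackstone,37,town,8804,,1.335,5.82,4,3,418,,6,749,3372,0.240,0.207,7.39,0.363
5,Mendon,38,town,5286,,0.347,6.84,3,4,224,,3,1044,2640,0.050,0.021,7.58,0.106
5,Millville,39,town,2724,,0.590,6.57,4,4,177,,3,607,1187,0.100,0.067,7.53,0.201
5,Northbridge,46,town,13182,,0.717,5.72,4,3,757,,9,465,2934,0.110,0.092,7.42,0.112
5,Uxbridge,36,town,11156,41152,0.682,6.02,4,3,625,2202,7,654,2610,0.090,0.065,7.54,0.328
6,Dudley,31,town,10036,,0.957,5.85,4,3,465,,7,877,2043,0.140,0.171,7.38,0.194
6,Southbridge,32,town,17214,,3.581,4.98,5,2,971,,17,556,1833,0.530,0.595,6.43,0.829
6,Webster,33,town,16415,43665,5.602,2.42,5,1,840,2275,13,525,2754,0.680,0.907,7.06,0.403
7,Hopedale,41,town,5907,,1.967,4.78,5,2,304,,3,1524,2709,0.240,0.174,7.60,0.137
7,Milford,42,town,26799,,4.183,4.27,5,2,1450,,19,663,2863,0.610,0.482,6.89,0.428
7,Upton,40,town,5642,38348,0.312,6.68,3,4,330,2084,4,644,1812,0.060,0.042,7.55,0.183
8,Grafton,45,town,14894,,1.062,5.97,4,3,909,,10,324,4332,0.140,0.113,6.76,1.951
8,Southborough,48,town,8781,,1.091,6.44,4,4,415,,6,796,2742,0.140,0.079,7.32,0.257
8,Westborough,49,town,17997,41672,2.162,5.74,5,3,834,2158,12,616,3100,0.280,0.247,6.70,0.667
9,Worcester,51,city_block_group,,29690,,,4,3,2075,2075,29,488,2367,1.599,0.869,5.98,0.954
10,Worcester,51,city_block_group,,32800,,,5,2,2155,2155,36,415,1743,1.970,0.982,4.84,1.144
11,Worcester,51,city_block_group,,37984,,,3,4,2041,2041,30,424,3305,0.526,0.355,6.78,0.618
12,Worcester,51,city_block_group,,35627,,,4,3,2096,2096,40,514,2123,1.652,1.311,5.69,1.145
13,Worcester,51,city_block_group,,36547,,,4,4,2018,2018,32,428,3538,0.592,0.311,6.63,0.919
14,Northborough,47,town,14013,,1.384,6.58,4,4,607,,9,787,2766,0.190,0.124,7.25,0.259
14,Shrewsbury,50,town,31640,45653,2.349,6.57,5,4,1698,2305,19,543,3150,0.330,0.238,6.90,0.588
15,Berlin,52,town,2380,,0.353,6.80,3,4,91,,3,394,1294,0.040,0.017,7.63,0.236
15,Bolton,53,town,4148,,0.260,5.76,3,3,245,,2,1831,2317,0.040,0.007,7.33,0.156
15,Boylston,54,town,4008,,0.423,7.20,3,5,175,,4,603,1787,0.070,0.066,7.34,0.220
15,Clinton,55,town,13435,,3.659,3.93,5,2,739,,9,856,3904,0.540,0.393,6.89,0.633
15,Harvard,56,town,5981,,0.264,5.91,3,3,156,,6,734,1202,0.040,0.019,6.89,0.748
15,Lancaster,57,town,7380,,0.577,6.81,4,4,251,,4,720,2966,0.080,0.064,7.06,0.245
15,Lunenburg,58,town,9401,46733,0.373,6.18,3,4,353,2010,6,1109,2208,0.060,0.033,7.26,0.260
16,Leominster,59,town,41303,41303,3.115,4.53,5,2,2037,2037,25,608,3330,0.470,0.297,6.74,0.791
17,Fitchburg,60,town,39102,39102,5.021,2.54,5,1,2181,2181,34,104,2207,0.720,0.732,6.40,0.849
18,Ashburnham,6,town,5546,,0.159,6.11,3,4,254,,5,788,1843,0.030,0.021,7.53,0.240
18,Brookfield,21,town,3051,,0.234,5.86,3,3,125,,3,929,1162,0.030,0.027,7.79,0.162
18,Hardwick,7,town,2622,,0.385,6.59,3,4,100,,2,900,1722,0.050,0.064,7.50,0.297
18,Hubbardston,8,town,3909,,0.060,7.00,2,5,198,,2,1310,2599,0.010,0.000,7.61,0.021
18,New Braintree,9,town,927,,0.015,7.94,2,4,39,,1,927,927,0.015,0.000,7.94,0.000
18,Petersham,11,town,1180,,0.000,7.02,1,5,37,,1,1180,1180,0.000,0.000,7.02,0.000
18,Phillipston,12,town,1621,,0.035,7.71,2,4,62,,1,1621,1621,0.035,0.000,7.71,0.000
18,Princeton,13,town,3353,,0.055,6.17,2,4,102,,2,1371,1982,0.010,0.007,7.21,0.120
18,Sterling,14,town,7257,,0.182,6.96,3,5,319,,3,1420,3092,0.030,0.010,7.41,0.189
18,Templeton,4,town,6799,,0.297,5.30,3,3,255,,6,502,1930,0.040,0.025,7.51,0.123
18,Warren,26,town,4776,,0.257,5.32,3,3,96,,4,1025,1450,0.040,0.013,7.50,0.090
18,W. Brookfield,27,town,3804,,0.346,6.80,3,4,138,,3,1114,1567,0.050,0.045,7.48,0.323
18,Westminster,15,town,6907,51752,0.245,6.93,3,5,263,1988,5,741,1789,0.030,0.016,7.33,0.251
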