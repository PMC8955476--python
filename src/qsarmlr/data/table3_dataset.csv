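compound_id,AATS7s,MATS2c,SpMin3_Bhi,MDEC-33,observed_pIC50,predicted_pIC50,residual
1,3.373101,0.041687,1.704602,10.0791391,5.59,5.564453,0.025547
2,3.351496,0.048774,1.70672,10.0791391,5.476,5.522631,-0.04663
3,3.348425,0.062204,1.709487,10.0791391,5.402,5.450572,-0.04857
4,3.357474,0.075511,1.729188,10.0791391,5.287,5.237408,0.049592
5,4.110095,0.03852,1.723253,10.0791391,5.372,5.360054,0.011946
6,2.850694,0.09839,1.701321,7.7983348,4.867,4.870679,-0.00368
7,3.455229,0.044554,1.698517,9.42319018,5.476,5.437684,0.038316
8,2.985512,0.06304,1.705109,9.42319018,5.374,5.354074,0.019926
9,2.965686,0.070285,1.707205,9.42319018,5.27,5.311702,-0.0417
10,2.962868,0.083909,1.709945,9.42319018,5.242,5.23913,0.00287
11,2.996642,0.097217,1.729488,9.42319018,5.005,5.025225,-0.02022
12,3.68196,0.059358,1.723591,9.42319018,5.193,5.156333,0.036667
13,2.867544,0.104709,1.695475,7.32266243,4.779,4.778616,0.000384
14,3.304386,0.043052,1.698914,8.86256391,5.288,5.315756,-0.02776
15,2.884113,0.061294,1.705445,8.86256391,5.222,5.229445,-0.00745
16,2.866374,0.068444,1.707524,8.86256391,5.162,5.187387,-0.02539
17,2.863853,0.081897,1.710244,8.86256391,5.11,5.115595,-0.0056
18,2.900165,0.095095,1.729668,8.86256391,4.946,4.90286,0.04314
19,3.51431,0.057675,1.723799,8.86256391,5.01,5.038041,-0.02804
20,2.794935,0.100075,1.695788,6.91156492,4.709,4.698848,0.010152
21,3.201797,0.03936,1.699197,8.37672004,5.218,5.217054,0.000946
22,2.810367,0.057278,1.705677,8.37672004,5.173,5.12996,0.04304
23,2.793845,0.06431,1.707742,8.37672004,5.137,5.088354,0.048646
24,2.791497,0.077555,1.710444,8.37672004,5.03,5.017453,0.012547
25,2.829475,0.09062,1.729779,8.37672004,4.831,4.80581,0.02519
26,3.40173,0.053783,1.72393,8.37672004,4.912,4.942162,-0.03016
27,3.373101,0.041687,1.704602,10.0791391,5.59,5.564453,0.025547
28,3.351496,0.048774,1.70672,10.0791391,5.476,5.522631,-0.04663
29,3.348425,0.062204,1.709487,10.0791391,5.402,5.450572,-0.04857
30,3.357474,0.075511,1.729188,10.0791391,5.287,5.237408,0.049592
31,4.110095,0.03852,1.723253,10.0791391,5.372,5.360054,0.011946
32,2.850694,0.09839,1.701321,7.7983348,4.867,4.870679,-0.00368
33,3.455229,0.044554,1.698517,9.42319018,5.476,5.437684,0.038316
34,2.985512,0.06304,1.705109,9.42319018,5.374,5.354074,0.019926
35,2.965686,0.070285,1.707205,9.42319018,5.27,5.311702,-0.0417
36,2.962868,0.083909,1.709945,9.42319018,5.242,5.23913,0.00287
37,2.996642,0.097217,1.729488,9.42319018,5.005,5.025225,-0.02022
38,3.68196,0.059358,1.723591,9.42319018,5.193,5.156333,0.036667
39,2.867544,0.104709,1.695475,7.32266243,4.779,4.778616,0.000384
40,3.304386,0.043052,1.698914,8.86256391,5.288,5.315756,-0.02776
41,2.884113,0.061294,1.705445,8.86256391,5.222,5.229445,-0.00745
42,2.866374,0.068444,1.707524,8.86256391,5.162,5.187387,-0.02539
43,2.863853,0.081897,1.710244,8.86256391,5.11,5.115595,-0.0056
44,2.900165,0.095095,1.729668,8.86256391,4.946,4.90286,0.04314
45,3.51431,0.057675,1.723799,8.86256391,5.01,5.038041,-0.02804
46,2.794935,0.100075,1.695788,6.91156492,4.709,4.698848,0.010152
47,3.201797,0.03936,1.699197,8.37672004,5.218,5.217054,0.000946
48,2.810367,0.057278,1.705677,8.37672004,5.173,5.12996,0.04304
49,2.793845,0.06431,1.707742,8.37672004,5.137,5.088354,0.048646
50,2.791497,0.077555,1.710444,8.37672004,5.03,5.017453,0.012547
51,2.829475,0.09062,1.729779,8.37672004,4.831,4.80581,0.02519
52,3.40173,0.053783,1.72393,8.37672004,4.912,4.942162,-0.03016
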