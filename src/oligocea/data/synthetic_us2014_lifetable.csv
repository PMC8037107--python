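age,qx
0,6.1e-05
1,6.6e-05
2,7.2e-05
3,7.8e-05
4,8.5e-05
5,9.3e-05
6,0.000101
7,0.00011
8,0.00012
9,0.00013
10,0.000142
11,0.000154
12,0.000168
13,0.000183
14,0.000199
15,0.000217
16,0.000236
17,0.000257
18,0.00028
19,0.000305
20,0.000332
21,0.000361
22,0.000393
23,0.000428
24,0.000466
25,0.000508
26,0.000553
27,0.000602
28,0.000655
29,0.000713
30,0.000776
31,0.000845
32,0.00092
33,0.001002
34,0.001091
35,0.001187
36,0.001293
37,0.001407
38,0.001532
39,0.001668
40,0.001816
41,0.001977
42,0.002152
43,0.002342
44,0.00255
45,0.002776
46,0.003022
47,0.003289
48,0.003581
49,0.003898
50,0.004243
51,0.004618
52,0.005027
53,0.005472
54,0.005956
55,0.006483
56,0.007056
57,0.007679
58,0.008358
59,0.009096
60,0.009899
61,0.010772
62,0.011722
63,0.012755
64,0.013879
65,0.015101
66,0.01643
67,0.017874
68,0.019444
69,0.021151
70,0.023006
71,0.025021
72,0.02721
73,0.029588
74,0.032171
75,0.034974
76,0.038018
77,0.04132
78,0.044902
79,0.048787
80,0.052998
81,0.057562
82,0.062506
83,0.067859
84,0.073652
85,0.079918
86,0.086692
87,0.094011
88,0.101911
89,0.110435
90,0.119622
91,0.129517
92,0.140163
93,0.151606
94,0.163891
95,0.177063
96,0.191169
97,0.206251
98,0.222351
99,0.239509
100,0.257759
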