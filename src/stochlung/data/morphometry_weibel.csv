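generation,mean_length_cm,mean_diameter_cm,cv_length,cv_diameter
0,12.000,1.800,0.3,0.3
1,4.760,1.220,0.3,0.3
2,1.900,0.830,0.3,0.3
3,0.760,0.560,0.3,0.3
4,1.270,0.450,0.3,0.3
5,1.070,0.350,0.3,0.3
6,0.900,0.280,0.3,0.3
7,0.760,0.230,0.3,0.3
8,0.640,0.186,0.3,0.3
9,0.540,0.154,0.3,0.3
10,0.460,0.130,0.3,0.3
11,0.390,0.109,0.3,0.3
12,0.330,0.095,0.3,0.3
13,0.270,0.082,0.3,0.3
14,0.230,0.074,0.3,0.3
15,0.200,0.066,0.3,0.3
16,0.165,0.060,0.3,0.3
17,0.141,0.054,0.3,0.3
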