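sample_id,spectro_absorbance,spectro_ppb,uiis_index,plate_ppb,error_fraction
1,0.0005,20.643,86.213,232.875,10.281
2,0.0430,187.412,89.779,174.740,0.068
3,0.0716,299.569,83.092,283.752,0.053
4,0.1420,575.647,65.795,565.741,0.017
5,0.0001,19.176,,,
6,0.0251,117.255,93.702,110.785,0.055
7,0.1101,450.549,73.373,442.200,0.019
8,0.0448,194.471,88.976,187.831,0.034
9,0.0770,320.745,81.041,317.192,0.011
10,0.1160,473.686,71.234,477.072,0.007
11,0.0100,58.000,97.994,40.815,0.296
12,0.0260,120.745,93.523,113.703,0.058
13,0.0002,19.569,,,
14,0.0200,97.216,94.593,96.260,0.010
15,0.1130,461.922,72.660,453.824,0.018
16,0.0160,81.529,,,
17,0.0603,255.255,84.607,259.057,0.015
18,0.1010,414.863,75.959,400.042,0.036
19,0.0003,19.961,,,
20,0.0011,23.098,,,
21,0.1060,434.471,73.908,433.478,0.002
22,0.1400,567.804,66.686,551.216,0.029
23,0.1470,595.255,64.623,584.848,0.017
24,0.0308,139.569,75.200,412.416,1.955
25,0.0520,222.706,86.218,232.794,0.045
26,0.0280,128.588,93.345,116.605,0.093
27,0.0148,76.824,96.109,71.545,0.069
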