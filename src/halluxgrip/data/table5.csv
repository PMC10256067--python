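size_mm,time_ratio
100,1
99.8,0.95
97.31,0.93
94.74,0.91
94.01,0.9
88.71,0.85
83.62,0.8
80.19,0.78
77.49,0.75
74.63,0.73
70,0.7
65,0.65
60,0.6
53.68,0.55
45.8,0.5
40.74,0.45
33.14,0.4
30.36,0.37
25.14,0.33
18.59,0.3
11.54,0.27
5.46,0.26
0,0.25
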