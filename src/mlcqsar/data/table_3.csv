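compound_id,log_km_over_kam,log_bb,log_bb_star,tpsa,hbd,hba,nrb,mw,alpha,parachor_P
1,−0.957,0.117,0.21,48.27,0,5,2,242.28,27.55,497.81
2,−0.834,0.305,0.32,48.27,0,5,2,256.30,29.30,528.90
3,−0.950,0.226,0.26,48.27,0,5,2,276.72,29.37,526.66
4,−0.789,0.270,0.30,48.27,0,5,2,276.72,29.37,526.66
5,−0.780,0.209,0.24,48.27,0,5,2,276.72,29.37,526.66
6,−0.674,0.360,0.34,48.27,0,5,2,311.17,31.20,555.51
7,−1.099,−0.243,−0.16,74.57,0,7,4,286.29,30.27,561.26
8,−0.968,−0.051,−0.04,74.57,0,7,4,300.31,32.02,592.35
9,−1.140,−0.293,−0.28,83.80,0,8,5,316.31,32.57,611.52
10,−1.012,−0.167,−0.20,83.80,0,8,6,330.34,34.40,650.13
11,−0.920,−0.151,−0.12,74.57,0,7,4,320.73,32.09,590.11
12,−0.949,−0.132,−0.10,74.57,0,7,5,300.31,32.09,604.35
13,−0.819,0.055,0.02,74.57,0,7,5,314.38,33.85,635.45
14,−0.876,−0.167,−0.20,83.80,0,8,6,330.34,34.40,599.87
15,−0.771,0.029,0.00,74.57,0,7,5,334.76,33.92,630.96
16,−0.766,−0.033,−0.05,74.57,0,7,5,334.76,33.92,650.13
17,−0.660,0.117,0.05,74.57,0,7,5,369.20,35.74,628.72
18,−0.850,0.038,0.06,61.41,0,6,2,280.31,30.82,628.72
19,−0.845,0.225,0.17,61.41,0,6,2,294.34,33.57,657.57
20,−0.684,0.225,0.17,61.41,0,6,2,294.34,32.57,578.01
21,−0.833,0.417,0.29,61.41,0,6,2,308.37,34.33,609.11
22,−0.722,0.006,−0.04,70.64,0,7,3,310.34,33.12,597.18
23,−0.755,0.003,−0.05,70.64,0,7,3,310.34,33.12,597.18
24,−1.113,0.141,0.11,61.41,0,6,2,314.75,32.64,575.77
25,−0.899,0.194,0.16,61.41,0,6,2,314.75,32.64,575.77
26,−0.687,0.130,0.09,61.41,0,6,2,314.75,32.64,575.77
27,−0.860,0.281,0.19,61.41,0,6,2,349.20,34.47,604.62
28,−0.725,0.297,0.21,61.41,0,6,2,349.20,34.47,604.62
29,−0.650,0.227,0.15,48.27,0,5,2,290.32,33.92,604.97
30,−0.772,0.407,0.26,48.27,0,5,2,304.35,35.68,636.07
31,−0.541,0.407,0.26,48.27,0,5,2,304.35,35.68,636.07
32,−0.521,0.407,0.26,48.27,0,5,2,304.35,35.68,636.07
33,−0.743,0.188,0.05,57.50,0,6,3,320.35,36.23,655.23
34,−0.583,0.172,0.04,57.50,0,6,3,320.35,36.23,655.23
35,−0.566,0.298,0.11,57.50,0,6,4,334.41,38.05,693.84
36,−0.699,0.594,0.38,48.27,0,5,2,318.37,37.43,667.16
37,−0.693,0.331,0.20,48.27,0,5,2,324.76,35.75,633.82
38,−0.682,0.376,0.25,48.27,0,5,2,324.76,35.75,633.82
39,−0.522,0.319,0.19,48.27,0,5,2,324.76,35.75,633.82
40,−0.393,0.465,0.29,48.27,0,5,2,359.21,37.57,662.67
41,−0.615,0.341,0.22,48.27,0,5,3,304.35,35.75,643.58
42,−0.521,0.459,0.28,48.27,0,5,3,338.82,37.57,672.43
43,−0.469,0.459,0.28,48.27,0,5,3,338.82,37.57,672.43
44,−0.451,0.459,0.28,48.27,0,5,3,338.82,37.57,672.43
45,−0.474,0.524,0.33,48.27,0,5,3,318.41,37.57,674.68
46,−0.373,0.712,0.45,48.27,0,5,3,332.44,39.26,705.77
47,−0.342,0.712,0.45,48.27,0,5,3,332.44,39.26,705.77
48,−0.356,0.635,0.38,48.27,0,5,3,352.85,39.26,703.53
49,−0.389,0.635,0.38,48.27,0,5,3,352.85,39.33,703.53
50,−0.302,0.635,0.38,48.27,0,5,3,352.85,39.33,703.53
51,−0.531,0.424,0.19,57.50,0,6,5,348.44,39.88,732.46
52,−0.387,0.602,0.37,57.50,0,6,5,362.47,41.63,763.55
53,−0.416,0.526,0.23,57.50,0,6,5,382.88,41.70,761.31
54,−0.505,0.526,0.23,57.50,0,6,5,382.88,41.70,761.31
55,−0.343,0.526,0.22,57.50,0,6,5,382.88,41.70,761.31
56,−0.550,0.635,0.38,48.27,0,5,3,352.85,39.33,703.53
57,−0.803,0.440,0.27,48.27,0,5,3,338.82,37.57,672.43
58,−0.317,0.551,0.31,48.27,0,5,3,373.27,39.40,701.28
59,−0.326,0.551,0.31,48.27,0,5,3,373.27,39.40,701.28
60,−0.260,0.551,0.31,48.27,0,5,3,373.27,39.40,701.28
61,−0.456,0.459,0.29,48.27,0,5,4,318.37,37.58,682.19
62,−0.312,0.651,0.41,48.27,0,5,4,332.40,39.33,713.29
63,−0.370,0.567,0.34,48.27,0,5,4,352.82,39.40,711.04
64,−0.256,0.551,0.33,48.27,0,5,4,352.82,39.40,711.04
65,−0.190,0.701,0.43,48.27,0,5,4,387.26,41.22,739.89
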