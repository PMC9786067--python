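compound_id,inv_km,kam_over_km,r2
1,−0.765,9.066,0.9178
2,−0.586,6.826,0.9530
3,−0.758,8.907,0.9110
4,−0.528,6.157,0.9700
5,−0.518,6.028,0.9553
6,−0.406,4.722,0.9748
7,−1.046,12.573,0.9124
8,−0.785,9.294,0.9592
9,−1.163,13.801,0.9618
10,−0.876,10.274,0.9477
11,−0.707,8.316,0.9759
12,−0.760,8.902,0.9302
13,−0.568,6.593,0.9592
14,−0.565,7.520,0.9932
15,−0.509,5.898,0.9696
16,−0.503,5.825,0.9732
17,−0.395,4.569,0.9734
18,−0.599,7.079,0.9622
19,−0.597,6.995,0.9375
20,−0.410,4.836,0.9776
21,−0.594,6.814,0.9473
22,−0.458,5.274,0.9638
23,−0.474,5.694,0.9695
24,−1.131,12.985,0.9193
25,−0.692,7.917,0.9672
26,−0.420,4.868,0.9733
27,−0.639,7.247,0.9662
28,−0.461,5.307,0.9593
29,−0.382,4.464,0.9659
30,−0.451,5.916,0.9656
31,−0.301,3.477,0.9657
32,−0.287,3.322,0.9707
33,−0.479,5.531,0.9187
34,−0.329,3.829,0.9615
35,−0.321,3.685,0.9604
36,−0.432,5.006,0.9593
37,−0.425,4.933,0.9442
38,−0.425,4.870,0.9606
39,−0.288,3.326,0.9717
40,−0.214,2.470,0.9692
41,−0.354,4.119,0.9753
42,−0.289,3.322,0.9764
43,−0.225,2.944,0.9724
44,−0.246,2.822,0.9741
45,−0.257,2.976,0.9378
46,−0.206,2.361,0.9705
47,−0.190,2.198,0.9728
48,−0.199,2.272,0.9694
49,−0.213,2.448,0.9695
50,−0.174,2.001,0.9666
51,−0.295,3.399,0.9704
52,−0.211,2.441,0.9718
53,−0.227,2.606,0.9684
54,−0.285,3.202,0.9441
55,−0.191,2.203,0.9636
56,−0.309,3.549,0.9763
57,−0.540,6.358,0.9690
58,−0.180,2.073,0.9521
59,−0.185,2.118,0.9609
60,−0.157,1.820,0.9465
61,−0.241,2.856,0.9792
62,−0.175,2.051,0.9765
63,−0.193,2.343,0.9682
64,−0.151,1.802,0.9488
65,−0.132,1.550,0.9358
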