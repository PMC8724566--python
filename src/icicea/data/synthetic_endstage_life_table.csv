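years_since_entry,survival_fraction
0.0,1.0
1.0,0.825582
2.0,0.693041
3.0,0.591555
4.0,0.511197
5.0,0.445303
6.0,0.391019
7.0,0.34611
8.0,0.308819
9.0,0.276881
10.0,0.248661
11.0,0.223689
12.0,0.20156
13.0,0.181924
14.0,0.164474
15.0,0.148947
16.0,0.13511
17.0,0.122763
18.0,0.11173
19.0,0.101859
20.0,0.093014
21.0,0.085009
22.0,0.077692
23.0,0.071005
24.0,0.064894
25.0,0.059309
26.0,0.054204
27.0,0.049539
28.0,0.045275
29.0,0.041378
30.0,0.037817
31.0,0.034562
32.0,0.031587
33.0,0.028869
34.0,0.026384
35.0,0.024113
36.0,0.022038
37.0,0.020141
38.0,0.018407
39.0,0.016823
40.0,0.015375
41.0,0.014052
42.0,0.012842
43.0,0.011737
44.0,0.010727
45.0,0.009804
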