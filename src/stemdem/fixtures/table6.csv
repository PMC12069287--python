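no,K_n,K_s,tau_m,R_ab,F_max
1,1,1,1,-1,706.67
2,1,-1,-1,-1,198.75
3,1,-1,1,-1,844.46
4,0,0,0,-1,718.49
5,-1,-1,-1,1,599.05
6,1,-1,-1,1,1271.36
7,1,1,-1,-1,486.46
8,1,-1,1,1,2113.33
9,-1,-1,1,-1,202.48
10,0,0,1,0,1237.14
11,0,0,-1,0,1236.68
12,1,1,1,1,2273.51
13,-1,1,1,-1,264.38
14,0,0,0,0,1562.00
15,-1,-1,1,1,602.16
16,-1,1,1,1,1037.15
17,0,0,0,1,2050.50
18,0,0,0,0,1236.68
19,0,1,0,0,919.73
20,-1,1,-1,-1,248.21
21,-1,1,-1,1,1026.42
22,1,1,-1,1,2051.28
23,-1,-1,-1,-1,450.22
24,-1,0,0,0,760.33
25,0,0,0,0,1258.68
26,1,0,0,0,1722.05
27,0,-1,0,0,915.53
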