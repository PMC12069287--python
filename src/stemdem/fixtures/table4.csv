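no,A,B,C,D,E,F,K_n,K_s,sigma_m,tau_m,R_ab,F_max
1,1,1,1,-1,-1,1,1,-1,1,1,-1,1097.85
2,1,-1,1,1,-1,-1,-1,-1,1,-1,1,149.85
3,-1,-1,-1,1,-1,1,-1,1,1,1,1,1167.05
4,1,1,-1,-1,1,1,-1,1,1,-1,-1,6.19
5,1,-1,-1,-1,-1,1,-1,1,-1,1,1,1612.92
6,-1,1,1,-1,1,1,-1,-1,-1,-1,1,155.47
7,-1,-1,1,1,-1,1,1,-1,-1,-1,-1,443
8,1,1,-1,-1,-1,-1,1,-1,1,-1,1,515.08
9,0,0,0,0,0,0,0,0,0,0,0,849.58
10,1,-1,1,-1,1,1,1,1,-1,-1,1,716.83
11,-1,1,1,-1,-1,-1,-1,1,-1,1,-1,7.11
12,1,-1,-1,1,1,-1,1,1,-1,-1,-1,625.17
13,-1,1,-1,1,-1,1,1,1,1,-1,-1,724.18
14,1,1,1,1,-1,-1,1,1,-1,1,1,1694.48
15,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1,1.92
16,1,-1,1,1,1,1,-1,-1,1,1,-1,84.01
17,-1,-1,1,-1,1,-1,1,1,1,1,-1,2610.67
18,1,1,-1,1,1,-1,-1,-1,-1,1,-1,22.99
19,-1,-1,-1,-1,1,-1,1,-1,1,1,1,1356.97
20,-1,1,-1,1,1,1,1,-1,-1,1,1,1022.18
21,-1,1,1,1,1,-1,-1,1,1,-1,1,1021.29
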