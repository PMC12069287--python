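no,K_n,K_s,tau_m,F_max,delta_E_printed,anomaly
1,5e10,5e10,1e10,2785.90,79.33,
2,5e10,3e10,1e9,2296.34,47.82,
3,5e10,1e10,1e8,1445.99,6.93,recompute_6.92
4,3e10,1e10,1e10,1269.11,18.31,
5,3e10,3e10,1e9,1459.89,6.02,recompute_6.03
6,3e10,5e10,1e8,1100.32,29.17,
7,1e10,1e10,1e10,933.54,39.91,
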