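metric,method,simulated,actual,error_pct_printed,anomaly
rupture_force_N,RSM,1459.35,1553.51,6.06,
rupture_force_N,GA-BP-GA,1596.78,1553.51,2.79,
elastic_slope_N_mm,RSM,1058.90,967.92,9.40,
elastic_slope_N_mm,GA-BP-GA,965.65,967.92,0.24,recompute_0.23
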