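source,sum_sq,df,mean_sq,F,p,sig,anomaly
Model,9.44E+06,14,6.70E+05,23.79,<0.0001,**,
K_n,2.33E+06,1,2.33E+06,82.84,<0.0001,**,
K_s,1.83E+05,1,1.83E+05,6.51,0.0254,*,
tau_m,1.63E+05,1,1.63E+05,5.79,0.0331,*,
R_ab,4.41E+06,1,4.41E+06,156.55,<0.0001,**,
K_n K_s,8454.02,1,8454.02,0.3004,0.5937,,
K_n tau_m,2.88E+05,1,2.88E+05,10.25,0.0076,**,
K_n R_ab,7.11E+05,1,7.11E+05,25.28,0.0003,**,
K_s tau_m,37413.13,1,37413.13,1.33,0.2713,,
K_s R_ab,2.01E+05,1,2.01E+05,7.14,0.0203,*,
tau_m R_ab,12303.19,1,12303.19,0.4372,0.5210,,
K_n^2,9020.20,1,9020.20,0.3206,0.5817,,
K_s^2,3.77E+05,1,3.77E+05,13.39,0.0033,**,
tau_m^2,10370.33,1,10370.33,0.3685,0.5551,,
R_ab^2,18178.72,1,18178.12,0.6460,0.4372,,mean_sq_differs_from_sum_sq_as_printed
Residual,3.38E+05,12,28138.71,,,,
Lack of Fit,2.72E+05,10,27155.78,1.05,0.5818,,text_quotes_p_0.6584
Pure Error,66106.71,2,33053.35,,,,
Cor Total,9.71E+06,26,,,,,
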