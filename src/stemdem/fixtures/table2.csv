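item,branch,steel
Poisson's ratio,0.36,0.30
Density/kg m^-3,984.7,7850
Shear modulus/Pa,6.40e8,7.94e10
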