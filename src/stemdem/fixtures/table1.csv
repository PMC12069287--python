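item,min,max,average,std,anomaly
Tensile force/N,187.69,428.46,312.32,90.44,
Compressive force/N,2073.56,1044.4,1553.51,409.02,min_max_swapped_as_printed
Bending force/N,258.78,895.60,520.48,162.09,
Shear force/N,811.02,2089.94,1376.52,260.47,
Elastic modulus/Pa,1.04e9,2.56e9,1.74e9,555.23,std_unit_unclear_as_printed
Shear modulus/Pa,3.82e8,9.41e8,6.40e8,204.04,std_unit_unclear_as_printed
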