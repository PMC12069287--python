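parameter,code,low,high
Particle-particle collision recovery coefficient,A,0.37,0.60
Particle-particle coefficient of static friction,B,0.45,0.57
Particle-particle coefficient of kinetic friction,C,0.22,0.3
Particle-geometry collision recovery coefficient,D,0.44,0.64
Particle-geometry's static friction coefficient,E,0.42,0.51
Particle-geometry's coefficient of kinetic friction,F,0.12,0.21
Particle-particle normal stiffness per unit area/N m^-3,K_n,1e9,1e11
Particle-particle shear stiffness per unit area/N m^-3,K_s,1e9,1e11
Particle-particle critical normal stress/Pa,sigma_m,1e7,1e10
Particle-particle critical shear stress/Pa,tau_m,1e7,1e10
Bonding radius/mm,R_ab,0.6,1
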