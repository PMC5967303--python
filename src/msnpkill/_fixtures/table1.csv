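mouse,si_mass_percent,t0,theta_f,p_value,r_squared,n_points
MSNP 4,0.00513,,0.4621,,,2
MSNP 7,0.00535,,0.3068,,,2
MSNP 2,0.00372,0,0.0096,0.0030,0.9648,4
MSNP 3,0.00362,0,0.0067,0.0050,0.9499,4
MSNP 1,0.00360,0,0.0064,0.0110,0.9155,4
MSNP 5,0.00138,0,0.0027,0.1990,0.4728,4
MSNP 6,0.00260,0,0.0013,0.0060,0.9409,4
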