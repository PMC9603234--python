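# Optimized parameter set scaled to 5 C.
k_s: 2.8
x1: 0.0
x11: 0.0
x2: -5.5
x3: -7.7
x_crit: 0.6
dG_w: 0.0
dG_on: 0.7
dG_PiR: 1.0
dG_LH: 5.1
dG_HD: 4.0
dG_ATP_const: 13.1
kon_prime: 62.5
kPr_prime: 750.0
kP_plus: 10000.0
kLH_minus: 2000.0
kLH_plus_cap: 6000.0
k5_minus: 2000.0
k2_zero: 413.0
k6: 5000.0
k3_sum: 12.5
K3: 4.0
K1: 1.7
KC: 10.0
mgatp: 5.0
pi: 0.5
mgadp: 0.0
temperature_C: 5.0
r_max_iso: 100000.0
r_max_shortening: 1000000.0
r_min: 1e-06
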