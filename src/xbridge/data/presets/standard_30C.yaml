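# Standard parameter set, fast mammalian skeletal myosin at 30 C.
# First sub-stroke d1 = 5.7 nm, second sub-stroke d2 = 1.0 nm.
k_s: 2.8
x1: 7.2
x11: 6.7
x2: 1.0
x3: 0.0
x_crit: 0.6
dG_w: 0.0
dG_on: 0.7
dG_PiR: 1.0
dG_LH: 14.0
dG_HD: 2.0
dG_ATP_const: 13.1
kon_prime: 130.0
kPr_prime: 3000.0
kP_plus: 10000.0
kLH_minus: 2000.0
kLH_plus_cap: 6000.0
k5_minus: 2000.0
k2_zero: 2000.0
k6: 5000.0
k3_sum: 220.0
K3: 10.0
K1: 1.7
KC: 10.0
mgatp: 5.0
pi: 0.5
mgadp: 0.0
temperature_C: 30.0
r_max_iso: 1.0e+5
r_max_shortening: 1.0e+6
r_min: 1.0e-6
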