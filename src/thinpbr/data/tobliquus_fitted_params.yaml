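# Fitted kinetic parameter sets for Tetradesmus obliquus in flat continuous
# photobioreactors, keyed by reactor thickness in mm. K_I and k_d are the
# fixed literature values shared by every thickness.
# Units: mu_max, k_d in d^-1; K_I, I_opt in umol m^-2 s^-1; k_a in m^2 g^-1.
2:
  mu_max: 1.8
  K_I: 110.0
  I_opt: 50.0
  k_d: 0.45
  k_a: 0.9
5:
  mu_max: 2.1
  K_I: 110.0
  I_opt: 59.0
  k_d: 0.45
  k_a: 0.57
8:
  mu_max: 2.1
  K_I: 110.0
  I_opt: 74.0
  k_d: 0.45
  k_a: 0.40
15:
  mu_max: 2.0
  K_I: 110.0
  I_opt: 405.0
  k_d: 0.45
  k_a: 0.14
35:
  mu_max: 2.0
  K_I: 110.0
  I_opt: 405.0
  k_d: 0.45
  k_a: 0.098
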