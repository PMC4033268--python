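# Vascular smooth muscle wall-mechanics constants for the five vasoactive
# compartments.  D0 is the passive diameter at 100 torr; C_pass/C'_pass the
# passive exponential tension curve; C_act/C'_act/C''_act the active
# length-tension Gaussian; C_myo and C_shear the myogenic and shear
# sensitivities of the tone stimulus.  C''_tone is not listed here: it is
# calibrated so the resting network is a fixed point.
time_constants:
  tau_d_s: 1.0     # diameter relaxation
  tau_a_s: 20.0    # smooth-muscle activation
compartments:
  FA: {D0_um: 173.1, C_myo: 0.0079, C_shear: 0.0258, C_pass: 1154.0,
       C_pass_prime: 7.846, C_act: 2671.0, C_act_prime: 0.6709, C_act_dprime: 0.2765}
  1A: {D0_um: 125.3, C_myo: 0.0109, C_shear: 0.0258, C_pass: 834.9,
       C_pass_prime: 9.138, C_act: 1654.0, C_act_prime: 0.6991, C_act_dprime: 0.3148}
  2A: {D0_um: 95.41, C_myo: 0.0143, C_shear: 0.0258, C_pass: 636.0,
       C_pass_prime: 9.944, C_act: 1106.0, C_act_prime: 0.7167, C_act_dprime: 0.3387}
  3A: {D0_um: 62.98, C_myo: 0.0217, C_shear: 0.0258, C_pass: 419.8,
       C_pass_prime: 10.82, C_act: 598.1, C_act_prime: 0.7358, C_act_dprime: 0.3646}
  TA: {D0_um: 41.35, C_myo: 0.0331, C_shear: 0.0258, C_pass: 275.6,
       C_pass_prime: 11.40, C_act: 320.8, C_act_prime: 0.7486, C_act_dprime: 0.3819}
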