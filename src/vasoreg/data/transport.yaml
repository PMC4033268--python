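# Oxygen transport, metabolic signaling and tissue geometry.
oxygen:
  M0: 1.0                 # oxygen demand, cm3 O2 / 100 cm3 tissue / min (rest)
  C0: 0.5                 # carrying capacity, cm3 O2 / cm3 blood
  HT: 0.3                 # tube hematocrit
  HD: 0.4                 # discharge hematocrit
  hill_n: 2.7             # Hill exponent
  P50: 26.0               # half-saturation tension, torr
  S_in: 0.97              # inlet saturation
  R0: 1.4                 # maximal ATP release rate, uM/s (= 1.4e-9 mol/s/cm3)
  R1: 0.891               # saturation feedback on ATP release
  C_atp_in: 0.5           # inlet plasma ATP, uM
  k_d: 2.0e-4             # wall ATP degradation rate, cm/s
signal:
  L_met_cm: 1.0           # conduction length constant
  C_meta: 30.0            # metabolic signal coefficient, uM^-1 cm^-1
tissue:
  sleeve_width_um: 18.8
  capillary_density_mm2: 500.0
integrator:
  dt_s: 0.01
  record_dt_s: 0.1
  steady_tol_um_s: 1.0e-6
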