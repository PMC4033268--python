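# Reference-network specification: the primary (specified) quantities of the
# resting state, one record per compartment in serial order.  Fields left
# null are derived: arterial/capillary viscosities from the in-vivo
# viscosity law, the artery diameter from its length/shear/pressure-drop,
# venous diameters from the venous wall shear and flow conservation.
inlet_pressure_mmHg: 100.0
viscosity_law: pries-invivo
compartments:
  - {name: A,  wall_shear_dyn_cm2: 55.0, dp_mmHg: 10.0, length_cm: 0.61,
     diameter_um: null, viscosity_cP: null, vasoactive: false, exchanges_oxygen: false}
  - {name: FA, wall_shear_dyn_cm2: 55.0, dp_mmHg: 15.0, diameter_um: 60.0,
     viscosity_cP: null, vasoactive: true, exchanges_oxygen: true}
  - {name: 1A, wall_shear_dyn_cm2: 55.0, dp_mmHg: 10.0, diameter_um: 37.0,
     viscosity_cP: null, vasoactive: true, exchanges_oxygen: true}
  - {name: 2A, wall_shear_dyn_cm2: 55.0, dp_mmHg: 10.0, diameter_um: 25.8,
     viscosity_cP: null, vasoactive: true, exchanges_oxygen: true}
  - {name: 3A, wall_shear_dyn_cm2: 55.0, dp_mmHg: 10.0, diameter_um: 15.6,
     viscosity_cP: null, vasoactive: true, exchanges_oxygen: true}
  - {name: TA, wall_shear_dyn_cm2: 55.0, dp_mmHg: 10.0, diameter_um: 9.7,
     viscosity_cP: null, vasoactive: true, exchanges_oxygen: true}
  - {name: C,  wall_shear_dyn_cm2: 55.0, dp_mmHg: 15.0, diameter_um: 6.0,
     viscosity_cP: null, vasoactive: false, exchanges_oxygen: true}
  - {name: TV, wall_shear_dyn_cm2: 10.0, viscosity_cP: 3.42,
     vasoactive: false, exchanges_oxygen: false}
  - {name: 1V, wall_shear_dyn_cm2: 10.0, viscosity_cP: 2.44,
     vasoactive: false, exchanges_oxygen: false}
  - {name: 2V, wall_shear_dyn_cm2: 10.0, viscosity_cP: 2.07,
     vasoactive: false, exchanges_oxygen: false}
  - {name: 3V, wall_shear_dyn_cm2: 10.0, viscosity_cP: 2.11,
     vasoactive: false, exchanges_oxygen: false}
  - {name: DV, wall_shear_dyn_cm2: 10.0, viscosity_cP: 2.30,
     vasoactive: false, exchanges_oxygen: false}
  - {name: V,  wall_shear_dyn_cm2: 10.0, viscosity_cP: 2.50,
     vasoactive: false, exchanges_oxygen: false}
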