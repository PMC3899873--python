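energy:
  J_E:
    ECM:
      ECM: 10.0
      ECM_fluid: 130.0
      luminal_fluid: 130.0
      cytoplasm: 130.0
      basolateral: 10.0
      apical: 10.0
      vesicle: 10.0
      vacuole: 10.0
    ECM_fluid:
      ECM: 130.0
      ECM_fluid: 0.0
      luminal_fluid: 0.0
      cytoplasm: 10.0
      basolateral: 200.0
      apical: 50.0
      vesicle: 10.0
      vacuole: 10.0
    luminal_fluid:
      ECM: 130.0
      ECM_fluid: 0.0
      luminal_fluid: 0.0
      cytoplasm: 10.0
      basolateral: 200.0
      apical: 50.0
      vesicle: 10.0
      vacuole: 10.0
    cytoplasm:
      ECM: 130.0
      ECM_fluid: 10.0
      luminal_fluid: 10.0
      cytoplasm: 10.0
      basolateral: 10.0
      apical: 200.0
      vesicle: 10.0
      vacuole: 10.0
    basolateral:
      ECM: 10.0
      ECM_fluid: 200.0
      luminal_fluid: 200.0
      cytoplasm: 10.0
      basolateral: 30.0
      apical: 50.0
      vesicle: 10.0
      vacuole: 10.0
    apical:
      ECM: 10.0
      ECM_fluid: 50.0
      luminal_fluid: 50.0
      cytoplasm: 200.0
      basolateral: 50.0
      apical: 200.0
      vesicle: 10.0
      vacuole: 10.0
    vesicle:
      ECM: 10.0
      ECM_fluid: 10.0
      luminal_fluid: 10.0
      cytoplasm: 10.0
      basolateral: 10.0
      apical: 10.0
      vesicle: 10.0
      vacuole: 10.0
    vacuole:
      ECM: 10.0
      ECM_fluid: 10.0
      luminal_fluid: 10.0
      cytoplasm: 10.0
      basolateral: 10.0
      apical: 10.0
      vesicle: 10.0
      vacuole: 10.0
  J_I:
    cytoplasm:
      cytoplasm: 10.0
      basolateral: 5.0
      apical: 5.0
      vesicle: 10.0
      vacuole: 20.0
    basolateral:
      cytoplasm: 5.0
      basolateral: 10.0
      apical: 70.0
      vesicle: 100.0
      vacuole: 100.0
    apical:
      cytoplasm: 5.0
      basolateral: 70.0
      apical: 10.0
      vesicle: 1.0
      vacuole: 1.0
    vesicle:
      cytoplasm: 10.0
      basolateral: 100.0
      apical: 1.0
      vesicle: 10.0
      vacuole: 5.0
    vacuole:
      cytoplasm: 20.0
      basolateral: 100.0
      apical: 1.0
      vesicle: 5.0
      vacuole: 5.0
  mu: 50.0
  J_rep: 200.0
  contact_neighborhood: moore
lambdas:
  cell: 7.0
  fluids: 6.0
  vacuole: 50.0
  vesicle: 1000.0
mechanisms:
  enable_polarization: true
  enable_vacuolation: true
  enable_repulsion: true
  P_pin: 1.0
  P_A: 1.0
  P_fuse: 1.0
  P_I: 0.0
run:
  mcs: 10000
  replicates: 30
  seed: 0
geometry:
  kind: branched_sprout
  width: 550
  height: 550
  cell_size: 25
  cap_size:
  - 25
  - 10
  n_layers: 1
  cells_per_row: 6
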