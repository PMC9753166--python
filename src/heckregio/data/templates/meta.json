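{
  "version": 1,
  "comment": "Idealized square-planar Pd(II) cores; Pd-X bond lengths (Angstrom) substituted per leaving group at load time.",
  "pd_x_distance": {"Cl": 2.40, "Br": 2.50, "I": 2.70, "OTf": 2.10},
  "x_attachment_element": {"Cl": "Cl", "Br": "Br", "I": "I", "OTf": "O"},
  "charges": {"neutral": 0, "cationic": 1}
}
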