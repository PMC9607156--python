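# Role map for the synthetic pseudo-molecules produced by ldtk.synth.
# Pseudo-molecules carry only role-bearing atoms; "W" is a single-site
# pseudo-water (mass 18.015 g/mol in the shipped mass table).
residues:
  CHY:                      # sterol-ester pseudo-molecule
    class: CHYO
    roles:
      ESTER_O: [O1, O2]
      STEROL_RING: ["R?"]
      STEROL_SIDE: [S1]
      ACYL_C: ["T?"]
    elements: {"R?": C, "S?": C, "T?": C}
  TGL:                      # triacylglycerol pseudo-molecule
    class: TG
    roles:
      ESTER_O: [E1, E2, E3]
      GLYCEROL_O: [G1, G2, G3]
      ACYL_C: ["A?"]
    elements: {"E?": O, "G?": O, "A?": C}
  PLM:                      # phospholipid pseudo-molecule
    class: PL
    roles:
      PHOSPHORUS: [P]
      HEAD: [P, ND]
      ACYL_C: ["C?"]
      ACYL_H: ["H??"]
  SOL:
    class: WATER
    roles:
      WATER_O: [W1]
    elements: {W1: W}
  NAI:
    class: ION
    roles: {}
    elements: {NA: NA}
  CLI:
    class: ION
    roles: {}
    elements: {CL: CL}
  # --- defect-leaflet marker molecules (0.1 A radius: each marker covers
  # --- exactly one cell of the 1 A defect grid)
  HDP:                      # head-group marker (one P atom per covered cell)
    class: PL
    roles:
      PHOSPHORUS: [P]
      HEAD: [P]
    radii: {"*": 0.1}
  PAD:                      # exposed PL acyl carbon markers
    class: PL
    roles:
      ACYL_C: ["A*"]
    elements: {"A*": C}
    radii: {"*": 0.1}
  TGD:                      # exposed TG glycerol/ester oxygen markers
    class: TG
    roles:
      ESTER_O: [O1, O2, O3]
      GLYCEROL_O: [O4, O5, O6]
    radii: {"*": 0.1}
  TAD:                      # exposed TG acyl markers (oxygens parked below z_thr)
    class: TG
    roles:
      ESTER_O: [O1, O2, O3]
      GLYCEROL_O: [O4, O5, O6]
      ACYL_C: ["A*"]
    elements: {"A*": C}
    radii: {"*": 0.1}
  CSD:                      # exposed sterol ring/side markers
    class: CHYO
    roles:
      ESTER_O: [O1, O2]
      STEROL_RING: ["R*"]
    elements: {"R*": C}
    radii: {"*": 0.1}
  CAD:                      # exposed CHYO acyl markers
    class: CHYO
    roles:
      ESTER_O: [O1, O2]
      ACYL_C: ["A*"]
    elements: {"A*": C}
    radii: {"*": 0.1}
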