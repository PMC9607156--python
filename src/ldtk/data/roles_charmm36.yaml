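# Best-effort role map for CHARMM36 residue/atom naming of the trilayer
# species (POPC, DOPE, SAPI phosphoinositol, triolein, cholesteryl oleate,
# TIP3 water, NaCl).  Atom patterns follow CHARMM36 lipid conventions:
# head-group/glycerol/ester atoms are polar (HEAD), chain carbons C2x/C3x
# are acyl.  Adjust per force-field port before analysing real data.
residues:
  POPC:
    class: PL
    roles:
      PHOSPHORUS: [P]
      HEAD: [N, P, "C1*", "H1*", "O1?", C1, C2, C3, HA, HB, HS, HX, HY,
             "O2?", "O3?"]
      ACYL_C: ["C2?", "C2??", "C3?", "C3??"]
      ACYL_H: ["H?R", "H?S", "H?X", "H?Y", "H?Z", "H??R", "H??S", "H??X",
               "H??Y", "H??Z", "H?T", "H??T", "H16*", "H18*", "H9?", "H10?"]
  DOPE:
    class: PL
    roles:
      PHOSPHORUS: [P]
      HEAD: [N, P, "HN?", "C1*", "H1*", "O1?", C1, C2, C3, HA, HB, HS, HX,
             HY, "O2?", "O3?"]
      ACYL_C: ["C2?", "C2??", "C3?", "C3??"]
      ACYL_H: ["H?R", "H?S", "H?X", "H?Y", "H?Z", "H??R", "H??S", "H??X",
               "H??Y", "H??Z", "H?T", "H??T", "H18*", "H9?", "H10?"]
  SAPI:
    class: PL
    roles:
      PHOSPHORUS: [P]
      HEAD: [P, "C1*", "H1*", "O1?", "O2", "O3", "O4", "O5", "O6", "HO?",
             C1, C2, C3, HA, HB, HS, HX, HY, "O2?", "O3?"]
      ACYL_C: ["C2?", "C2??", "C3?", "C3??"]
      ACYL_H: ["H?R", "H?S", "H?X", "H?Y", "H?Z", "H??R", "H??S", "H??X",
               "H??Y", "H??Z", "H?T", "H??T", "H9?", "H10?", "H20*"]
  TRIO:                     # triolein: six ester-linkage oxygens
    class: TG
    roles:
      ESTER_O: ["O1?", "O2?", "O3?"]
      ACYL_C: ["C1??", "C2??", "C3??", "C18", "C28", "C38"]
      ACYL_H: ["H*"]
  CHYO:                     # cholesteryl oleate
    class: CHYO
    roles:
      ESTER_O: [O1, O2]
      STEROL_RING: [C1, C2, C3, C4, C5, C6, C7, C8, C9, C10, C11, C12, C13,
                    C14, C15, C16, C17, C18, C19]
      STEROL_SIDE: [C20, C21, C22, C23, C24, C25, C26, C27]
      ACYL_C: ["C1'", "C2'", "C3'", "C4'", "C5'", "C6'", "C7'", "C8'",
               "C9'", "C10'", "C11'", "C12'", "C13'", "C14'", "C15'",
               "C16'", "C17'", "C18'"]
      ACYL_H: ["H*'"]
  TIP3:
    class: WATER
    roles:
      WATER_O: [OH2, OW]
  SOD:
    class: ION
    roles: {}
    elements: {SOD: NA}
  CLA:
    class: ION
    roles: {}
    elements: {CLA: CL}
  POT:
    class: ION
    roles: {}
    elements: {POT: K}
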