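{
  "ALA": {},
  "GLY": {},
  "SER": {},
  "THR": {},
  "CYS": {},
  "VAL": {},
  "LEU": {},
  "ILE": {},
  "MET": {},
  "PRO": {},
  "ASN": {},
  "GLN": {},
  "PHE": {"rings": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]]},
  "TYR": {"rings": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]]},
  "TRP": {"rings": [["CG", "CD1", "NE1", "CE2", "CD2"],
                    ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]]},
  "HIS": {"rings": [["CG", "ND1", "CD2", "CE1", "NE2"]]},
  "LYS": {"cation_groups": [["NZ"]]},
  "ARG": {"cation_groups": [["NE", "CZ", "NH1", "NH2"]]},
  "ASP": {"anion_groups": [["CG", "OD1", "OD2"]]},
  "GLU": {"anion_groups": [["CD", "OE1", "OE2"]]},
  "AIB": {},
  "BIP": {"rings": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
                    ["C1B", "C2B", "C3B", "C4B", "C5B", "C6B"]]},
  "PHF": {"rings": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]]},
  "MPH": {"rings": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]]},
  "MPF": {"rings": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]]},
  "NH4": {"cation_groups": [["N"]]},
  "ACT": {"anion_groups": [["C", "O1", "O2"]]},
  "BNZ": {"rings": [["C1", "C2", "C3", "C4", "C5", "C6"]]},
  "ALK": {},
  "CBX": {},
  "AMN": {}
}
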