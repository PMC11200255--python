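{
  "comment": "AutoDock-Vina-style extended (XS) atom types. vdw_radius in Angstroms. 'hydrophobic' marks atoms that count toward hydrophobic terms; 'donor'/'acceptor' mark hydrogen-bond capability. 'pair_types' lists the 25 canonical heavy types that parameterize atom_type_gaussian pair terms; GenericMetal is the logged fallback for unrecognized elements and does not enter pair terms.",
  "types": {
    "AliphaticCarbonXSHydrophobe":    {"vdw_radius": 1.9, "hydrophobic": true,  "donor": false, "acceptor": false},
    "AliphaticCarbonXSNonHydrophobe": {"vdw_radius": 1.9, "hydrophobic": false, "donor": false, "acceptor": false},
    "AromaticCarbonXSHydrophobe":     {"vdw_radius": 1.9, "hydrophobic": true,  "donor": false, "acceptor": false},
    "AromaticCarbonXSNonHydrophobe":  {"vdw_radius": 1.9, "hydrophobic": false, "donor": false, "acceptor": false},
    "Nitrogen":                       {"vdw_radius": 1.8, "hydrophobic": false, "donor": false, "acceptor": false},
    "NitrogenXSDonor":                {"vdw_radius": 1.8, "hydrophobic": false, "donor": true,  "acceptor": false},
    "NitrogenXSAcceptor":             {"vdw_radius": 1.8, "hydrophobic": false, "donor": false, "acceptor": true},
    "NitrogenXSDonorAcceptor":        {"vdw_radius": 1.8, "hydrophobic": false, "donor": true,  "acceptor": true},
    "Oxygen":                         {"vdw_radius": 1.7, "hydrophobic": false, "donor": false, "acceptor": false},
    "OxygenXSDonor":                  {"vdw_radius": 1.7, "hydrophobic": false, "donor": true,  "acceptor": false},
    "OxygenXSAcceptor":               {"vdw_radius": 1.7, "hydrophobic": false, "donor": false, "acceptor": true},
    "OxygenXSDonorAcceptor":          {"vdw_radius": 1.7, "hydrophobic": false, "donor": true,  "acceptor": true},
    "Sulfur":                         {"vdw_radius": 2.0, "hydrophobic": false, "donor": false, "acceptor": false},
    "SulfurAcceptor":                 {"vdw_radius": 2.0, "hydrophobic": false, "donor": false, "acceptor": true},
    "Phosphorus":                     {"vdw_radius": 2.1, "hydrophobic": false, "donor": false, "acceptor": false},
    "Fluorine":                       {"vdw_radius": 1.5, "hydrophobic": true,  "donor": false, "acceptor": false},
    "Chlorine":                       {"vdw_radius": 1.8, "hydrophobic": true,  "donor": false, "acceptor": false},
    "Bromine":                        {"vdw_radius": 2.0, "hydrophobic": true,  "donor": false, "acceptor": false},
    "Iodine":                         {"vdw_radius": 2.2, "hydrophobic": true,  "donor": false, "acceptor": false},
    "Boron":                          {"vdw_radius": 1.92,"hydrophobic": false, "donor": false, "acceptor": false},
    "Magnesium":                      {"vdw_radius": 1.2, "hydrophobic": false, "donor": true,  "acceptor": false},
    "Manganese":                      {"vdw_radius": 1.2, "hydrophobic": false, "donor": true,  "acceptor": false},
    "Zinc":                           {"vdw_radius": 1.2, "hydrophobic": false, "donor": true,  "acceptor": false},
    "Calcium":                        {"vdw_radius": 1.2, "hydrophobic": false, "donor": true,  "acceptor": false},
    "Iron":                           {"vdw_radius": 1.2, "hydrophobic": false, "donor": true,  "acceptor": false},
    "GenericMetal":                   {"vdw_radius": 1.2, "hydrophobic": false, "donor": true,  "acceptor": false},
    "Hydrogen":                       {"vdw_radius": 0.0, "hydrophobic": false, "donor": false, "acceptor": false},
    "PolarHydrogen":                  {"vdw_radius": 0.0, "hydrophobic": false, "donor": false, "acceptor": false}
  },
  "pair_types": [
    "AliphaticCarbonXSHydrophobe", "AliphaticCarbonXSNonHydrophobe",
    "AromaticCarbonXSHydrophobe", "AromaticCarbonXSNonHydrophobe",
    "Nitrogen", "NitrogenXSDonor", "NitrogenXSAcceptor", "NitrogenXSDonorAcceptor",
    "Oxygen", "OxygenXSDonor", "OxygenXSAcceptor", "OxygenXSDonorAcceptor",
    "Sulfur", "SulfurAcceptor", "Phosphorus",
    "Fluorine", "Chlorine", "Bromine", "Iodine",
    "Boron", "Magnesium", "Manganese", "Zinc", "Calcium", "Iron"
  ],
  "element_map": {
    "MG": "Magnesium", "MN": "Manganese", "ZN": "Zinc", "CA": "Calcium", "FE": "Iron",
    "B": "Boron", "P": "Phosphorus", "S": "Sulfur",
    "F": "Fluorine", "CL": "Chlorine", "BR": "Bromine", "I": "Iodine"
  }
}
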