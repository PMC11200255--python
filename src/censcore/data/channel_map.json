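{
  "comment": "Default 28-channel map for voxelization: 14 receptor groups followed by 14 ligand groups. Each group lists the XS types it collects. Types not listed deposit no density.",
  "receptor_groups": [
    ["AliphaticCarbonXSHydrophobe"],
    ["AliphaticCarbonXSNonHydrophobe"],
    ["AromaticCarbonXSHydrophobe"],
    ["AromaticCarbonXSNonHydrophobe"],
    ["Calcium"],
    ["Iron"],
    ["Magnesium", "Manganese", "GenericMetal"],
    ["Nitrogen", "NitrogenXSAcceptor"],
    ["NitrogenXSDonor", "NitrogenXSDonorAcceptor"],
    ["Oxygen", "OxygenXSAcceptor"],
    ["OxygenXSDonor", "OxygenXSDonorAcceptor"],
    ["Phosphorus"],
    ["Sulfur", "SulfurAcceptor"],
    ["Zinc"]
  ],
  "ligand_groups": [
    ["AliphaticCarbonXSHydrophobe"],
    ["AliphaticCarbonXSNonHydrophobe"],
    ["AromaticCarbonXSHydrophobe"],
    ["AromaticCarbonXSNonHydrophobe"],
    ["Bromine", "Iodine"],
    ["Chlorine"],
    ["Fluorine"],
    ["Nitrogen", "NitrogenXSAcceptor"],
    ["NitrogenXSDonor", "NitrogenXSDonorAcceptor"],
    ["Oxygen", "OxygenXSAcceptor"],
    ["OxygenXSDonor", "OxygenXSDonorAcceptor"],
    ["Phosphorus"],
    ["Sulfur", "SulfurAcceptor"],
    ["Boron", "GenericMetal", "Magnesium", "Manganese", "Zinc", "Calcium", "Iron"]
  ]
}
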