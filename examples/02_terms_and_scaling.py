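"""Compute raw physicochemical terms, fit corpus scaling, filter sparse terms.

Featurizes a small synthetic corpus with the full default registry (named
Vina/smina terms, electrostatics, ligand counts, and all 325 pairwise steric
candidates), fits the corpus-wide max-abs scaling, and applies the sparsity
rule that discards steric terms nonzero in less than 1% of examples.
"""

import censcore as cs

spec = cs.SyntheticSpec(n_complexes=100, seed=0)
dataset = cs.generate_dataset(spec)

registry = cs.default_registry()
matrix = cs.featurize_dataset(dataset.complexes, registry)
print(f"raw term matrix: {matrix.shape[0]} complexes x {matrix.shape[1]} terms")

kept = cs.filter_sparse_terms(matrix, registry, threshold=0.01)
n_steric = sum(d.family == "atom_type_gaussian" for d in registry)
n_kept = sum(d.family == "atom_type_gaussian" for d in kept)
print(f"sparsity filter: {n_steric} steric candidates -> {n_kept} retained "
      f"(nonzero in >= 1% of examples); non-steric terms always retained")

scaling = cs.fit_scaling(matrix[[d.name for d in kept]])
scaled = cs.apply_scaling(matrix[[d.name for d in kept]], scaling)
print(f"after scaling: values span [{scaled.to_numpy().min():+.3f}, "
      f"{scaled.to_numpy().max():+.3f}] (always within [-1, +1], "
      "signs preserved)")
print("\nexample scaling factors (corpus-wide max |raw value|):")
for name in ["gauss(o=0,_w=0.5,_c=8)", "repulsion(o=0,_c=8)",
             "num_heavy_atoms"]:
    print(f"  {name:<28s} {scaling.factors[name]:.3f}")
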