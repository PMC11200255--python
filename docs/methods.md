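# Methods

## The model

`censcore` implements a *context explanation network* (CEN) scoring
function for protein/ligand complexes. Instead of regressing binding
affinity directly from structure, a 3D convolutional network maps a
voxelized complex to a vector of per-term weights `w`, and the affinity
prediction is the pure linear combination

    pK = w · t

of those weights with the complex's precalculated, corpus-scaled
physicochemical terms `t`. There is deliberately no intercept and no
nonlinearity after the weight head: the prediction decomposes exactly into
per-term contributions `w_j t_j`, which is the point of the architecture —
the weights are the interpretable output, affinity accuracy is what makes
them trustworthy.

## Physicochemical terms

Pairwise terms act on receptor–ligand heavy-atom pairs within a cutoff
(default 8 Å) as functions of the surface distance `ds = d − d0`, where
`d0` is the summed Vina-style vdW radii:

| family | form (per pair) | parameters (defaults) |
|---|---|---|
| gauss | `exp(−((ds−o)/w)²)` | `(o=0, w=0.5)` and `(o=3, w=2)` |
| repulsion | `(ds−o)²` for `ds<o`, else 0 | `o=0` |
| hydrophobic | ramp: 1 below `g`, 0 above `b` | `g=0.5, b=1.5`; both atoms hydrophobic |
| non_dir_h_bond | same ramp | `g=−0.7, b=0`; donor/acceptor-complementary pair |
| electrostatic | `q₁q₂/dⁱ`, magnitude capped | `i∈{1,2}`, cap 100 |
| atom_type_gaussian | `exp(−(ds/w)²)` over one XS type pair | `o=0, w=1.0` |

Whole-ligand count terms: `num_tors_div` (rotatable bonds / 5, divisor
configurable), `num_hydrophobic_atoms`, `num_heavy_atoms`, `ligand_length`
(maximal interatomic distance). Hydrogens inform typing but never enter
pairwise sums.

Notes on choices that were genuinely open:

* **Electrostatic cap.** The cap is applied to the pair value
  (`clip(q₁q₂/dⁱ, −cap, +cap)`), symmetric in sign; this matches the
  term's description as "each pair's value capped at 100" and keeps
  favorable and unfavorable contacts on the same footing.
* **atom_type_gaussian width.** Offset 0 and width 1.0 Å (the smina default
  for this keyword), configurable per descriptor.
* **Steric candidates.** The default registry enumerates all unordered
  pairs over 25 canonical heavy XS types — 325 candidates — plus the named
  terms above (336 total). A corpus-dependent sparsity filter drops steric
  terms nonzero in <1 % of examples (train and test jointly); on the toy
  corpora used here roughly 20 survive. The retained production list is a
  property of a specific corpus, not of the package.
* **XS typing.** Carbons are hydrophobic unless bonded to a heteroatom;
  nitrogen/oxygen donor flags require a bonded hydrogen; acceptor flags
  require an available lone pair (fewer than four connections, no positive
  formal charge). The full table (radii, flags, canonical pair types) ships
  as editable JSON (`censcore/data/xs_types.json`) so it is auditable.
* **Charges.** Protonation and charge assignment are not reimplemented;
  inputs are assumed preprocessed. Missing charges are zero-filled and
  flagged in metadata (charge-dependent terms then evaluate to zero), and
  the charge source (SDF property block, MOL2, PDBQT column) is recorded.

## Scaling

Each term is scaled by the corpus-wide maximum of its absolute raw value,
`t = t₀ / max_e |t₀,e|` (factor 1 for all-zero columns), the unique simple
rule that places every term in [−1, 1] without changing any sign. Factors
are fitted once over the full corpus (training and testing jointly) and
persisted with the model so inference reuses them; reapplication is
idempotent.

## Voxelization

Default grid: 48³ voxels at 0.5 Å, 28 channels (14 receptor + 14 ligand
XS-type groups; map in `censcore/data/channel_map.json`). Each heavy atom
deposits `exp(−2d²/r²)` out to one vdW radius, continued by the matching
quadratic reaching zero at 1.5 r (the gnina-style kernel; constants and an
overall amplitude gain configurable — tests assert only kernel-independent
properties). Atoms
whose support misses the grid are truncated silently and counted in a
coverage statistic. Augmentation draws a uniform random rotation about the
grid center and i.i.d. per-axis translations in [−2 Å, +2 Å] (an L∞ ball,
the usual grid-augmentation reading of "at most 2 Å").

## Network and training

The production backbone is a default2018-style trunk — avg-pool 2, conv 3³
(32) + ReLU, conv 1³ (32) + ReLU, pool, conv 3³ (64), conv 1³ (64), pool,
conv 3³ (128) — ending in two parallel fully connected heads of
`out_terms` outputs each, the vector analogue of the parent architecture's
two scalar heads; the weight vector is read from the first. With 28×48³
input and 144 terms this counts exactly 8,269,024 trainable parameters.
The backbone is configuration data, so desk-scale networks (e.g. one conv
unit on a 16³ grid) share the code path, and the network stack itself
(conv/pool/linear forward and backward, SGD with momentum and weight
decay, step decay) is implemented in numpy within the package.

Production training defaults: SGD lr 0.01, momentum 0.9, weight decay
1e-4, StepLR(step 80, gamma 0.1), smooth-L1 loss (transition beta = 1.0 —
unstated upstream, the common default), batch 25, 250 epochs, a fresh
augmentation transform per presentation, per-batch mean loss. Gradients
flow only through the weight head; terms are fixed inputs. Within-epoch
order is shuffled from the run seed; with augmentation off, grids are
cached and epochs are bitwise repeatable.

## Data curation

Affinity records (Kd/Ki/IC50 → pK = −log₁₀ molar, uniformly) are kept for
qualifiers "=" and "~", dropped for ">", and kept for "<" only at ≤ 1 μM
(boundary inclusive — the upstream convention for exactly 1 μM is
unstated; such entries are trained on as exact values since no censoring
model is given). Entries whose chains map to two or more sequence clusters
are removed. Clustered k-fold assignment places whole clusters into folds
greedily, largest cluster first into the currently smallest fold, ties
broken by a seeded shuffle; no cluster ever straddles folds.

## Interpretability

* **Per-atom attribution.** For each pairwise steric term, every matching
  pair's Gaussian value is divided by that term's scaling factor,
  multiplied by the complex-specific weight, and split half to each atom;
  atoms accumulate over pairs and terms. The per-atom sums conserve the
  summed weighted scaled steric contribution to 1e−9 relative. Display
  thresholds (suppress |v| ≤ 0.025) and clamping (±0.15) are presentation
  settings of the PDB writer, not of the attribution math.
* **Weight z-scores.** `|z| = |mean_target − mean_ref| / sd_ref` per term,
  with the *population* standard deviation (unstated upstream; recorded in
  the report). Zero-variance terms are flagged rather than scored.
* **Embedding.** t-SNE (scikit-learn, PCA init, seeded) to 2D, with an
  adjusted-Rand consistency score between k-means labels computed in the
  original weight space and on the embedded points.
* **Screening metrics.** AUROC via the tie-averaged rank statistic and
  enrichment factors EF_f = (active rate in the top ⌈fN⌉) / (overall
  active rate).

## Synthetic corpus

The generator emulates the data the pipeline consumes without any
downloads: receptor pockets as jittered spherical shells (radius 6 Å,
40–60 atoms) around 8–16-atom interior ligands, with two deterministic
contact motifs per complex (a donor/acceptor pair in hydrogen-bond range
and a hydrophobic pair in clash range) so that every term family is
exercised in nearly every complex. Atom charges are drawn independently of
pocket composition.

Each complex belongs to a *context* visible in the grid: the fraction of
hydrophobic carbons lining the pocket, drawn from [0.15, 0.35] (polar) or
[0.65, 0.85] (hydrophobic). Ground truth is `pK = w*_k · t + ε`,
`ε ~ N(0, 0.3²)` pK units by default, clipped to [0, 14]. The per-context
true weights agree on all terms except `electrostatic(i=1)`, which carries
−6 in polar and +6 in hydrophobic pockets. Because the charges (and hence
that term's values) are independent of context, the best single global
weight vector loses essentially the whole flipped contribution (held-out
Pearson ≈ 0.6–0.7 under the default conditions), while a context-aware
predictor approaches the noise ceiling (≈ 0.98); the weight magnitudes
were chosen once, from this variance budget, so that the two regimes are
well separated. Sequence-cluster ids are context-linked with jitter (five
clusters per context) so clustered splits are nontrivial, and qualifier
codes are sampled (≈ 80 % "=", plus "~", ">", "<") to exercise the filter.

What the generator does *not* emulate: real stereochemistry, bonded
topology (exported SDF files carry no bond block), force-field geometry,
pose errors, or the long-tailed term distributions of crystallographic
corpora. Passing the recovery tests therefore demonstrates the mechanism —
structure-conditioned weighting recoverable by the training loop — not
performance on real complexes.

## Desk-scale recovery experiment

The headline property test trains a tiny CEN (pool 2 → conv 3³(8) → ReLU →
pool 2 → two-bank affine head collapsed to one) on 16³ grids at 1.5 Å over
the 600-complex default corpus, affinity-filtered and split by clustered
3-fold (one fold held out). Training uses at most 300 optimizer steps,
batch 50, lr 0.02, momentum 0.9, weight decay 1e-4, augmentation off
(2 Å jitter on a 1.5 Å grid is disproportionately disruptive at this
scale, and caching unaugmented grids keeps the experiment fast), and a
grid input gain of 8: toy grids are far sparser than crystallographic
ones, and rescaling the input to O(1) conditions the conv pathway so the
step budget is spent learning the context signal rather than escaping a
tiny-activation regime. The problem sizes were chosen so the full
experiment runs in minutes on one CPU. Success criteria: held-out Pearson
≥ 0.9 for the network versus ≤ 0.75 for the best global least-squares
weight vector on the same split.

## Numerical choices and degenerate inputs

* Pair enumeration uses a KD-tree whose contract is exact agreement with
  the all-pairs double loop (tested to 1e−9 relative on randomized toys).
* Terms are order-stable and rigid-motion invariant (distance-only).
* All-zero scaling columns get factor 1; scaled vectors marked `scaled`
  are returned unchanged on rescaling.
* Pearson correlation raises on zero variance; AUROC raises on
  single-class input; the z-score report flags zero-variance terms.
* Empty complexes voxelize to zero grids; atoms off-grid are truncated and
  counted. Grids must be divisible by every pooling stride; violations
  raise at model construction.
* Unknown elements type as GenericMetal (logged in metadata) and do not
  enter the 325 canonical steric pairs.

## Known limitations

* The numpy network is CPU-only and single-threaded BLAS-bound; the
  production 48³ configuration is buildable and countable but not
  practical to train here.
* PDBQT parsing covers the charge column of well-formed files only.
* Bond perception for PDB receptors relies on rdkit proximity bonding;
  exotic residues may type conservatively (non-hydrophobic carbon).
* `num_tors_div`'s divisor (5) is a convention; change it in the registry
  if matching another implementation's convention matters.
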