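"""Train a desk-scale network and show context-dependent weight recovery.

The synthetic corpus hides a sign flip: in polar pockets the first
electrostatic term carries weight -6, in hydrophobic pockets +6. A single
global linear model cannot represent both; a context explanation network
reads the pocket composition from the voxel grid and flips the weight
accordingly. This script trains a tiny network for 300 optimizer steps and
compares its held-out correlation with an ordinary least-squares fit given
the same terms.

Runtime: a few minutes on one CPU.
"""

import numpy as np

import censcore as cs

spec = cs.SyntheticSpec(n_complexes=300, seed=0)
dataset = cs.generate_dataset(spec)

retained = {r.entry_id for r in cs.filter_affinities(dataset.records)}
entries = [c.entry_id for c in dataset.complexes if c.entry_id in retained]
plan = cs.clustered_kfold(
    entries, {e: dataset.cluster_table[e][0] for e in entries}, k=3, seed=0)
test_ids = set(plan.fold_entries(0))
cmap = {c.entry_id: c for c in dataset.complexes}


def examples(ids):
    return [cs.TrainingExample(cmap[e], dataset.scaled_vector(e),
                               dataset.pk_of_entry[e]) for e in ids]


train_ex = examples([e for e in entries if e not in test_ids])
test_ex = examples(sorted(test_ids))

model = cs.build_model(
    cs.ModelConfig.tiny(28, 16, len(dataset.registry)), rng_seed=0)
grid = cs.GridConfig(dim=16, resolution=1.5, gain=8.0)
config = cs.TrainingConfig(epochs=100, max_steps=300, batch_size=50,
                           learning_rate=0.02, augment=False, seed=0)
history = cs.train(model, train_ex, config, grid_config=grid)
print(f"trained {history.steps} steps; "
      f"loss {history.epoch_loss[0]:.3f} -> {history.epoch_loss[-1]:.3f}")

obs = np.array([ex.pk for ex in test_ex])
r_cen = cs.pearson(cs.evaluate(model, test_ex, grid_config=grid), obs)

X = np.stack([ex.scaled_terms.values for ex in train_ex])
y = np.array([ex.pk for ex in train_ex])
w_global, *_ = np.linalg.lstsq(X, y, rcond=None)
Xte = np.stack([ex.scaled_terms.values for ex in test_ex])
r_ols = cs.pearson(Xte @ w_global, obs)

print(f"held-out Pearson, context network:     {r_cen:.3f}")
print(f"held-out Pearson, global linear model: {r_ols:.3f}")
print("\nThe gap is the value of predicting weights from structure: the"
      "\nnetwork flips the electrostatic weight per pocket context, which"
      "\nno single weight vector can do.")
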