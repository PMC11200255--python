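"""Virtual-screening metrics: AUROC and enrichment factors.

Simulates a rescored ranked list (actives drawn from a higher score
distribution than inactives at a realistic 1:50 active-to-decoy ratio) and
evaluates it the way benchmark screens are judged: AUROC — the probability
a random active outranks a random inactive — and enrichment factors at the
top of the ranking.
"""

import numpy as np

import censcore as cs

rng = np.random.default_rng(0)
n_actives, n_decoys = 90, 4500
scores = np.concatenate([rng.normal(1.2, 1.0, n_actives),
                         rng.normal(0.0, 1.0, n_decoys)])
labels = np.concatenate([np.ones(n_actives, int), np.zeros(n_decoys, int)])

result = cs.screen_metrics(scores, labels, top_fractions=(0.01, 0.05, 0.10))
print(f"{n_actives} actives vs {n_decoys} decoys")
print(f"AUROC = {result.auroc:.4f}  (0.5 = random, 1.0 = perfect ranking)")
for frac, ef in result.enrichment.items():
    print(f"EF at top {frac:4.0%} = {ef:5.2f}  "
          f"(x-fold actives concentration vs the whole library)")
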