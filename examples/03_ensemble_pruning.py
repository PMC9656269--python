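"""Prune an expert pool with both selection criteria.

Builds a pool of decision-level experts (four informative, eight
chance-level), scores it with the mixed diversity measure
(rho + Q + disagreement against the pool, keep above-average) and the
greedy complementarity ranking, then sweeps accuracy against ensemble
size — the curve peaks before the chance experts enter.
"""

import numpy as np

from harfuse import (complementarity_rank, correctness_matrix, majority_vote,
                     mixed_diversity_select, sweep_ensemble_scale)

rng = np.random.default_rng(0)
classes = ["walking", "sitting", "lying"]
labels = rng.choice(classes, size=300)

decided = []
for _ in range(4):  # informative experts: correct 80% of the time
    pred = labels.copy()
    flip = rng.random(300) >= 0.8
    pred = np.where(flip, rng.choice(classes, size=300), pred)
    decided.append(pred)
for _ in range(8):  # chance-level experts
    decided.append(rng.choice(classes, size=300))
decided = np.stack(decided)

corr = correctness_matrix(decided, labels)
accs = corr.mean(axis=1)
print("individual accuracies:", np.round(accs, 2))

report = mixed_diversity_select(corr)
print(f"mixed diversity: eta range [{report.eta.min():.3f}, "
      f"{report.eta.max():.3f}], pool mean {report.av:.3f}")
print("selected by eta > mean:", report.selected)

ranking = complementarity_rank(corr, accs)
print("complementarity order:", ranking.order)

curve, best = sweep_ensemble_scale(
    ranking.order,
    lambda ids: majority_vote(decided[list(ids)], classes),
    labels,
)
print("accuracy vs ensemble size:", np.round(curve, 3))
print(f"best ensemble size: {best} (chance experts would only dilute the vote)")
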