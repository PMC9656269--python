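"""Ensemble pruning: mixed diversity measure and complementarity measure.

Both criteria operate on a binary *correctness matrix* (experts x
evaluation samples, 1 = correct decision), typically computed on a
held-out validation split.

The mixed diversity measure scores every classifier by the average of
three pairwise statistics against the whole pool — correlation
coefficient rho, Yule's Q, and the disagreement rate — and keeps the
classifiers whose score exceeds the pool mean.  The complementarity
measure grows a sub-ensemble greedily from the most accurate
classifier, at each step adding the candidate that is correct on the
most samples the current sub-ensemble gets wrong.

An accuracy-versus-ensemble-size sweep over a ranking picks the final
sub-ensemble size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ContractError

__all__ = [
    "PairwiseCounts",
    "DiversityReport",
    "ComplementarityRanking",
    "correctness_matrix",
    "pairwise_counts",
    "rho",
    "q_stat",
    "disagreement",
    "mixed_diversity_select",
    "complementarity_rank",
    "sweep_ensemble_scale",
]


@dataclass(frozen=True)
class PairwiseCounts:
    """Joint-correctness counts for an ordered classifier pair (C_i, C_j).

    n11: both correct; n10: only C_i correct; n01: only C_j correct;
    n00: both wrong.  They sum to the number of evaluation samples.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass
class DiversityReport:
    rho: np.ndarray          # (n, n) pairwise correlation coefficients
    q: np.ndarray            # (n, n) pairwise Q statistics
    dis: np.ndarray          # (n, n) pairwise disagreement rates
    eta: np.ndarray          # (n,) per-classifier mixed scores
    av: float                # pool mean of eta
    selected: list[int]      # ids with eta > av, descending eta
    transform: str = "literal"

    def to_dict(self) -> dict:
        return {
            "eta": self.eta.tolist(),
            "av": self.av,
            "selected": self.selected,
            "transform": self.transform,
        }


@dataclass
class ComplementarityRanking:
    order: list[int]               # permutation of the pool, best-first
    step_scores: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"order": self.order, "step_scores": self.step_scores}


def correctness_matrix(
    decided_labels: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """1/0 matrix (experts x samples): did each expert decide correctly?"""
    decided_labels = np.asarray(decided_labels)
    labels = np.asarray(labels)
    if decided_labels.ndim != 2 or decided_labels.shape[1] != len(labels):
        raise ContractError("decided_labels must be (experts, len(labels))")
    return (decided_labels == labels[None, :]).astype(int)


def pairwise_counts(c_i: np.ndarray, c_j: np.ndarray) -> PairwiseCounts:
    c_i = np.asarray(c_i).astype(bool)
    c_j = np.asarray(c_j).astype(bool)
    if c_i.shape != c_j.shape or c_i.ndim != 1 or len(c_i) < 1:
        raise ContractError("correctness vectors must be equal-length 1-D")
    return PairwiseCounts(
        n11=int(np.sum(c_i & c_j)),
        n10=int(np.sum(c_i & ~c_j)),
        n01=int(np.sum(~c_i & c_j)),
        n00=int(np.sum(~c_i & ~c_j)),
    )


def rho(counts: PairwiseCounts) -> float:
    """Pairwise correlation coefficient; 0 when any marginal factor is 0."""
    a, b, c, d = counts.n11, counts.n10, counts.n01, counts.n00
    denom2 = (a + b) * (c + d) * (a + c) * (b + d)
    if denom2 == 0:
        return 0.0
    return (a * d - b * c) / np.sqrt(denom2)


def q_stat(counts: PairwiseCounts) -> float:
    """Yule's Q statistic; 0 when n11*n00 + n10*n01 = 0."""
    a, b, c, d = counts.n11, counts.n10, counts.n01, counts.n00
    denom = a * d + b * c
    if denom == 0:
        return 0.0
    return (a * d - b * c) / denom


def disagreement(counts: PairwiseCounts) -> float:
    """Fraction of samples on which exactly one of the pair is correct."""
    if counts.total == 0:
        raise ContractError("empty counts")
    return (counts.n10 + counts.n01) / counts.total


def _pair_matrices(correctness: np.ndarray):
    n = correctness.shape[0]
    R = np.zeros((n, n))
    Q = np.zeros((n, n))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            cnt = pairwise_counts(correctness[i], correctness[j])
            R[i, j] = rho(cnt)
            Q[i, j] = q_stat(cnt)
            D[i, j] = disagreement(cnt)
    return R, Q, D


def mixed_diversity_select(
    correctness: np.ndarray, transform: str = "literal"
) -> DiversityReport:
    """Select classifiers whose mixed score exceeds the pool average.

    ``eta_i`` averages the pairwise statistic over *all* j (self pair
    included — its contribution is a constant shift that cannot change
    which classifiers clear the pool mean).  ``transform="literal"``
    sums rho + Q + Dis as printed; ``transform="normalized"`` rescales
    each statistic so that larger uniformly means more diverse:
    ((1 - rho)/2 + (1 - Q)/2 + Dis) / 3.

    Ties on eta break toward the lower id; if no classifier strictly
    exceeds the mean (all eta equal), the full pool is returned in id
    order.
    """
    correctness = np.asarray(correctness)
    n = correctness.shape[0]
    if n < 2:
        raise ContractError("mixed diversity needs >= 2 classifiers")
    if transform not in ("literal", "normalized"):
        raise ContractError(f"unknown diversity transform {transform!r}")
    R, Q, D = _pair_matrices(correctness)
    if transform == "literal":
        pair = R + Q + D
    else:
        pair = ((1 - R) / 2 + (1 - Q) / 2 + D) / 3
    eta = pair.mean(axis=1)
    av = float(eta.mean())
    selected = [i for i in range(n) if eta[i] > av]
    selected.sort(key=lambda i: (-eta[i], i))
    if not selected:
        selected = list(range(n))
    return DiversityReport(
        rho=R, q=Q, dis=D, eta=eta, av=av, selected=selected,
        transform=transform,
    )


def _ensemble_correct(
    sub: Sequence[int], correctness: np.ndarray, accuracies: np.ndarray
) -> np.ndarray:
    """Per-sample correctness of the sub-ensemble's majority decision.

    A strict majority of correct members decides correctly (they all
    vote the true label); a strict majority of wrong members is scored
    wrong; an exact split defers to the most accurate member (ties on
    accuracy break toward the lower id).
    """
    sub_c = correctness[list(sub)]
    n_corr = sub_c.sum(axis=0)
    u = len(sub)
    best = min(sub, key=lambda i: (-accuracies[i], i))
    out = np.where(2 * n_corr > u, 1, 0)
    tie = 2 * n_corr == u
    out = np.where(tie, correctness[best], out)
    return out


def complementarity_rank(
    correctness: np.ndarray, accuracies: Sequence[float]
) -> ComplementarityRanking:
    """Greedy forward ranking by complementarity with the sub-ensemble.

    Start from the individually most accurate classifier (tie: lower
    id).  At each step add the candidate correct on the most samples
    the current sub-ensemble decides wrongly; ties break toward higher
    individual accuracy, then lower id.  The returned order is a
    permutation of the whole pool; ``step_scores[0]`` is the seed
    classifier's accuracy-count and subsequent entries are the winning
    complementarity counts.
    """
    correctness = np.asarray(correctness)
    accuracies = np.asarray(accuracies, dtype=float)
    m = correctness.shape[0]
    if m < 1:
        raise ContractError("empty pool")
    if len(accuracies) != m:
        raise ContractError("one accuracy per classifier required")
    first = min(range(m), key=lambda i: (-accuracies[i], i))
    order = [first]
    scores = [float(correctness[first].sum())]
    while len(order) < m:
        ens_wrong = 1 - _ensemble_correct(order, correctness, accuracies)
        candidates = [k for k in range(m) if k not in order]
        step = {k: int(np.sum(correctness[k] * ens_wrong)) for k in candidates}
        chosen = min(candidates, key=lambda k: (-step[k], -accuracies[k], k))
        order.append(chosen)
        scores.append(float(step[chosen]))
    return ComplementarityRanking(order=order, step_scores=scores)


def sweep_ensemble_scale(
    ranking: Sequence[int],
    fuse: Callable[[Sequence[int]], np.ndarray],
    y_val: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Accuracy-versus-size curve over ranking prefixes.

    ``fuse(ids)`` must return fused predicted labels on the validation
    samples.  Returns ``(curve, best_size)`` where ``curve[u-1]`` is the
    accuracy of the first ``u`` classifiers and ``best_size`` is the
    argmax (ties toward the smallest size).
    """
    ranking = list(ranking)
    if not ranking:
        raise ContractError("empty ranking")
    y_val = np.asarray(y_val)
    curve = np.empty(len(ranking))
    for u in range(1, len(ranking) + 1):
        pred = np.asarray(fuse(ranking[:u]))
        curve[u - 1] = float(np.mean(pred == y_val))
    best_size = int(np.argmax(curve)) + 1  # first maximum = smallest size
    return curve, best_size
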