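"""Group-decision-making fusion with GA subjective weights and
deviation-driven objective weights.

Each selected base classifier is an *expert* whose per-sample decision
vector U_k lies on the class simplex (one-hot of its decided label in
crisp mode, a softmax of its scores in soft mode).  The group decision
for a sample is the weighted aggregate

    G = sum_k lambda_k U_k,        sum_k lambda_k = 1,

and the fused label is argmax G (ties to the lowest class index,
globally).  The expert weight combines two parts,

    lambda_k = phi * alpha_k + (1 - phi) * beta_k,

where alpha is a *subjective* weight optimized by a binary-coded
genetic algorithm against training accuracy, and beta is an
*objective* weight built on the basis of the subjective weights:
initialized at alpha and adjusted from the deviation between each
expert's decisions and the group decision.  Experts below the mean
deviation gain Delta_lambda / c, experts above it lose
Delta_lambda / d (c, d = counts on each side), which conserves the
simplex.  The adjustment is a small correction — one pass by default;
iterating it to its absorbing state hands all objective weight to the
most consensual expert and collapses the ensemble to a single
classifier, defeating the purpose of fusion (the epoch count stays
configurable for studying that regime).  Majority-vote,
accuracy-weighted-average and GA-only fusers are provided as
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import softmax

from .errors import ConfigurationError, ContractError
from .elm import ELMModel, predict_scores
from .features import FeatureTable, Normalizer, apply_normalizer

__all__ = [
    "DecisionProfile",
    "ExpertWeights",
    "GAConfig",
    "EnsembleModel",
    "make_profile",
    "decode_chromosome",
    "ga_fitness",
    "ga_optimize",
    "group_decision",
    "group_decide_batch",
    "deviations",
    "update_objective_weights",
    "combine_weights",
    "fit_gdm_weights",
    "fit_gdm_ensemble",
    "predict_ensemble",
    "majority_vote",
    "accuracy_weights",
    "baseline_fusers",
]


@dataclass
class DecisionProfile:
    """Per-expert decision vectors U (experts x samples x classes)."""

    U: np.ndarray
    class_order: list

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if self.U.ndim != 3 or self.U.shape[2] != len(self.class_order):
            raise ContractError("U must be (experts, samples, classes)")

    @property
    def n_experts(self) -> int:
        return self.U.shape[0]

    @property
    def n_samples(self) -> int:
        return self.U.shape[1]

    @property
    def decided_indices(self) -> np.ndarray:
        """Argmax class index per expert/sample (ties to lowest index)."""
        return np.argmax(self.U, axis=2)

    @property
    def decided_labels(self) -> np.ndarray:
        co = np.asarray(self.class_order, dtype=object)
        return co[self.decided_indices]

    def subset(self, expert_ids: Sequence[int]) -> "DecisionProfile":
        return DecisionProfile(U=self.U[list(expert_ids)],
                               class_order=list(self.class_order))


@dataclass
class ExpertWeights:
    """Subjective alpha, objective beta, combined lambda; all on the simplex."""

    alpha: np.ndarray
    beta: np.ndarray
    lam: np.ndarray
    phi: float = 0.5
    delta_lambda: float = 0.05

    def validate(self, atol: float = 1e-9) -> None:
        for name in ("alpha", "beta", "lam"):
            w = getattr(self, name)
            if np.any(w < -atol) or abs(float(w.sum()) - 1.0) > atol:
                raise ContractError(f"{name} left the probability simplex")


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters for the subjective weights."""

    population: int = 30
    generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    bits_per_gene: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ConfigurationError("population must be >= 2")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        if not (0 <= self.crossover_prob <= 1):
            raise ConfigurationError("crossover_prob must be in [0, 1]")
        if not (0 <= self.mutation_prob <= 1):
            raise ConfigurationError("mutation_prob must be in [0, 1]")
        if self.bits_per_gene < 1:
            raise ConfigurationError("bits_per_gene must be >= 1")


def make_profile(
    score_matrices: Sequence[np.ndarray],
    class_order: Sequence,
    mode: str = "crisp",
) -> DecisionProfile:
    """Build expert decision vectors from raw score matrices.

    crisp: one-hot of each expert's argmax (ties to lowest class
    index); soft: row-wise softmax of the scores.
    """
    if mode not in ("crisp", "soft"):
        raise ConfigurationError(f"unknown decision mode {mode!r}")
    mats = [np.asarray(s, dtype=float) for s in score_matrices]
    if not mats:
        raise ContractError("no expert score matrices")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats) or shape[1] != len(class_order):
        raise ContractError("expert score matrices disagree in shape")
    S = np.stack(mats)  # (m, N, c)
    if mode == "crisp":
        idx = np.argmax(S, axis=2)
        U = np.zeros_like(S)
        m, n, _ = S.shape
        U[np.arange(m)[:, None], np.arange(n)[None, :], idx] = 1.0
    else:
        U = softmax(S, axis=2)
    return DecisionProfile(U=U, class_order=list(class_order))


def decode_chromosome(genes: np.ndarray) -> np.ndarray:
    """Binary genes (m, bits) -> weights x_i / sum x_i (MSB first)."""
    genes = np.asarray(genes)
    if genes.ndim != 2:
        raise ContractError("genes must be (m, bits)")
    powers = 2 ** np.arange(genes.shape[1] - 1, -1, -1)
    x = genes @ powers
    total = x.sum()
    if total == 0:
        raise ContractError("all-zero chromosome: repair precondition violated")
    return x / total


def group_decision(lam: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Aggregate one sample's expert vectors: G = sum_k lam_k U_k."""
    lam = np.asarray(lam, dtype=float)
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or U.shape[0] != len(lam):
        raise ContractError("U must be (experts, classes) matching lam")
    return lam @ U


def group_decide_batch(lam: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Group vectors for a batch: (m, N, c) -> (N, c)."""
    lam = np.asarray(lam, dtype=float)
    U = np.asarray(U, dtype=float)
    if U.ndim != 3 or U.shape[0] != len(lam):
        raise ContractError("U must be (experts, samples, classes)")
    return np.tensordot(lam, U, axes=(0, 0))


def ga_fitness(
    W: np.ndarray, profile: DecisionProfile, label_indices: np.ndarray
) -> float:
    """Reciprocal-of-errors fitness: 1 / (Y - #correct + 1e-6).

    Strictly increasing in the number of correctly fused samples; the
    epsilon guard keeps a perfectly fused batch finite.
    """
    G = group_decide_batch(W, profile.U)
    pred = np.argmax(G, axis=1)
    correct = int(np.sum(pred == label_indices))
    return 1.0 / (len(label_indices) - correct + 1e-6)


def _repair(chrom: np.ndarray, rng: np.random.Generator) -> None:
    if chrom.sum() == 0:
        chrom[rng.integers(chrom.shape[0]), rng.integers(chrom.shape[1])] = 1


def ga_optimize(
    profile: DecisionProfile,
    labels: np.ndarray,
    cfg: GAConfig | None = None,
) -> np.ndarray:
    """GA search for the subjective weight vector alpha.

    Binary chromosomes of ``m * bits_per_gene`` bits (one gene per
    expert); roulette-wheel parent selection; single-point crossover at
    a uniform random cut of the flattened bit string; double mutation —
    with probability ``mutation_prob`` an offspring either flips every
    bit of one random gene or flips one random bit, chosen uniformly;
    elitism of one keeps the generation best.  Returns the decoded
    best-ever chromosome; deterministic for identical inputs and seed.
    """
    cfg = cfg or GAConfig()
    labels = np.asarray(labels)
    m = profile.n_experts
    if m == 1:
        return np.array([1.0])
    y_idx = _label_indices(labels, profile.class_order)
    b = cfg.bits_per_gene
    rng = np.random.default_rng(cfg.seed)
    pop = rng.integers(0, 2, size=(cfg.population, m, b))
    for chrom in pop:
        _repair(chrom, rng)
    best_genes, best_fit = None, -np.inf

    def evaluate(p):
        fits = np.empty(len(p))
        for i, chrom in enumerate(p):
            fits[i] = ga_fitness(decode_chromosome(chrom), profile, y_idx)
        return fits

    for _ in range(cfg.generations):
        fits = evaluate(pop)
        gi = int(np.argmax(fits))
        if fits[gi] > best_fit:
            best_fit, best_genes = float(fits[gi]), pop[gi].copy()
        elite = pop[gi].copy()
        probs = fits / fits.sum()
        children = [elite]
        while len(children) < cfg.population:
            pa, pb = rng.choice(cfg.population, size=2, p=probs)
            c1, c2 = pop[pa].reshape(-1).copy(), pop[pb].reshape(-1).copy()
            if rng.random() < cfg.crossover_prob and m * b > 1:
                cut = int(rng.integers(1, m * b))
                c1[cut:], c2[cut:] = c2[cut:].copy(), c1[cut:].copy()
            for child in (c1, c2):
                if len(children) >= cfg.population:
                    break
                child = child.reshape(m, b)
                if rng.random() < cfg.mutation_prob:
                    if rng.random() < 0.5:  # overall gene mutation
                        g = int(rng.integers(m))
                        child[g] = 1 - child[g]
                    else:  # single binary bit mutation
                        flat = child.reshape(-1)
                        i = int(rng.integers(flat.shape[0]))
                        flat[i] = 1 - flat[i]
                _repair(child, rng)
                children.append(child)
        pop = np.stack(children)
    # final generation still counts toward best-ever
    fits = evaluate(pop)
    gi = int(np.argmax(fits))
    if fits[gi] > best_fit:
        best_genes = pop[gi].copy()
    return decode_chromosome(best_genes)


def deviations(U: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Mean squared class-vector deviation of each expert from the group.

    Per sample, r_k = sum_j (u_kj - g_j)^2 over classes; returned per
    expert as the mean over the batch.
    """
    U = np.asarray(U, dtype=float)
    G = np.asarray(G, dtype=float)
    if U.ndim != 3 or U.shape[1:] != G.shape:
        raise ContractError("U (m, N, c) must match G (N, c)")
    return ((U - G[None]) ** 2).sum(axis=2).mean(axis=1)


def update_objective_weights(
    beta: np.ndarray, r: np.ndarray, delta_lambda: float = 0.05
) -> np.ndarray:
    """Shift weight toward experts whose deviation is below the mean.

    Experts with r_k below the mean deviation gain delta_lambda / c;
    those above lose delta_lambda / d (c, d = the respective counts),
    so the total is conserved before the non-negativity clip; the
    result is re-normalized to the simplex.  If every expert sits on
    one side (c = 0 or d = 0) the weights are unchanged.
    """
    beta = np.asarray(beta, dtype=float)
    r = np.asarray(r, dtype=float)
    if beta.shape != r.shape:
        raise ContractError("beta and r must have matching shape")
    if delta_lambda <= 0:
        raise ConfigurationError("delta_lambda must be > 0")
    r_bar = float(r.mean())
    below = r < r_bar
    above = r > r_bar
    c, d = int(below.sum()), int(above.sum())
    if c == 0 or d == 0:
        return beta.copy()
    out = beta.copy()
    out[below] += delta_lambda / c
    out[above] -= delta_lambda / d
    out = np.clip(out, 0.0, None)
    return out / out.sum()


def combine_weights(alpha: np.ndarray, beta: np.ndarray, phi: float) -> np.ndarray:
    """lambda_k = phi * alpha_k + (1 - phi) * beta_k."""
    if not (0 <= phi <= 1):
        raise ConfigurationError("phi must be in [0, 1]")
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if alpha.shape != beta.shape:
        raise ContractError("alpha and beta must have matching shape")
    return phi * alpha + (1 - phi) * beta


def _label_indices(labels: np.ndarray, class_order: Sequence) -> np.ndarray:
    idx = {c: i for i, c in enumerate(class_order)}
    try:
        return np.asarray([idx[v] for v in labels])
    except KeyError as e:  # pragma: no cover - defensive
        raise ContractError(f"label {e.args[0]!r} not in class_order") from e


def fit_gdm_weights(
    profile: DecisionProfile,
    labels: np.ndarray,
    phi: float = 0.5,
    delta_lambda: float = 0.05,
    epochs: int = 1,
    tol: float = 1e-4,
    ga_config: GAConfig | None = None,
) -> ExpertWeights:
    """Run the full GDM weight schedule on a training batch.

    alpha from the GA; beta starts at alpha (the objective weight is a
    deviation-driven correction of the subjective weight, not an
    independent prior); then per epoch: recompose lambda, take the
    group decision over the batch, measure deviations, update beta;
    stop early once lambda moves less than ``tol`` in any coordinate.
    With ``phi = 1`` the objective part is inert and the result equals
    the GA-only weights exactly.  The simplex constraint is asserted
    every epoch.
    """
    m = profile.n_experts
    if m < 1:
        raise ContractError("empty expert set")
    alpha = ga_optimize(profile, labels, ga_config)
    beta = alpha.copy()
    lam = combine_weights(alpha, beta, phi)
    for _ in range(max(1, epochs)):
        G = group_decide_batch(lam, profile.U)
        r = deviations(profile.U, G)
        beta = update_objective_weights(beta, r, delta_lambda)
        new_lam = combine_weights(alpha, beta, phi)
        weights = ExpertWeights(alpha=alpha, beta=beta, lam=new_lam,
                                phi=phi, delta_lambda=delta_lambda)
        weights.validate()
        moved = float(np.max(np.abs(new_lam - lam)))
        lam = new_lam
        if moved < tol:
            break
    return ExpertWeights(alpha=alpha, beta=beta, lam=lam,
                         phi=phi, delta_lambda=delta_lambda)


@dataclass
class EnsembleModel:
    """Fitted selective ensemble: experts, weights, preprocessing state."""

    expert_ids: list[str]
    models: dict[str, ELMModel]
    weights: ExpertWeights
    class_order: list
    normalizer: Normalizer | None = None
    decision_mode: str = "crisp"
    config: dict = field(default_factory=dict)


def fit_gdm_ensemble(
    models: dict[str, ELMModel],
    train_table: FeatureTable,
    expert_ids: Sequence[str] | None = None,
    normalizer: Normalizer | None = None,
    decision_mode: str = "crisp",
    phi: float = 0.5,
    delta_lambda: float = 0.05,
    epochs: int = 1,
    tol: float = 1e-4,
    ga_config: GAConfig | None = None,
) -> EnsembleModel:
    """Fit the GDM fusion weights over trained per-group experts.

    ``train_table`` holds *raw* features; if ``normalizer`` is given it
    is applied before scoring (and frozen into the model).
    """
    ids = list(expert_ids) if expert_ids is not None else list(models)
    if not ids:
        raise ContractError("empty expert set")
    table = apply_normalizer(normalizer, train_table) if normalizer else train_table
    class_order = models[ids[0]].class_order
    scores = [predict_scores(models[g], table.group_matrix(g)) for g in ids]
    profile = make_profile(scores, class_order, mode=decision_mode)
    if len(ids) == 1:
        weights = ExpertWeights(
            alpha=np.array([1.0]), beta=np.array([1.0]), lam=np.array([1.0]),
            phi=phi, delta_lambda=delta_lambda,
        )
    else:
        weights = fit_gdm_weights(
            profile, table.labels, phi=phi, delta_lambda=delta_lambda,
            epochs=epochs, tol=tol, ga_config=ga_config,
        )
    return EnsembleModel(
        expert_ids=ids,
        models={g: models[g] for g in ids},
        weights=weights,
        class_order=list(class_order),
        normalizer=normalizer,
        decision_mode=decision_mode,
        config={
            "phi": phi, "delta_lambda": delta_lambda, "epochs": epochs,
            "tol": tol,
            "ga": vars(ga_config) if ga_config else vars(GAConfig()),
        },
    )


def predict_ensemble(model: EnsembleModel, table: FeatureTable) -> np.ndarray:
    """Fused labels for raw feature rows; weights are frozen at test time."""
    t = apply_normalizer(model.normalizer, table) if model.normalizer else table
    missing = [g for g in model.expert_ids if g not in t.groups]
    if missing:
        raise ContractError(f"feature table lacks groups {missing}")
    scores = [predict_scores(model.models[g], t.group_matrix(g))
              for g in model.expert_ids]
    profile = make_profile(scores, model.class_order, mode=model.decision_mode)
    G = group_decide_batch(model.weights.lam, profile.U)
    co = np.asarray(model.class_order, dtype=object)
    return co[np.argmax(G, axis=1)]


def majority_vote(decided_labels: np.ndarray, class_order: Sequence) -> np.ndarray:
    """Plurality over expert decided labels; ties to the lowest class index."""
    decided_labels = np.asarray(decided_labels)
    if decided_labels.ndim != 2:
        raise ContractError("decided_labels must be (experts, samples)")
    co = list(class_order)
    counts = np.zeros((decided_labels.shape[1], len(co)), dtype=int)
    for ci, c in enumerate(co):
        counts[:, ci] = np.sum(decided_labels == c, axis=0)
    out = np.asarray(co, dtype=object)[np.argmax(counts, axis=1)]
    return out


def accuracy_weights(correctness: np.ndarray) -> np.ndarray:
    """Weighted-average baseline weights: lambda_k proportional to accuracy."""
    correctness = np.asarray(correctness, dtype=float)
    acc = correctness.mean(axis=1)
    total = acc.sum()
    if total == 0:
        return np.full(len(acc), 1.0 / len(acc))
    return acc / total


def baseline_fusers(
    profile: DecisionProfile,
    labels_train: np.ndarray,
    ga_config: GAConfig | None = None,
) -> dict[str, np.ndarray]:
    """Weight vectors of the comparison fusers fitted on a training profile.

    mv: uniform weights over crisp votes (applied to decided labels);
    wa: weights proportional to each expert's training accuracy;
    ga: GA-optimized weights with no dynamic update.
    """
    labels_train = np.asarray(labels_train)
    m = profile.n_experts
    correct = (profile.decided_labels == labels_train[None, :]).astype(float)
    return {
        "mv": np.full(m, 1.0 / m),
        "wa": accuracy_weights(correct),
        "ga": ga_optimize(profile, labels_train, ga_config),
    }
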