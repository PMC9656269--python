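"""End-to-end orchestration: clean, segment, featurize, split, train
the expert pool, prune, size the ensemble, fuse, evaluate.

A single ``seed`` fans out deterministically to every stage (data
split, per-expert ELM initialization, GA search), so two runs with the
same configuration are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import gdm
from .elm import predict_labels, predict_scores, train_elm
from .errors import ConfigurationError
from .evaluate import confusion, metrics
from .features import (FeatureTable, apply_normalizer, extract_features,
                       fit_normalizer)
from .preprocess import SensorStream, concat_windows, fill_missing, \
    remove_outliers, segment
from .pruning import (complementarity_rank, correctness_matrix,
                      mixed_diversity_select, sweep_ensemble_scale)
from .synthdata import SynthConfig, complementary_scenario_config, \
    generate_dataset

__all__ = [
    "RunConfig",
    "derive_seeds",
    "stratified_split",
    "PipelineState",
    "prepare",
    "fit_and_evaluate",
    "run_experiment",
    "compare_fusers",
    "run_complementary_benchmark",
]

FUSION_METHODS = ("gdm", "ga", "wa", "mv")
PRUNING_METHODS = ("mixed_diversity", "complementarity")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the defaults the method uses."""

    window_seconds: float = 0.5
    overlap: float = 0.5
    hampel_half_width: int | None = None   # default: half a second of samples
    hampel_sigmas: float = 3.0
    elm_hidden: int = 100
    elm_ridge: float = 1e-6
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    pruning: str = "mixed_diversity"
    diversity_transform: str = "literal"
    ensemble_size: int | None = None       # None: pick by validation sweep
    fusion: str = "gdm"
    decision_mode: str = "crisp"
    phi: float = 0.5
    delta_lambda: float = 0.05
    gdm_epochs: int = 1
    gdm_tol: float = 1e-4
    ga: gdm.GAConfig = field(default_factory=gdm.GAConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fusion not in FUSION_METHODS:
            raise ConfigurationError(f"fusion must be one of {FUSION_METHODS}")
        if self.pruning not in PRUNING_METHODS:
            raise ConfigurationError(f"pruning must be one of {PRUNING_METHODS}")
        fr = self.split
        if len(fr) != 3 or any(f <= 0 for f in fr) or abs(sum(fr) - 1) > 1e-9:
            raise ConfigurationError(
                "split fractions must be three positives summing to 1"
            )


def derive_seeds(global_seed: int, names: Sequence[str]) -> dict[str, int]:
    """Deterministic per-stage seeds below 2**31 from one global seed."""
    ss = np.random.SeedSequence(global_seed)
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        for n, c in zip(names, children)
    }


def stratified_split(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled per-class train/val/test index split."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        train.append(idx[:n_train])
        val.append(idx[n_train:n_train + n_val])
        test.append(idx[n_train + n_val:])
    return (np.sort(np.concatenate(train)),
            np.sort(np.concatenate(val)),
            np.sort(np.concatenate(test)))


@dataclass
class PipelineState:
    """Everything shared by the fusers: data splits, experts, pruning."""

    cfg: RunConfig
    seeds: dict[str, int]
    group_ids: list[str]
    train: FeatureTable
    val: FeatureTable
    test: FeatureTable
    normalizer: object
    models: dict
    val_accuracies: np.ndarray
    pruning_report: object
    ranking: list[int]
    curve: np.ndarray
    ensemble_size: int
    selected_ids: list[str]
    class_order: list


def _clean_and_window(streams: Sequence[SensorStream], cfg: RunConfig):
    windows = []
    for s in streams:
        s = fill_missing(s)
        s = remove_outliers(s, half_width=cfg.hampel_half_width,
                            n_sigmas=cfg.hampel_sigmas)
        windows.append(segment(s, cfg.window_seconds, cfg.overlap))
    return concat_windows(windows)


def prepare(streams: Sequence[SensorStream], cfg: RunConfig) -> PipelineState:
    """Run every stage up to (and including) ensemble-size selection."""
    seeds = derive_seeds(cfg.seed, ["split", "elm", "ga"])
    ws = _clean_and_window(streams, cfg)
    raw = extract_features(ws)
    tr_idx, va_idx, te_idx = stratified_split(raw.labels, cfg.split,
                                              seeds["split"])
    train_raw = raw.subset(tr_idx)
    normalizer = fit_normalizer(train_raw)
    train = apply_normalizer(normalizer, train_raw)
    val = apply_normalizer(normalizer, raw.subset(va_idx))
    test = apply_normalizer(normalizer, raw.subset(te_idx))

    group_ids = list(train.groups)
    elm_seeds = derive_seeds(seeds["elm"], group_ids)
    models = {
        g: train_elm(train.group_matrix(g), train.labels,
                     hidden=cfg.elm_hidden, ridge=cfg.elm_ridge,
                     seed=elm_seeds[g], group_id=g)
        for g in group_ids
    }
    class_order = models[group_ids[0]].class_order

    val_pred = np.stack([predict_labels(models[g], val.group_matrix(g))
                         for g in group_ids])
    corr = correctness_matrix(val_pred, val.labels)
    accs = corr.mean(axis=1)

    if cfg.pruning == "mixed_diversity":
        report = mixed_diversity_select(corr, transform=cfg.diversity_transform)
        ranking = report.selected
    else:
        report = complementarity_rank(corr, accs)
        ranking = report.order

    def fuse(ids):
        return gdm.majority_vote(val_pred[list(ids)], class_order)

    curve, best_size = sweep_ensemble_scale(ranking, fuse, val.labels)
    size = cfg.ensemble_size or best_size
    size = max(1, min(size, len(ranking)))
    return PipelineState(
        cfg=cfg, seeds=seeds, group_ids=group_ids,
        train=train, val=val, test=test, normalizer=normalizer,
        models=models, val_accuracies=accs, pruning_report=report,
        ranking=list(ranking), curve=curve, ensemble_size=size,
        selected_ids=[group_ids[i] for i in ranking[:size]],
        class_order=list(class_order),
    )


def _fixed_weight_model(state: PipelineState, lam, fusion: str):
    m = len(state.selected_ids)
    w = gdm.ExpertWeights(alpha=np.asarray(lam, dtype=float),
                          beta=np.full(m, 1.0 / m),
                          lam=np.asarray(lam, dtype=float),
                          phi=1.0, delta_lambda=state.cfg.delta_lambda)
    return gdm.EnsembleModel(
        expert_ids=list(state.selected_ids),
        models={g: state.models[g] for g in state.selected_ids},
        weights=w, class_order=list(state.class_order),
        normalizer=None,  # state tables are already normalized
        decision_mode=state.cfg.decision_mode,
        config={"fusion": fusion},
    )


def fit_and_evaluate(state: PipelineState, fusion: str | None = None) -> dict:
    """Fit the chosen fuser on the training split, evaluate on the test split."""
    cfg = state.cfg
    fusion = fusion or cfg.fusion
    if fusion not in FUSION_METHODS:
        raise ConfigurationError(f"fusion must be one of {FUSION_METHODS}")
    ga_cfg = replace(cfg.ga, seed=state.seeds["ga"])
    ids = state.selected_ids
    if fusion == "gdm":
        model = gdm.fit_gdm_ensemble(
            state.models, state.train, expert_ids=ids,
            normalizer=None, decision_mode=cfg.decision_mode,
            phi=cfg.phi, delta_lambda=cfg.delta_lambda,
            epochs=cfg.gdm_epochs, tol=cfg.gdm_tol, ga_config=ga_cfg,
        )
    else:
        scores = [predict_scores(state.models[g], state.train.group_matrix(g))
                  for g in ids]
        profile = gdm.make_profile(scores, state.class_order,
                                   mode=cfg.decision_mode)
        lam = gdm.baseline_fusers(profile, state.train.labels, ga_cfg)[fusion]
        model = _fixed_weight_model(state, lam, fusion)
    pred = gdm.predict_ensemble(model, state.test)
    cm = confusion(state.test.labels, pred, state.class_order)
    rep = metrics(cm)
    return {
        "fusion": fusion,
        "model": model,
        "predictions": pred,
        "confusion": cm,
        "metrics": rep,
        "test_accuracy": rep.accuracy,
        "macro_f1": rep.macro_f1,
    }


def run_experiment(streams: Sequence[SensorStream], cfg: RunConfig) -> dict:
    """Full pipeline for one fuser; returns the state plus evaluation."""
    state = prepare(streams, cfg)
    result = fit_and_evaluate(state)
    result["state"] = state
    return result


def compare_fusers(streams: Sequence[SensorStream], cfg: RunConfig) -> dict:
    """All four fusers on identical splits, experts and selection."""
    state = prepare(streams, cfg)
    results = {f: fit_and_evaluate(state, f) for f in FUSION_METHODS}
    return {"state": state, "results": results}


def run_complementary_benchmark(
    seed: int = 0,
    n_train: int = 600,
    n_test: int = 300,
    cfg: RunConfig | None = None,
) -> dict:
    """The complementary-experts benchmark: fusers vs individual experts.

    Four positions, three activities, each position blind to one class
    pair; 600 training and 300 test windows (stratified).  No pruning:
    all four experts enter the fusion, since the scenario is about the
    value of fusing complementary sensors.  Returns individual expert
    test accuracies and the test accuracy of each fuser.
    """
    cfg = cfg or RunConfig()
    seeds = derive_seeds(seed, ["data", "split", "elm", "ga"])
    synth = complementary_scenario_config(seed=seeds["data"])
    streams = generate_dataset(synth)
    ws = _clean_and_window(streams, cfg)
    raw = extract_features(ws)

    # exact-size stratified split
    classes = sorted(set(raw.labels.tolist()))
    per_tr = n_train // len(classes)
    per_te = n_test // len(classes)
    rng = np.random.default_rng(seeds["split"])
    tr, te = [], []
    for cls in classes:
        idx = rng.permutation(np.flatnonzero(raw.labels == cls))
        if len(idx) < per_tr + per_te:
            raise ConfigurationError(
                f"not enough windows for class {cls!r}: {len(idx)}"
            )
        tr.append(idx[:per_tr])
        te.append(idx[per_tr:per_tr + per_te])
    train_raw = raw.subset(np.sort(np.concatenate(tr)))
    test_raw = raw.subset(np.sort(np.concatenate(te)))
    normalizer = fit_normalizer(train_raw)
    train = apply_normalizer(normalizer, train_raw)
    test = apply_normalizer(normalizer, test_raw)

    group_ids = list(train.groups)
    elm_seeds = derive_seeds(seeds["elm"], group_ids)
    models = {
        g: train_elm(train.group_matrix(g), train.labels,
                     hidden=cfg.elm_hidden, ridge=cfg.elm_ridge,
                     seed=elm_seeds[g], group_id=g)
        for g in group_ids
    }
    class_order = models[group_ids[0]].class_order
    individual = {
        g: float(np.mean(predict_labels(models[g], test.group_matrix(g))
                         == test.labels))
        for g in group_ids
    }

    ga_cfg = replace(cfg.ga, seed=seeds["ga"])
    train_scores = [predict_scores(models[g], train.group_matrix(g))
                    for g in group_ids]
    train_profile = gdm.make_profile(train_scores, class_order,
                                     mode=cfg.decision_mode)
    test_scores = [predict_scores(models[g], test.group_matrix(g))
                   for g in group_ids]
    test_profile = gdm.make_profile(test_scores, class_order,
                                    mode=cfg.decision_mode)

    def evaluate_lam(lam):
        G = gdm.group_decide_batch(lam, test_profile.U)
        co = np.asarray(class_order, dtype=object)
        pred = co[np.argmax(G, axis=1)]
        return pred, float(np.mean(pred == test.labels))

    weights = gdm.fit_gdm_weights(
        train_profile, train.labels, phi=cfg.phi,
        delta_lambda=cfg.delta_lambda, epochs=cfg.gdm_epochs,
        tol=cfg.gdm_tol, ga_config=ga_cfg,
    )
    base = gdm.baseline_fusers(train_profile, train.labels, ga_cfg)
    accuracies = {}
    predictions = {}
    for name, lam in [("gdm", weights.lam), ("ga", base["ga"]),
                      ("wa", base["wa"]), ("mv", base["mv"])]:
        pred, acc = evaluate_lam(lam)
        accuracies[name] = acc
        predictions[name] = pred
    cm = confusion(test.labels, predictions["gdm"], class_order)
    return {
        "individual_accuracies": individual,
        "fuser_accuracies": accuracies,
        "weights": weights,
        "gdm_metrics": metrics(cm),
        "n_train": train.n_rows,
        "n_test": test.n_rows,
        "class_order": class_order,
        "group_ids": group_ids,
    }
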