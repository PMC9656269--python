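"""File-format contracts: sensor-stream CSV, feature-table CSV, model JSON.

A stream CSV has columns ``timestamp,label,<POS>/<Sensor>/<axis>,...``
with missing samples as empty fields; the sampling rate is recovered
from the timestamp spacing.  Feature tables serialize with their
``group:channel:feature`` headers and a ``label`` column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .features import FeatureTable
from .preprocess import ChannelTag, SensorStream

__all__ = [
    "write_stream_csv",
    "read_stream_csv",
    "write_feature_csv",
    "read_feature_csv",
    "write_json",
    "save_ensemble",
    "load_ensemble",
]


def write_stream_csv(stream: SensorStream, path) -> None:
    path = Path(path)
    t = np.arange(stream.n_samples) / stream.sampling_rate
    df = pd.DataFrame({"timestamp": t, "label": stream.labels})
    for i, tag in enumerate(stream.channel_tags):
        df[str(tag)] = stream.values[:, i]
    df.to_csv(path, index=False, na_rep="")


def read_stream_csv(path, subject_id: str | None = None) -> SensorStream:
    path = Path(path)
    df = pd.read_csv(path)
    if "timestamp" not in df.columns or "label" not in df.columns:
        raise DataError(f"{path.name}: stream CSV needs timestamp and label columns")
    chan_cols = [c for c in df.columns if c not in ("timestamp", "label")]
    if not chan_cols:
        raise DataError(f"{path.name}: no channel columns")
    ts = df["timestamp"].to_numpy(dtype=float)
    if len(ts) < 2:
        raise DataError(f"{path.name}: need at least 2 samples")
    dt = np.median(np.diff(ts))
    if dt <= 0:
        raise DataError(f"{path.name}: timestamps are not increasing")
    return SensorStream(
        subject_id=subject_id or path.stem,
        sampling_rate=1.0 / dt,
        channel_tags=[ChannelTag.parse(c) for c in chan_cols],
        values=df[chan_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(),
    )


def write_feature_csv(table: FeatureTable, path) -> None:
    df = table.values.copy()
    df.insert(0, "label", table.labels)
    df.to_csv(path, index=False)


def read_feature_csv(path) -> FeatureTable:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise DataError("feature CSV needs a label column")
    labels = df.pop("label").to_numpy()
    groups: dict[str, list[str]] = {}
    for col in df.columns:
        gid = col.split(":", 1)[0]
        groups.setdefault(gid, []).append(col)
    return FeatureTable(values=df, labels=labels, groups=groups)


def save_ensemble(model, dirpath) -> None:
    """Serialize a fitted ensemble: model.json + one array file per expert."""
    from .elm import ELMModel

    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    meta = {
        "expert_ids": model.expert_ids,
        "class_order": model.class_order,
        "decision_mode": model.decision_mode,
        "config": model.config,
        "weights": {
            "alpha": model.weights.alpha.tolist(),
            "beta": model.weights.beta.tolist(),
            "lam": model.weights.lam.tolist(),
            "phi": model.weights.phi,
            "delta_lambda": model.weights.delta_lambda,
        },
        "normalizer": (
            None if model.normalizer is None else {
                "columns": list(model.normalizer.mins.index),
                "mins": model.normalizer.mins.tolist(),
                "maxs": model.normalizer.maxs.tolist(),
            }
        ),
    }
    write_json(meta, dirpath / "model.json")
    for i, gid in enumerate(model.expert_ids):
        m: ELMModel = model.models[gid]
        write_json({
            "group_id": m.group_id,
            "activation": m.activation,
            "seed": m.seed,
            "class_order": m.class_order,
            "input_weights": m.input_weights,
            "biases": m.biases,
            "output_weights": m.output_weights,
        }, dirpath / f"expert_{i}.json")


def load_ensemble(dirpath):
    """Inverse of :func:`save_ensemble`."""
    from .elm import ELMModel
    from .features import Normalizer
    from .gdm import EnsembleModel, ExpertWeights

    dirpath = Path(dirpath)
    meta = json.loads((dirpath / "model.json").read_text())
    models = {}
    for i, gid in enumerate(meta["expert_ids"]):
        d = json.loads((dirpath / f"expert_{i}.json").read_text())
        models[gid] = ELMModel(
            input_weights=np.asarray(d["input_weights"]),
            biases=np.asarray(d["biases"]),
            output_weights=np.asarray(d["output_weights"]),
            class_order=d["class_order"],
            activation=d["activation"],
            group_id=d["group_id"],
            seed=d["seed"],
        )
    w = meta["weights"]
    norm = None
    if meta["normalizer"] is not None:
        nd = meta["normalizer"]
        norm = Normalizer(
            mins=pd.Series(nd["mins"], index=nd["columns"]),
            maxs=pd.Series(nd["maxs"], index=nd["columns"]),
        )
    return EnsembleModel(
        expert_ids=list(meta["expert_ids"]),
        models=models,
        weights=ExpertWeights(
            alpha=np.asarray(w["alpha"]),
            beta=np.asarray(w["beta"]),
            lam=np.asarray(w["lam"]),
            phi=w["phi"],
            delta_lambda=w["delta_lambda"],
        ),
        class_order=list(meta["class_order"]),
        normalizer=norm,
        decision_mode=meta["decision_mode"],
        config=meta["config"],
    )


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
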