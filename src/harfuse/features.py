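"""Window features and min-max normalization.

Eight time-domain features per channel per window: max, min, mean,
RMS, standard deviation (population 1/N divisor), skewness, kurtosis
(fourth standardized moment, no excess subtraction) and signal energy
sum(a_i^2).  A zero-variance window gets skewness = kurtosis = 0 by
convention.  Features are min-max scaled to [0, 1] with statistics
fitted on the training split only; test values are clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError, DataError
from .preprocess import WindowSet

__all__ = [
    "FEATURE_NAMES",
    "FeatureTable",
    "Normalizer",
    "default_groups",
    "extract_features",
    "fit_normalizer",
    "apply_normalizer",
]

FEATURE_NAMES = ("max", "min", "mean", "rms", "std", "skew", "kurt", "energy")


@dataclass
class FeatureTable:
    """Windowed feature matrix with labels and channel-group provenance.

    ``values`` columns are named ``"<group>:<channel>:<feature>"``;
    ``groups`` maps a group id (one sensor unit = one base classifier's
    training data) to its column names.
    """

    values: pd.DataFrame
    labels: np.ndarray
    groups: dict[str, list[str]]

    @property
    def n_rows(self) -> int:
        return len(self.values)

    def group_matrix(self, group_id: str) -> np.ndarray:
        """Feature rows restricted to one channel group, as an array."""
        if group_id not in self.groups:
            raise ConfigurationError(f"unknown group {group_id!r}")
        return self.values[self.groups[group_id]].to_numpy(dtype=float)

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            values=self.values.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            groups={g: list(cols) for g, cols in self.groups.items()},
        )


@dataclass
class Normalizer:
    """Per-column (min, max) fitted on training rows."""

    mins: pd.Series
    maxs: pd.Series


def default_groups(windows: WindowSet) -> dict[str, list[int]]:
    """Group channel indices by sensor unit (position/sensor tag)."""
    groups: dict[str, list[int]] = {}
    for i, tag in enumerate(windows.channel_tags):
        groups.setdefault(tag.unit, []).append(i)
    if not groups:
        groups = {"all": list(range(windows.data.shape[1]))}
    return groups


def _window_features(x: np.ndarray) -> np.ndarray:
    """Features for ``x`` of shape (n_windows, n_channels, window_len).

    Returns (n_windows, n_channels, 8) in :data:`FEATURE_NAMES` order.
    """
    n = x.shape[-1]
    mx = x.max(axis=-1)
    mn = x.min(axis=-1)
    mean = x.mean(axis=-1)
    centered = x - mean[..., None]
    var = (centered ** 2).mean(axis=-1)
    std = np.sqrt(var)
    energy = (x ** 2).sum(axis=-1)
    rms = np.sqrt(energy / n)
    m3 = (centered ** 3).mean(axis=-1)
    m4 = (centered ** 4).mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(std > 0, m3 / np.where(std > 0, std, 1) ** 3, 0.0)
        kurt = np.where(std > 0, m4 / np.where(std > 0, std, 1) ** 4, 0.0)
    return np.stack([mx, mn, mean, rms, std, skew, kurt, energy], axis=-1)


def extract_features(
    windows: WindowSet,
    groups: dict[str, list[int]] | None = None,
) -> FeatureTable:
    """Compute the eight per-channel features for every window.

    ``groups`` maps group id -> channel indices; defaults to one group
    per sensor unit derived from the window set's channel tags.
    """
    if windows.n_windows == 0:
        raise DataError("cannot extract features from an empty WindowSet")
    if groups is None:
        groups = default_groups(windows)
    n_ch = windows.data.shape[1]
    for gid, chans in groups.items():
        if not chans:
            raise ConfigurationError(f"group {gid!r} is empty")
        if any(not (0 <= c < n_ch) for c in chans):
            raise ConfigurationError(
                f"group {gid!r} references an unknown channel index"
            )
    feats = _window_features(windows.data)  # (nw, nc, 8)
    cols: list[str] = []
    data: list[np.ndarray] = []
    col_groups: dict[str, list[str]] = {}
    for gid, chans in groups.items():
        col_groups[gid] = []
        for c in chans:
            for fi, fname in enumerate(FEATURE_NAMES):
                name = f"{gid}:{c}:{fname}"
                cols.append(name)
                col_groups[gid].append(name)
                data.append(feats[:, c, fi])
    df = pd.DataFrame(dict(zip(cols, data)))
    return FeatureTable(values=df, labels=windows.labels.copy(), groups=col_groups)


def fit_normalizer(train: FeatureTable) -> Normalizer:
    """Per-column min/max over training rows (constant columns: max = min)."""
    if train.n_rows < 1:
        raise DataError("cannot fit a normalizer on an empty table")
    return Normalizer(mins=train.values.min(axis=0), maxs=train.values.max(axis=0))


def apply_normalizer(norm: Normalizer, table: FeatureTable) -> FeatureTable:
    """Scale to [0, 1]: (v - min) / (max - min), clipped; constant columns -> 0."""
    if list(norm.mins.index) != list(table.values.columns):
        raise ContractError("normalizer columns do not match the table")
    span = (norm.maxs - norm.mins).to_numpy()
    mins = norm.mins.to_numpy()
    vals = table.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(span > 0, (vals - mins) / np.where(span > 0, span, 1), 0.0)
    scaled = np.clip(scaled, 0.0, 1.0)
    return FeatureTable(
        values=pd.DataFrame(scaled, columns=table.values.columns),
        labels=table.labels.copy(),
        groups={g: list(c) for g, c in table.groups.items()},
    )
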