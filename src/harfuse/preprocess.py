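"""Raw-stream containers and cleaning: missing-value fill, spike removal,
sliding-window segmentation.

A :class:`SensorStream` is one subject's synchronized multi-channel
recording; every sample carries an activity label.  Cleaning is
channel-wise and order matters: fill missing values first (the Hampel
filter assumes a gap-free series), then remove spikes, then segment
into fixed-length windows with fractional overlap.  Windows whose
samples span more than one activity are discarded — recordings are
per-activity blocks, so a straddling window is a segmentation artifact,
not a real transition example.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, ContractError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelTag",
    "SensorStream",
    "WindowSet",
    "fill_missing",
    "remove_outliers",
    "segment",
]


@dataclass(frozen=True)
class ChannelTag:
    """Identity of one sensor channel: body position, sensor type, axis.

    Rendered as ``"RKN/Acc/x"`` in CSV headers.  A *sensor unit* (one
    base classifier's data source) is the set of channels sharing
    ``(position, sensor)``, e.g. the triaxial accelerometer at the
    right knee.
    """

    position: str
    sensor: str
    axis: str

    @property
    def unit(self) -> str:
        return f"{self.position}/{self.sensor}"

    def __str__(self) -> str:
        return f"{self.position}/{self.sensor}/{self.axis}"

    @classmethod
    def parse(cls, text: str) -> "ChannelTag":
        parts = text.split("/")
        if len(parts) != 3:
            raise DataError(f"channel header {text!r} is not POS/Sensor/axis")
        return cls(*parts)


@dataclass
class SensorStream:
    """One subject's labeled multi-channel time series.

    Parameters
    ----------
    subject_id
        Opaque identifier.
    sampling_rate
        Samples per second, > 0.
    channel_tags
        One :class:`ChannelTag` per column of ``values``.
    values
        Array of shape ``(n_samples, n_channels)``; NaN marks missing.
    labels
        Per-sample activity class, shape ``(n_samples,)``; never missing.
    """

    subject_id: str
    sampling_rate: float
    channel_tags: list[ChannelTag]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if self.values.ndim != 2:
            raise ContractError("values must be 2-D (samples x channels)")
        n, c = self.values.shape
        if n < 2:
            raise DataError("stream must have at least 2 samples")
        if c != len(self.channel_tags):
            raise ContractError(
                f"{c} value columns but {len(self.channel_tags)} channel tags"
            )
        if len(self.labels) != n:
            raise ContractError("labels length does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class WindowSet:
    """Segmented windows: ``data`` has shape (n_windows, n_channels, window_len)."""

    data: np.ndarray
    labels: np.ndarray
    window_len: int
    step: int
    channel_tags: list[ChannelTag] = field(default_factory=list)
    sampling_rate: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]


def fill_missing(stream: SensorStream) -> SensorStream:
    """Replace missing samples by the last observed value (forward fill).

    A run of missing values at the head of a channel, with no previous
    value to repeat, is filled backward from the first observed value.
    Channel with no observed value at all -> :class:`DataError`.
    Idempotent; a stream without missing markers is returned unchanged
    in value.
    """
    vals = stream.values
    all_nan = np.all(np.isnan(vals), axis=0)
    if np.any(all_nan):
        bad = stream.channel_tags[int(np.flatnonzero(all_nan)[0])]
        raise DataError(f"channel {bad} is entirely missing")
    out = vals.copy()
    n = out.shape[0]
    # forward fill: index of last non-NaN row per position, per channel
    for c in range(out.shape[1]):
        col = out[:, c]
        mask = np.isnan(col)
        if not mask.any():
            continue
        idx = np.where(mask, 0, np.arange(n))
        np.maximum.accumulate(idx, out=idx)
        col = col[idx]
        # head: positions before the first observed value still NaN
        if np.isnan(col[0]):
            first = np.flatnonzero(~np.isnan(col))[0]
            col[:first] = col[first]
        out[:, c] = col
    return replace(stream, values=out)


def _hampel(x: np.ndarray, half_width: int, n_sigmas: float) -> np.ndarray:
    """Vectorized centered Hampel filter on a 1-D gap-free series."""
    pad = np.full(half_width, np.nan)
    xp = np.concatenate([pad, x, pad])
    win = sliding_window_view(xp, 2 * half_width + 1)
    med = np.nanmedian(win, axis=1)
    mad = np.nanmedian(np.abs(win - med[:, None]), axis=1)
    # 1.4826 * MAD estimates sigma for Gaussian noise; a zero MAD
    # (locally constant signal) would pass every spike, so fall back
    # to an epsilon scale there.
    scale = 1.4826 * np.where(mad > 0, mad, 1e-9)
    dev = np.abs(x - med)
    return np.where(dev > n_sigmas * scale, med, x)


def remove_outliers(
    stream: SensorStream,
    half_width: int | None = None,
    n_sigmas: float = 3.0,
) -> SensorStream:
    """Replace spike samples by their rolling-window median (Hampel filter).

    A sample is a spike when it deviates from the median of its
    ``2 * half_width + 1`` neighbourhood by more than
    ``n_sigmas * 1.4826 * MAD`` of that neighbourhood.  Missing values
    must already be filled.  ``half_width`` defaults to half a second
    of samples.
    """
    if half_width is None:
        half_width = max(1, int(round(stream.sampling_rate / 2)))
    if half_width < 1:
        raise ConfigurationError("half_width must be >= 1")
    if half_width >= stream.n_samples:
        raise ConfigurationError(
            f"half_width {half_width} >= series length {stream.n_samples}"
        )
    if np.isnan(stream.values).any():
        raise DataError("remove_outliers requires missing values to be filled")
    out = np.column_stack(
        [_hampel(stream.values[:, c], half_width, n_sigmas)
         for c in range(stream.n_channels)]
    )
    return replace(stream, values=out)


def segment(
    stream: SensorStream,
    window_seconds: float = 0.5,
    overlap: float = 0.5,
) -> WindowSet:
    """Cut the stream into fixed-length windows with fractional overlap.

    ``window_len = max(2, floor(window_seconds * sampling_rate))`` and
    ``step = max(1, floor(window_len * (1 - overlap)))``.  Windows start
    at 0, step, 2*step, ... while fully inside the stream.  Windows whose
    samples carry more than one distinct label are discarded.  A stream
    shorter than one window yields an empty :class:`WindowSet` (logged,
    not an error).
    """
    if window_seconds <= 0:
        raise ConfigurationError("window_seconds must be > 0")
    if not (0 <= overlap < 1):
        raise ConfigurationError("overlap must be in [0, 1)")
    window_len = max(2, math.floor(window_seconds * stream.sampling_rate))
    step = max(1, math.floor(window_len * (1 - overlap)))
    n = stream.n_samples
    if n < window_len:
        logger.warning(
            "stream %s shorter than one window (%d < %d); empty WindowSet",
            stream.subject_id, n, window_len,
        )
        return WindowSet(
            data=np.empty((0, stream.n_channels, window_len)),
            labels=np.empty((0,), dtype=stream.labels.dtype),
            window_len=window_len,
            step=step,
            channel_tags=list(stream.channel_tags),
            sampling_rate=stream.sampling_rate,
        )
    starts = np.arange(0, n - window_len + 1, step)
    # (n_windows, window_len) views over samples and labels
    keep, data, labels = [], [], []
    for s in starts:
        lab = stream.labels[s:s + window_len]
        if (lab != lab[0]).any():
            continue
        data.append(stream.values[s:s + window_len, :].T)
        labels.append(lab[0])
    arr = (np.stack(data) if data
           else np.empty((0, stream.n_channels, window_len)))
    return WindowSet(
        data=arr,
        labels=np.asarray(labels, dtype=stream.labels.dtype),
        window_len=window_len,
        step=step,
        channel_tags=list(stream.channel_tags),
        sampling_rate=stream.sampling_rate,
    )


def concat_windows(sets: Sequence[WindowSet]) -> WindowSet:
    """Pool windows from several streams (same channels / window geometry)."""
    sets = [w for w in sets if w.n_windows > 0]
    if not sets:
        raise DataError("no non-empty window sets to concatenate")
    first = sets[0]
    for w in sets[1:]:
        if w.window_len != first.window_len or w.data.shape[1] != first.data.shape[1]:
            raise ContractError("window sets have incompatible geometry")
    return WindowSet(
        data=np.concatenate([w.data for w in sets]),
        labels=np.concatenate([w.labels for w in sets]),
        window_len=first.window_len,
        step=first.step,
        channel_tags=list(first.channel_tags),
        sampling_rate=first.sampling_rate,
    )
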