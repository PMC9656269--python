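"""Synthetic multi-position wearable-sensor data.

Emulates the structure the pipeline assumes: each subject wears one
triaxial sensor unit per body position; each activity is recorded as a
contiguous block; each channel is a class-dependent sinusoid plus a
slow linear trend, with Gaussian noise, optional missing samples and
optional spike outliers.

How discriminable the classes are at a position is controlled by that
position's ``separability`` ``s``: the class with index ``k`` gets a
mean offset ``s * mean_step * k`` and sinusoid frequency
``base_freq * (1 + 0.2 * s * k)``.  With ``s = 0`` every class looks
identical at that position (chance-level classifier); larger ``s``
spreads the classes apart in both amplitude and frequency, the way a
knee-mounted accelerometer separates walking from lying far better
than a wrist sensor does.

``class_confusions`` lets a position render one activity with another
activity's signal parameters, making exactly that pair of classes
indistinguishable there.  This is how the complementary-experts
benchmark is built: each position resolves a different class pair, so
no single sensor suffices but the pool jointly covers all classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .preprocess import ChannelTag, SensorStream

__all__ = ["SynthConfig", "generate_dataset", "complementary_scenario_config"]

_AXES = ("x", "y", "z", "u", "v", "w")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    Attributes
    ----------
    n_subjects, n_positions, channels_per_position
        Pool geometry; one sensor unit ("Acc") per position, 3 axes by
        default.
    activities
        Class names; generated as contiguous blocks per subject.
    sampling_rate
        Hz, >= 4.
    duration_per_activity
        Seconds of signal per activity block.
    separability
        Per-position non-negative scale of between-class mean/frequency
        differences; length must equal ``n_positions``.
    noise_sd
        Gaussian noise standard deviation added to every sample.
    missing_rate, spike_rate
        Fractions in [0, 1) of samples replaced by NaN / by values at
        least 10 channel standard deviations from the channel mean.
    mean_step, base_freq, amplitude
        Signal family parameters (offset step per class index, base
        sinusoid frequency in Hz, sinusoid amplitude).
    class_confusions
        Optional ``{position_index: {activity: mimicked_activity}}``:
        at that position the activity is rendered with the mimicked
        activity's parameters, collapsing the pair.
    seed
        Generator seed; identical configs give bit-identical output.
    """

    n_subjects: int = 1
    n_positions: int = 5
    channels_per_position: int = 3
    activities: Sequence[str] = ("walking", "sitting", "lying")
    sampling_rate: float = 32.0
    duration_per_activity: float = 30.0
    separability: Sequence[float] | None = None
    noise_sd: float = 0.6
    missing_rate: float = 0.0
    spike_rate: float = 0.0
    mean_step: float = 1.0
    base_freq: float = 1.0
    amplitude: float = 1.0
    class_confusions: Mapping[int, Mapping[str, str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separability is None:
            self.separability = tuple(1.5 for _ in range(self.n_positions))
        self.separability = tuple(float(s) for s in self.separability)
        self.activities = tuple(str(a) for a in self.activities)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_positions < 2:
            raise ConfigurationError("n_positions must be >= 2")
        if self.channels_per_position < 1:
            raise ConfigurationError("channels_per_position must be >= 1")
        if len(self.activities) < 2:
            raise ConfigurationError("activities must list >= 2 classes")
        if len(set(self.activities)) != len(self.activities):
            raise ConfigurationError("activities must be distinct")
        if self.sampling_rate < 4:
            raise ConfigurationError("sampling_rate must be >= 4 Hz")
        if self.duration_per_activity <= 0:
            raise ConfigurationError("duration_per_activity must be > 0")
        if len(self.separability) != self.n_positions:
            raise ConfigurationError(
                "separability length must equal n_positions"
            )
        if any(s < 0 for s in self.separability):
            raise ConfigurationError("separability entries must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not (0 <= self.spike_rate < 1):
            raise ConfigurationError("spike_rate must be in [0, 1)")
        for p, mapping in self.class_confusions.items():
            if not (0 <= int(p) < self.n_positions):
                raise ConfigurationError("class_confusions position out of range")
            for a, b in mapping.items():
                if a not in self.activities or b not in self.activities:
                    raise ConfigurationError(
                        "class_confusions names an unknown activity"
                    )

    def channel_tags(self) -> list[ChannelTag]:
        tags = []
        for p in range(self.n_positions):
            for c in range(self.channels_per_position):
                axis = _AXES[c % len(_AXES)] + ("" if c < len(_AXES) else str(c))
                tags.append(ChannelTag(f"P{p}", "Acc", axis))
        return tags


def generate_dataset(cfg: SynthConfig) -> list[SensorStream]:
    """Generate one labeled :class:`SensorStream` per subject."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_block = int(round(cfg.duration_per_activity * cfg.sampling_rate))
    n_total = n_block * len(cfg.activities)
    tags = cfg.channel_tags()
    n_ch = len(tags)
    class_index = {a: k for k, a in enumerate(cfg.activities)}
    streams = []
    t = np.arange(n_total) / cfg.sampling_rate
    for subj in range(cfg.n_subjects):
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        slopes = rng.uniform(-0.01, 0.01, size=n_ch)
        values = np.empty((n_total, n_ch))
        labels = np.empty(n_total, dtype=object)
        for b, act in enumerate(cfg.activities):
            sl = slice(b * n_block, (b + 1) * n_block)
            labels[sl] = act
            tb = t[sl]
            # trend is block-local: sensor drift restarts with each
            # recording, so elapsed time never encodes class identity
            tb_local = tb - tb[0]
            ci = 0
            for p in range(cfg.n_positions):
                s = cfg.separability[p]
                eff = cfg.class_confusions.get(p, {}).get(act, act)
                k = class_index[eff]
                mu = s * cfg.mean_step * k
                freq = cfg.base_freq * (1.0 + 0.2 * s * k)
                for c in range(cfg.channels_per_position):
                    # quarter-turn phase offset per axis of a unit
                    ph = phases[ci] + c * np.pi / 2
                    values[sl, ci] = (
                        mu
                        + cfg.amplitude * np.sin(2 * np.pi * freq * tb + ph)
                        + slopes[ci] * tb_local
                    )
                    ci += 1
        values += rng.normal(0.0, cfg.noise_sd, size=values.shape)
        # spikes then missing, on disjoint index sets per channel
        for ci in range(n_ch):
            n_spike = int(round(cfg.spike_rate * n_total))
            n_miss = int(round(cfg.missing_rate * n_total))
            if n_spike + n_miss == 0:
                continue
            perm = rng.permutation(n_total)
            spike_idx = perm[:n_spike]
            miss_idx = perm[n_spike:n_spike + n_miss]
            if n_spike:
                col = values[:, ci]
                sd = float(np.std(col)) or 1.0
                mean = float(np.mean(col))
                sign = rng.choice([-1.0, 1.0], size=n_spike)
                mag = 10.0 + rng.uniform(0.0, 2.0, size=n_spike)
                values[spike_idx, ci] = mean + sign * mag * sd
            if n_miss:
                values[miss_idx, ci] = np.nan
        streams.append(
            SensorStream(
                subject_id=f"S{subj + 1}",
                sampling_rate=cfg.sampling_rate,
                channel_tags=list(tags),
                values=values,
                labels=labels,
            )
        )
    return streams


def complementary_scenario_config(
    seed: int = 0,
    duration_per_activity: float = 78.0,
    noise_sd: float = 0.6,
    missing_rate: float = 0.0,
    spike_rate: float = 0.0,
) -> SynthConfig:
    """Benchmark conditions: 4 positions, 3 activities, complementary experts.

    Each position is blind to one pair of the three activities (rendered
    with identical signal parameters) and separates the rest, so no
    single sensor suffices but the pool jointly covers every class.
    Separability decays across positions (2.0, 1.5, 1.0, 0.6), making
    experts unequal in quality as real body positions are.  At 32 Hz with
    0.5 s windows and 50% overlap, 78 s per activity yields roughly
    930 single-label windows per subject — enough for a 600-train /
    300-test split.
    """
    acts = ("walking", "sitting", "lying")
    # Each position collapses one activity pair and cleanly separates the
    # rest; the three distinct pairs are covered, the weakest position
    # duplicates one pair in the mirrored direction.
    confusions = {
        0: {"lying": "walking"},     # blind to (walking, lying)
        1: {"walking": "sitting"},   # blind to (walking, sitting)
        2: {"sitting": "lying"},     # blind to (sitting, lying)
        3: {"lying": "sitting"},     # blind to (sitting, lying), mirrored
    }
    return SynthConfig(
        n_subjects=1,
        n_positions=4,
        channels_per_position=3,
        activities=acts,
        sampling_rate=32.0,
        duration_per_activity=duration_per_activity,
        separability=(2.0, 1.5, 1.0, 0.6),
        noise_sd=noise_sd,
        missing_rate=missing_rate,
        spike_rate=spike_rate,
        class_confusions=confusions,
        seed=seed,
    )
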