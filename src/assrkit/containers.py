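"""Shared in-memory containers for the ASSR analysis pipeline.

The central currency is the :class:`EpochSet` (trials x channels x samples,
time axis anchored at stimulus onset); continuous simulated or recorded data
live in :class:`ContinuousRecording`, and the spatial-filter stage produces a
single :class:`VirtualChannelEpochs` time series per participant/modality.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

CONDITIONS = ("40Hz", "20Hz", "60Hz")
MODALITIES = ("EEG", "OPM", "SQUID")

#: epoch window relative to stimulus onset, seconds, half-open at the right edge
EPOCH_WINDOW_S = (-1.0, 3.0)


@dataclass
class ChannelInfo:
    """Metadata for one sensor/electrode.

    ``position_tag`` is a nominal scalp-position label (``frontocentral``,
    ``temporal_left`` ...); ``axis`` distinguishes the two measurement
    directions of dual-axis OPM sensors (``rad``/``tan``); ``site`` groups the
    two axes of one physical OPM sensor.
    """

    label: str
    modality: str
    position_tag: str = "other"
    axis: str = "rad"
    site: int = -1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelInfo":
        return cls(**d)


@dataclass
class Event:
    sample_index: int
    condition: str

    def to_dict(self) -> dict:
        return {"sample_index": int(self.sample_index), "condition": self.condition}


@dataclass(eq=False)
class ContinuousRecording:
    """Multichannel continuous time series with event markers.

    data : (n_channels, n_samples) array in modality units (V or T).
    """

    data: np.ndarray
    sampling_rate_hz: float
    channel_info: list[ChannelInfo]
    events: list[Event]
    participant_id: str = "sim"
    #: ground-truth log of injected artifacts (simulated data only):
    #: [{"kind": "blink"|"muscle", "sample_index": int, "n_samples": int, ...}]
    artifact_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_info) != self.data.shape[0]:
            raise ValueError(
                f"channel_info length {len(self.channel_info)} does not match "
                f"data channel dimension {self.data.shape[0]}"
            )
        idx = [e.sample_index for e in self.events]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("events must be sorted by sample_index")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def modality(self) -> str:
        return self.channel_info[0].modality if self.channel_info else "unknown"

    def channel_labels(self) -> list[str]:
        return [c.label for c in self.channel_info]


@dataclass(eq=False)
class EpochSet:
    """Trials x channels x samples, with t = 0 at stimulus onset."""

    data: np.ndarray
    time_axis_s: np.ndarray
    sampling_rate_hz: float
    condition_labels: np.ndarray
    kept_trial_ids: np.ndarray
    channel_info: list[ChannelInfo]
    participant_id: str = "sim"
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis_s = np.asarray(self.time_axis_s, dtype=float)
        self.condition_labels = np.asarray(self.condition_labels)
        self.kept_trial_ids = np.asarray(self.kept_trial_ids, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        if self.data.shape[2] != self.time_axis_s.size:
            raise ValueError("time axis length does not match sample dimension")
        if len(self.channel_info) != self.data.shape[1]:
            raise ValueError("channel_info length does not match channel dimension")
        if self.data.shape[0] != self.kept_trial_ids.size:
            raise ValueError("kept_trial_ids length does not match trial dimension")
        if np.any(np.diff(self.kept_trial_ids) <= 0):
            raise ValueError("kept_trial_ids must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_labels(self) -> list[str]:
        return [c.label for c in self.channel_info]

    def copy_with(self, **kw) -> "EpochSet":
        base = dict(
            data=self.data,
            time_axis_s=self.time_axis_s,
            sampling_rate_hz=self.sampling_rate_hz,
            condition_labels=self.condition_labels,
            kept_trial_ids=self.kept_trial_ids,
            channel_info=list(self.channel_info),
            participant_id=self.participant_id,
            modality=self.modality,
        )
        base.update(kw)
        return EpochSet(**base)

    def drop_trials(self, trial_ids: Sequence[int]) -> "EpochSet":
        """Remove trials by their original chronological ids."""
        bad = set(int(t) for t in trial_ids)
        keep = np.array([i for i, t in enumerate(self.kept_trial_ids) if int(t) not in bad])
        if keep.size == 0:
            raise ValueError("dropping these trials would leave an empty EpochSet")
        return self.copy_with(
            data=self.data[keep],
            condition_labels=self.condition_labels[keep],
            kept_trial_ids=self.kept_trial_ids[keep],
        )

    def drop_channels(self, labels: Sequence[str]) -> "EpochSet":
        bad = set(labels)
        keep = [i for i, c in enumerate(self.channel_info) if c.label not in bad]
        if not keep:
            raise ValueError("dropping these channels would leave an empty EpochSet")
        return self.copy_with(
            data=self.data[:, keep, :],
            channel_info=[self.channel_info[i] for i in keep],
        )

    def pick_channels(self, indices: Sequence[int]) -> "EpochSet":
        indices = list(indices)
        return self.copy_with(
            data=self.data[:, indices, :],
            channel_info=[self.channel_info[i] for i in indices],
        )

    def exclude_tags(self, tags: Sequence[str]) -> "EpochSet":
        tags = set(tags)
        keep = [i for i, c in enumerate(self.channel_info) if c.position_tag not in tags]
        return self.pick_channels(keep)


@dataclass(eq=False)
class SpatialFilterSpec:
    """Channel weights + polarity sign defining one virtual channel."""

    weights: np.ndarray
    polarity_sign: int = 1
    fit_band_hz: tuple[float, float] = (39.0, 41.0)
    fit_window_s: tuple[float, float] = (0.25, 1.0)
    canonical_correlation_value: float = np.nan

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be a vector")
        if not np.any(self.weights != 0):
            raise ValueError("weights must not be all zero")
        if self.polarity_sign not in (-1, 1):
            raise ValueError("polarity_sign must be +1 or -1")

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "polarity_sign": int(self.polarity_sign),
                "fit_band_hz": list(self.fit_band_hz),
                "fit_window_s": list(self.fit_window_s),
                "canonical_correlation_value": float(self.canonical_correlation_value),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "SpatialFilterSpec":
        d = json.loads(s)
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            polarity_sign=int(d["polarity_sign"]),
            fit_band_hz=tuple(d["fit_band_hz"]),
            fit_window_s=tuple(d["fit_window_s"]),
            canonical_correlation_value=float(d["canonical_correlation_value"]),
        )


@dataclass(eq=False)
class VirtualChannelEpochs:
    """Single-channel trials x samples series produced by a spatial filter."""

    data: np.ndarray
    time_axis_s: np.ndarray
    sampling_rate_hz: float
    kept_trial_ids: np.ndarray
    provenance: dict = field(default_factory=dict)
    participant_id: str = "sim"
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis_s = np.asarray(self.time_axis_s, dtype=float)
        self.kept_trial_ids = np.asarray(self.kept_trial_ids, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (trials x samples)")
        if self.data.shape[0] != self.kept_trial_ids.size:
            raise ValueError("kept_trial_ids length does not match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def average(self, trial_rows: Sequence[int] | None = None) -> np.ndarray:
        if trial_rows is None:
            return self.data.mean(axis=0)
        return self.data[list(trial_rows)].mean(axis=0)


@dataclass(eq=False)
class SpectroTemporalMap:
    """Frequency x time map of power (of the trial average) or ITPC.

    Invalid cells (analysis window does not fit inside the epoch) are NaN.
    """

    values: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    kind: str  # "power_of_average" | "itpc"
    n_trials_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.values.shape != (self.freqs_hz.size, self.times_s.size):
            raise ValueError("values shape must be (n_freqs, n_times)")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.kind not in ("power_of_average", "itpc"):
            raise ValueError(f"unknown map kind {self.kind!r}")
        finite = self.values[np.isfinite(self.values)]
        if self.kind == "itpc" and finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("ITPC values must lie in [0, 1]")
        if self.kind == "power_of_average" and finite.size and finite.min() < -1e-12:
            raise ValueError("power values must be non-negative")


@dataclass
class SnrResult:
    """Linear-ratio SNR (power) or ITPC-ratio at 40 Hz vs a noise band."""

    snr: float
    metric: str  # "power_snr" | "itpc_ratio"
    n_trials: int
    signal_freq_hz: float = 40.0
    noise_band_hz: tuple = ((20.0, 38.0), (42.0, 48.0))
    modality: str | None = None
    participant_id: str | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.snr > 0:
            raise ValueError("snr must be positive")


@dataclass(eq=False)
class TrialCountCurve:
    """Metric values computed from the first k retained trials, k in bins."""

    bins: np.ndarray
    results: list[SnrResult]
    metric: str
    participant_id: str | None = None
    modality: str | None = None
    selection_rule: str = "chronological"

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=int)
        if np.any(np.diff(self.bins) <= 0):
            raise ValueError("bins must be strictly increasing")
        if len(self.results) != self.bins.size:
            raise ValueError("one result per bin required")

    @property
    def values(self) -> np.ndarray:
        return np.array([r.snr for r in self.results])
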