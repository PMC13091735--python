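"""Shared fixtures: small, fast synthetic objects built programmatically."""
from __future__ import annotations

import numpy as np
import pytest

from assrkit.containers import ChannelInfo, EpochSet, VirtualChannelEpochs

FS = 500.0
N_SAMP = 2000  # 4 s epochs at 500 Hz


def make_epochs(data: np.ndarray, modality: str = "SQUID", fs: float = FS,
                tags: list[str] | None = None) -> EpochSet:
    """EpochSet from a (trials, channels, samples) array with a [-1, 3) s axis."""
    n_tr, n_ch, n_s = data.shape
    t = (np.arange(n_s) - int(fs)) / fs
    if tags is None:
        tags = ["other"] * n_ch
    chs = [ChannelInfo(label=f"C{i:02d}", modality=modality, position_tag=tags[i])
           for i in range(n_ch)]
    return EpochSet(data=data, time_axis_s=t, sampling_rate_hz=fs,
                    condition_labels=np.array(["40Hz"] * n_tr),
                    kept_trial_ids=np.arange(n_tr), channel_info=chs,
                    modality=modality)


def make_virtual(data: np.ndarray, fs: float = FS) -> VirtualChannelEpochs:
    n_tr, n_s = data.shape
    t = (np.arange(n_s) - int(fs)) / fs
    return VirtualChannelEpochs(data=data, time_axis_s=t, sampling_rate_hz=fs,
                                kept_trial_ids=np.arange(n_tr))


def phase_locked_trials(n_trials: int, fs: float = FS, n_samp: int = N_SAMP,
                        freq: float = 40.0, amp: float = 1.0,
                        noise_sd: float = 1.0, jitter_sd: float = 0.0,
                        seed: int = 0) -> np.ndarray:
    """Trials x samples: windowed 40 Hz oscillation (0-1 s) in white noise."""
    rng = np.random.default_rng(seed)
    t = (np.arange(n_samp) - int(fs)) / fs
    stim = (t >= 0) & (t < 1.0)
    out = np.empty((n_trials, n_samp))
    for k in range(n_trials):
        ph = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
        out[k] = amp * np.sin(2 * np.pi * freq * t + ph) * stim
    out += noise_sd * rng.standard_normal(out.shape)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
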