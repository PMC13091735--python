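"""Synthetic multichannel ASSR session generator.

Emulates 108-trial auditory steady-state sessions (100 x 40 Hz, 4 x 20 Hz,
4 x 60 Hz; 1 s amplitude-modulated tones, jittered 1.3-1.7 s inter-trial
intervals) as they would appear on three sensor arrays:

* ``EEG``   -- 56 scalp electrodes + EOG, spatially smeared fronto-central
  response topography, microvolt-scale background, blinks;
* ``OPM``   -- 10-16 dual-axis optically pumped magnetometers over bilateral
  temporal cortex, evoked amplitude x2-3 relative to SQUID;
* ``SQUID`` -- 124 cryogenic gradiometers, low sensor noise, response
  restricted to temporal sensor clusters.

The evoked waveform (onset transient + 40 Hz steady state), the trial-phase
jitter model and the 1/f background are parametric models of the statistical
structure the downstream pipeline assumes, not a biophysical head model.
Generation is a pure function of (config, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import signal

from .containers import ChannelInfo, ContinuousRecording, Event

VACUUM_PERMEABILITY = 4e-7 * math.pi  # N/A^2

_DEFAULT_TRIALS = {"40Hz": 100, "20Hz": 4, "60Hz": 4}


@dataclass
class SimulationConfig:
    """Full description of one simulated session.

    Amplitudes/noise are in the modality's physical units (V for EEG, T for
    OPM/SQUID). ``noise_density`` is the one-sided white-noise amplitude
    spectral density (units/sqrt(Hz)); ``background_asd_10hz`` sets the 1/f
    background's amplitude spectral density at 10 Hz.
    """

    modality: str = "SQUID"
    n_channels: int = 124
    sampling_rate_hz: float = 4000.0
    n_trials_per_condition: dict = field(default_factory=lambda: dict(_DEFAULT_TRIALS))
    stim_duration_s: float = 1.0
    iti_range_s: tuple[float, float] = (1.3, 1.7)
    carrier_hz: float = 1000.0  # conceptual only; never synthesized
    evoked_amplitude: float = 30e-15
    amplitude_factor_vs_squid: float = 1.0
    noise_density: float = 2.5e-15
    background_asd_10hz: float = 60e-15
    background_exponent: float = 1.0  # 1/f^a power slope
    n_background_sources: int = 24  # spatial rank of the 1/f background
    line_noise_hz: float = 50.0
    line_amplitude: float = 150e-15
    phase_jitter_sd_rad: float = 0.3
    onset_transient_amplitude: float = 2.0  # relative to steady-state
    onset_transient_freq_hz: float = 10.0
    onset_transient_tau_s: float = 0.08
    blink_rate_per_min: float = 10.0
    blink_amplitude: float = 300e-15
    muscle_rate_per_min: float = 1.5
    muscle_amplitude: float = 200e-15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("EEG", "OPM", "SQUID"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.stim_duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("rates and durations must be strictly positive")
        lo, hi = self.iti_range_s
        if not lo < hi:
            raise ValueError("iti_range lower bound must be below upper bound")
        if lo <= 0:
            raise ValueError("ITI must be strictly positive")
        if self.noise_density < 0:
            raise ValueError("noise density must be non-negative")
        if sum(self.n_trials_per_condition.values()) < 1:
            raise ValueError("at least one trial required")
        if any(v < 0 for v in self.n_trials_per_condition.values()):
            raise ValueError("trial counts must be non-negative")

    @property
    def n_trials_total(self) -> int:
        return int(sum(self.n_trials_per_condition.values()))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["iti_range_s"] = list(self.iti_range_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "iti_range_s" in d:
            d["iti_range_s"] = tuple(d["iti_range_s"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))


# Per-modality presets. Evoked amplitude is the peak-channel amplitude a
# SQUID-equivalent sensor would see; the OPM proximity factor (default 2.5,
# from the reported 2-3x range) is applied in mix_to_sensors. The 1/f
# background does NOT scale with that factor (it aggregates distant sources
# and room noise), which is what gives OPM its SNR edge over SQUID.
_PRESETS = {
    "EEG": dict(
        modality="EEG",
        n_channels=57,  # 56 scalp + 1 EOG
        sampling_rate_hz=500.0,
        evoked_amplitude=0.6e-6,
        amplitude_factor_vs_squid=1.0,
        noise_density=1.0e-6,
        background_asd_10hz=2.5e-6,
        line_amplitude=5.0e-6,
        blink_amplitude=120e-6,
        muscle_amplitude=30e-6,
    ),
    "OPM": dict(
        modality="OPM",
        n_channels=20,  # 10 dual-axis sites
        sampling_rate_hz=4000.0,
        evoked_amplitude=40e-15,
        amplitude_factor_vs_squid=2.5,
        noise_density=20e-15,
        background_asd_10hz=75e-15,
        line_amplitude=200e-15,
        blink_amplitude=500e-15,
        muscle_amplitude=600e-15,
    ),
    "SQUID": dict(
        modality="SQUID",
        n_channels=124,
        sampling_rate_hz=4000.0,
        evoked_amplitude=40e-15,
        amplitude_factor_vs_squid=1.0,
        noise_density=2.5e-15,
        background_asd_10hz=120e-15,  # separate session, reduced shielding factor
        line_amplitude=150e-15,
        blink_amplitude=300e-15,
        muscle_amplitude=200e-15,
    ),
}


def modality_preset(modality: str, **overrides) -> SimulationConfig:
    """Default :class:`SimulationConfig` for a modality, with overrides."""
    if modality not in _PRESETS:
        raise ValueError(f"unknown modality {modality!r}")
    kw = dict(_PRESETS[modality])
    kw.update(overrides)
    return SimulationConfig(**kw)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # fixed per-purpose substreams so standalone ops match the full pipeline
    return np.random.default_rng(np.random.SeedSequence(entropy=int(config.seed), spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# stimulus schedule
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class StimulusSchedule:
    onsets_s: np.ndarray
    conditions: list[str]
    total_duration_s: float

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.onsets_s.size != len(self.conditions):
            raise ValueError("onsets and conditions must be parallel")


#: padding before the first and after the last stimulus so that every
#: [-1, +3] s epoch window fits inside the recording
_PRE_PAD_S = 1.5
_POST_PAD_S = 3.5


def make_stimulus_schedule(config: SimulationConfig) -> StimulusSchedule:
    """Randomly ordered condition sequence with jittered inter-trial gaps."""
    rng = _rng(config, 0)
    conditions: list[str] = []
    for cond, n in config.n_trials_per_condition.items():
        conditions.extend([cond] * int(n))
    if not conditions:
        raise ValueError("schedule needs at least one trial")
    order = rng.permutation(len(conditions))
    conditions = [conditions[i] for i in order]

    onsets = np.empty(len(conditions))
    t = _PRE_PAD_S
    lo, hi = config.iti_range_s
    for i in range(len(conditions)):
        onsets[i] = t
        t += config.stim_duration_s + rng.uniform(lo, hi)
    total = onsets[-1] + config.stim_duration_s + _POST_PAD_S
    total = max(total, onsets[-1] + 4.0)  # honor the epoch window even for 1 trial
    return StimulusSchedule(onsets_s=onsets, conditions=conditions, total_duration_s=total)


# ---------------------------------------------------------------------------
# source waveform
# ---------------------------------------------------------------------------

_COND_FREQ = {"40Hz": 40.0, "20Hz": 20.0, "60Hz": 60.0}

#: duration of the post-offset decay appended to the 1 s stimulation
_OFFSET_DECAY_S = 0.05
_ONSET_RAMP_S = 0.05


def synthesize_source_waveform(condition: str, config: SimulationConfig,
                               trial_phase: float = 0.0) -> np.ndarray:
    """One trial of source activity: onset transient + steady-state oscillation.

    Returns samples covering [0, stim_duration + offset decay) at the native
    rate. The steady-state phase is locked to stimulus onset up to
    ``trial_phase`` (radians); unit amplitude in source space.
    """
    if condition not in _COND_FREQ:
        raise ValueError(f"unknown condition {condition!r}")
    f_mod = _COND_FREQ[condition]
    fs = config.sampling_rate_hz
    n = int(round((config.stim_duration_s + _OFFSET_DECAY_S) * fs))
    t = np.arange(n) / fs

    transient = (
        config.onset_transient_amplitude
        * np.exp(-t / config.onset_transient_tau_s)
        * np.sin(2 * np.pi * config.onset_transient_freq_hz * t)
    )
    ramp_on = np.clip(t / _ONSET_RAMP_S, 0.0, 1.0)
    ramp_off = np.clip((config.stim_duration_s + _OFFSET_DECAY_S - t) / _OFFSET_DECAY_S, 0.0, 1.0)
    steady = ramp_on * ramp_off * np.sin(2 * np.pi * f_mod * t + trial_phase)
    return transient + steady


# ---------------------------------------------------------------------------
# sensor layouts and forward mixing
# ---------------------------------------------------------------------------

def make_channel_info(config: SimulationConfig) -> list[ChannelInfo]:
    """Deterministic per-modality channel layout with position tags."""
    m = config.modality
    chs: list[ChannelInfo] = []
    if m == "EEG":
        n_scalp = config.n_channels - 1
        if n_scalp < 12:
            raise ValueError("EEG layout needs at least 12 scalp channels + EOG")
        tags = (
            ["frontocentral"] * 10
            + ["frontal"] * 4
            + ["temporal_left"] * 3
            + ["temporal_right"] * 3
        )
        rest = n_scalp - len(tags)
        tags += ["parietal" if i % 2 == 0 else "occipital" for i in range(max(rest, 0))]
        tags = tags[:n_scalp]
        for i, tag in enumerate(tags):
            chs.append(ChannelInfo(label=f"EEG{i:03d}", modality="EEG", position_tag=tag))
        chs.append(ChannelInfo(label="EOG", modality="EEG", position_tag="eog"))
    elif m == "OPM":
        if config.n_channels % 2 != 0:
            raise ValueError("OPM channel count must be even (two axes per site)")
        n_sites = config.n_channels // 2
        if n_sites < 4:
            raise ValueError("OPM layout needs at least 4 sites")
        n_left = (n_sites + 1) // 2
        for s in range(n_sites):
            side = "temporal_left" if s < n_left else "temporal_right"
            for axis in ("rad", "tan"):
                chs.append(
                    ChannelInfo(
                        label=f"OPM{s:02d}_{axis}",
                        modality="OPM",
                        position_tag=side,
                        axis=axis,
                        site=s,
                    )
                )
    elif m == "SQUID":
        n = config.n_channels
        if n < 24:
            raise ValueError("SQUID layout needs at least 24 channels")
        left = _squid_cluster_indices(n, "left")
        right = _squid_cluster_indices(n, "right")
        frontal = set(range(min(8, n // 10)))
        for i in range(n):
            if i in left:
                tag = "temporal_left"
            elif i in right:
                tag = "temporal_right"
            elif i in frontal:
                tag = "frontal"
            else:
                tag = "other"
            chs.append(ChannelInfo(label=f"MEG{i:03d}", modality="SQUID", position_tag=tag))
    return chs


def _squid_cluster_indices(n: int, side: str) -> list[int]:
    start = n // 4 if side == "left" else (3 * n) // 4 - 2
    return list(range(start, start + 5))


def _cluster_profile(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Radial (sign-flipping, dipolar) and tangential profiles across a cluster."""
    if m == 1:
        return np.array([1.0]), np.array([0.6])
    k = np.arange(m)
    radial = np.cos(np.pi * k / (m - 1))          # +1 ... -1 across the cluster
    tangential = 0.6 * np.sin(np.pi * k / (m - 1))  # peaked mid-cluster, reduced gain
    return radial, tangential


def forward_pattern(config: SimulationConfig,
                    channel_info: list[ChannelInfo] | None = None) -> np.ndarray:
    """Fixed per-modality mixing vector (peak radial gain 1, modality units applied later)."""
    if channel_info is None:
        channel_info = make_channel_info(config)
    m = config.modality
    w = np.zeros(len(channel_info))
    if m == "EEG":
        gains = {
            "frontocentral": 1.0,
            "frontal": 0.75,
            "parietal": 0.45,
            "temporal_left": 0.35,
            "temporal_right": 0.35,
            "occipital": 0.2,
            "eog": 0.02,
        }
        # broad topography + a smooth taper across the fronto-central group:
        # wide spatial autocorrelation stands in for volume-conduction smearing
        fc_seen = 0
        for i, c in enumerate(channel_info):
            g = gains.get(c.position_tag, 0.2)
            if c.position_tag == "frontocentral":
                g *= 0.85 + 0.15 * np.cos(np.pi * fc_seen / 9)
                fc_seen += 1
            w[i] = g
    else:
        for side in ("temporal_left", "temporal_right"):
            if m == "OPM":
                sites = sorted({c.site for c in channel_info if c.position_tag == side})
                rad, tan = _cluster_profile(len(sites))
                for i, c in enumerate(channel_info):
                    if c.position_tag != side:
                        continue
                    k = sites.index(c.site)
                    w[i] = rad[k] if c.axis == "rad" else tan[k]
            else:
                idx = [i for i, c in enumerate(channel_info) if c.position_tag == side]
                rad, _ = _cluster_profile(len(idx))
                for k, i in enumerate(idx):
                    w[i] = rad[k]
        if m == "SQUID":
            # weak residual field on the remaining gradiometers, decaying with
            # index distance from the nearest temporal cluster
            cl = [i for i, c in enumerate(channel_info)
                  if c.position_tag in ("temporal_left", "temporal_right")]
            for i, c in enumerate(channel_info):
                if w[i] == 0.0:
                    d = min(abs(i - j) for j in cl)
                    w[i] = 0.3 * np.exp(-d / 6.0) * (1 if (i % 2 == 0) else -1)
    return w


def mix_to_sensors(source: np.ndarray, config: SimulationConfig,
                   channel_info: list[ChannelInfo] | None = None) -> np.ndarray:
    """Project a source time series to sensors: channels x samples, modality units."""
    if channel_info is None:
        channel_info = make_channel_info(config)
    if len(channel_info) != config.n_channels:
        raise ValueError("channel_info does not match configured channel count")
    pattern = forward_pattern(config, channel_info)
    gain = config.evoked_amplitude
    if config.modality == "OPM":
        gain *= config.amplitude_factor_vs_squid
    return np.outer(pattern * gain, np.asarray(source, dtype=float))


# ---------------------------------------------------------------------------
# noise and artifacts
# ---------------------------------------------------------------------------

def _one_over_f_timecourse(n: int, fs: float, asd_10hz: float, exponent: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^a (power) noise with one-sided ASD anchored at 10 Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    asd = np.zeros_like(freqs)
    nz = freqs > 0
    f_eff = np.maximum(freqs[nz], 0.5)  # flatten below 0.5 Hz to avoid DC blowup
    asd[nz] = asd_10hz * (10.0 / f_eff) ** (exponent / 2.0)
    # E|X_k|^2 = asd^2 * fs * n / 2 gives a periodogram matching the target ASD
    scale = asd * np.sqrt(fs * n / 2.0)
    coeffs = scale * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2.0)
    coeffs[0] = 0.0
    if n % 2 == 0:
        coeffs[-1] = coeffs[-1].real * np.sqrt(2.0)
    return np.fft.irfft(coeffs, n=n)


def _blink_template(fs: float, tau_s: float = 0.045) -> np.ndarray:
    """Blink deflection: fast ~50 ms rise with a slower decay (~0.35 s total).

    The asymmetric shape keeps part of the blink energy above 5 Hz, as real
    blinks do, so band-limited decompositions can still isolate it.
    """
    n = int(round(0.35 * fs))
    t = np.arange(n) / fs
    return (t / tau_s) * np.exp(1.0 - t / tau_s)


def _blink_pattern(channel_info: list[ChannelInfo]) -> np.ndarray:
    w = np.zeros(len(channel_info))
    eeg_gain = {"eog": 1.0, "frontal": 0.6, "frontocentral": 0.35}
    for i, c in enumerate(channel_info):
        if c.modality == "EEG":
            w[i] = eeg_gain.get(c.position_tag, 0.1)
        elif c.modality == "SQUID":
            w[i] = 0.6 if c.position_tag == "frontal" else 0.08
        else:  # OPM: anterior sites pick up more of the ocular field
            w[i] = 0.4 * np.exp(-max(c.site, 0) / 2.0) + 0.1
    return w


def add_noise_and_artifacts(clean: ContinuousRecording,
                            config: SimulationConfig) -> ContinuousRecording:
    """Add white sensor noise, 1/f background, 50 Hz line noise and artifacts.

    Deterministic given (config, seed); with all noise/artifact parameters at
    zero the input is returned unchanged (a no-op).
    """
    if config.noise_density < 0:
        raise ValueError("noise density must be non-negative")
    fs = clean.sampling_rate_hz
    n_ch, n_samp = clean.data.shape
    out = clean.data.copy()
    rng = _rng(config, 2)

    if config.noise_density > 0:
        sigma = config.noise_density * np.sqrt(fs / 2.0)
        out += sigma * rng.standard_normal((n_ch, n_samp))

    if config.background_asd_10hz > 0:
        k_src = int(config.n_background_sources)
        pats = rng.standard_normal((k_src, n_ch))
        if config.modality == "EEG":
            # smooth patterns across the channel index: spatially smeared background
            kernel = np.hanning(9)
            kernel /= kernel.sum()
            pats = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, pats)
        pats /= np.linalg.norm(pats, axis=0, keepdims=True) + 1e-30
        for k in range(k_src):
            tc = _one_over_f_timecourse(n_samp, fs, config.background_asd_10hz,
                                        config.background_exponent, rng)
            out += np.outer(pats[k], tc)

    if config.line_amplitude > 0:
        t = np.arange(n_samp) / fs
        phase = rng.uniform(0, 2 * np.pi)
        amps = config.line_amplitude * (0.5 + rng.random(n_ch))
        out += np.outer(amps, np.sin(2 * np.pi * config.line_noise_hz * t + phase))

    rng_art = _rng(config, 3)
    dur_min = n_samp / fs / 60.0

    artifact_log = list(clean.artifact_log)

    if config.blink_rate_per_min > 0 and config.blink_amplitude > 0:
        n_blinks = rng_art.poisson(config.blink_rate_per_min * dur_min)
        tmpl = _blink_template(fs)
        pat = _blink_pattern(clean.channel_info) * config.blink_amplitude
        for _ in range(n_blinks):
            start = int(rng_art.integers(0, max(n_samp - tmpl.size, 1)))
            amp = float(rng_art.uniform(0.7, 1.3))
            out[:, start:start + tmpl.size] += amp * np.outer(pat, tmpl)
            artifact_log.append({"kind": "blink", "sample_index": start,
                                 "n_samples": int(tmpl.size), "amplitude": amp})

    if config.muscle_rate_per_min > 0 and config.muscle_amplitude > 0:
        if fs / 2.0 > 140.0:
            n_bursts = rng_art.poisson(config.muscle_rate_per_min * dur_min)
            sos = signal.butter(4, [110.0, 140.0], btype="bandpass", fs=fs, output="sos")
            blen = int(round(0.3 * fs))
            for _ in range(n_bursts):
                start = int(rng_art.integers(0, max(n_samp - blen, 1)))
                n_hit = int(rng_art.integers(3, min(7, n_ch + 1)))
                hit = rng_art.choice(n_ch, size=n_hit, replace=False)
                burst = signal.sosfilt(sos, rng_art.standard_normal(blen))
                burst *= config.muscle_amplitude / (np.std(burst) + 1e-30)
                taper = np.hanning(blen)
                for c in hit:
                    out[c, start:start + blen] += burst * taper
                artifact_log.append({"kind": "muscle", "sample_index": start,
                                     "n_samples": blen,
                                     "channels": [int(c) for c in hit]})

    return ContinuousRecording(
        data=out,
        sampling_rate_hz=fs,
        channel_info=clean.channel_info,
        events=clean.events,
        participant_id=clean.participant_id,
        artifact_log=artifact_log,
    )


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def simulate_session(config: SimulationConfig, participant_id: str = "sim") -> ContinuousRecording:
    """Generate a complete continuous session (signal + noise + artifacts)."""
    schedule = make_stimulus_schedule(config)
    fs = config.sampling_rate_hz
    n_samp = int(round(schedule.total_duration_s * fs))
    channel_info = make_channel_info(config)
    pattern = forward_pattern(config, channel_info)
    gain = config.evoked_amplitude
    if config.modality == "OPM":
        gain *= config.amplitude_factor_vs_squid
    data = np.zeros((len(channel_info), n_samp))

    rng_phase = _rng(config, 1)
    events: list[Event] = []
    for onset, cond in zip(schedule.onsets_s, schedule.conditions):
        phase = rng_phase.normal(0.0, config.phase_jitter_sd_rad) if config.phase_jitter_sd_rad > 0 else 0.0
        src = synthesize_source_waveform(cond, config, trial_phase=phase)
        start = int(round(onset * fs))
        stop = min(start + src.size, n_samp)
        data[:, start:stop] += np.outer(pattern * gain, src[: stop - start])
        events.append(Event(sample_index=start, condition=cond))

    clean = ContinuousRecording(
        data=data,
        sampling_rate_hz=fs,
        channel_info=channel_info,
        events=events,
        participant_id=participant_id,
    )
    return add_noise_and_artifacts(clean, config)


# ---------------------------------------------------------------------------
# cable-interference estimate
# ---------------------------------------------------------------------------

def estimate_cable_interference(distance_m: float,
                                current_a: float | None = None,
                                voltage_v: float | None = None,
                                resistance_ohm: float | None = None,
                                mu0: float = VACUUM_PERMEABILITY) -> float:
    """Magnetic field of a long straight cable: B = mu0 * I / (2 pi r), tesla.

    The current may be given directly or as ``voltage_v / resistance_ohm``
    (e.g. the EEG signal amplitude over the amplifier input impedance, for
    estimating whether electrode cables can disturb co-located OPM sensors).
    """
    if distance_m <= 0:
        raise ValueError("distance must be strictly positive")
    if current_a is None:
        if voltage_v is None or resistance_ohm is None:
            raise ValueError("provide current_a or (voltage_v, resistance_ohm)")
        if resistance_ohm <= 0:
            raise ValueError("resistance must be strictly positive")
        current_a = voltage_v / resistance_ohm
    return mu0 * current_a / (2.0 * math.pi * distance_m)
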