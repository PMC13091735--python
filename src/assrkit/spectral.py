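"""Spectral power, inter-trial phase coherence, and SNR statistics.

Power of the trial average uses a sliding Hanning taper whose duration is 7
cycles of the analysis frequency (1-60 Hz, 0.5 Hz steps, time points within
0.25-1 s). ITPC uses a 7-cycle Gaussian (Morlet-family) wavelet on a 0.1 Hz
grid between -1 and 2 s with 0.25 s resolution; ITPC(f, t) is the magnitude
of the across-trial mean unit phasor. SNR is the linear ratio of 40 Hz power
to the mean over 20-38 and 42-48 Hz; the ITPC-ratio uses a 20-30 Hz noise
band to keep spectral smearing of the signal out of the denominator.

Frequencies whose 7-cycle window cannot fit inside the epoch are marked
invalid (NaN), never imputed.
"""
from __future__ import annotations

import numpy as np

from .containers import SnrResult, SpectroTemporalMap, TrialCountCurve, VirtualChannelEpochs

POWER_FREQS_HZ = np.arange(1.0, 60.0 + 1e-9, 0.5)
ITPC_FREQS_HZ = np.round(np.arange(1.0, 60.0 + 1e-9, 0.1), 1)
ITPC_TIMES_S = np.arange(-1.0, 2.0 + 1e-9, 0.25)
POWER_WINDOW_S = (0.25, 1.0)
POWER_TIME_STEP_S = 0.05
POWER_NOISE_BAND = ((20.0, 38.0), (42.0, 48.0))
ITPC_NOISE_BAND = ((20.0, 30.0),)
ITPC_STIM_TIMES_S = (0.25, 0.5, 0.75, 1.0)
DEFAULT_BINS = (1, 10, 20, 30, 40, 50, 60, 70, 80)

#: Gaussian wavelet temporal width for an n-cycle wavelet: sigma_t = n / (2 pi f)
WAVELET_CYCLES = 7.0
#: taper/window truncation half-width in units of sigma_t
WAVELET_GWIDTH = 3.0


def _odd_window_len(duration_s: float, fs: float) -> int:
    n = int(round(duration_s * fs))
    return max(n + (1 - n % 2), 3)


def _hann_coeff(x: np.ndarray, fs: float, t0_index: int, f: float,
                center_idx: int) -> complex:
    """Hanning-tapered complex demodulate at one (f, t) point, amplitude-normalized."""
    n = _odd_window_len(WAVELET_CYCLES / f, fs)
    half = n // 2
    lo, hi = center_idx - half, center_idx + half + 1
    if lo < 0 or hi > x.size:
        return np.nan + 0j
    w = np.hanning(n)
    tt = (np.arange(lo, hi) - t0_index) / fs
    kern = w * np.exp(-2j * np.pi * f * tt)
    return 2.0 * np.dot(x[lo:hi], kern) / w.sum()


def power_of_average(virtual: VirtualChannelEpochs,
                     trial_rows: np.ndarray | list | None = None,
                     freqs_hz: np.ndarray = POWER_FREQS_HZ,
                     window_s: tuple[float, float] = POWER_WINDOW_S,
                     time_step_s: float = POWER_TIME_STEP_S) -> SpectroTemporalMap:
    """Time-frequency power of the trial average (average first, then transform)."""
    if trial_rows is not None and len(trial_rows) == 0:
        raise ValueError("empty trial selection")
    avg = virtual.average(trial_rows)
    n_used = virtual.n_trials if trial_rows is None else len(trial_rows)
    fs = virtual.sampling_rate_hz
    t = virtual.time_axis_s
    t0 = int(np.argmin(np.abs(t)))

    times = np.arange(window_s[0], window_s[1] + 1e-9, time_step_s)
    centers = np.array([t0 + int(round(tt * fs)) for tt in times])
    vals = np.full((freqs_hz.size, times.size), np.nan)
    for i, f in enumerate(freqs_hz):
        for j, c in enumerate(centers):
            coeff = _hann_coeff(avg, fs, t0, f, c)
            if not np.isnan(coeff):
                vals[i, j] = np.abs(coeff) ** 2
    return SpectroTemporalMap(values=vals, freqs_hz=freqs_hz, times_s=times,
                              kind="power_of_average", n_trials_used=n_used)


# ---------------------------------------------------------------------------
# wavelet ITPC
# ---------------------------------------------------------------------------

def wavelet_coefficients(virtual: VirtualChannelEpochs,
                         freqs_hz: np.ndarray = ITPC_FREQS_HZ,
                         times_s: np.ndarray = ITPC_TIMES_S) -> np.ndarray:
    """Per-trial complex Gaussian-wavelet coefficients: (trials, freqs, times).

    Invalid (window does not fit) cells are NaN. Exposed so trial-count curves
    can reuse one decomposition across bins.
    """
    fs = virtual.sampling_rate_hz
    t = virtual.time_axis_s
    t0 = int(np.argmin(np.abs(t)))
    n_samp = virtual.data.shape[1]
    coeffs = np.full((virtual.n_trials, freqs_hz.size, times_s.size), np.nan, dtype=complex)

    centers = np.array([t0 + int(round(tt * fs)) for tt in times_s])
    for i, f in enumerate(freqs_hz):
        sigma_t = WAVELET_CYCLES / (2.0 * np.pi * f)
        half = int(round(WAVELET_GWIDTH * sigma_t * fs))
        n = 2 * half + 1
        tt = (np.arange(-half, half + 1)) / fs
        kern = np.exp(-(tt ** 2) / (2 * sigma_t ** 2)) * np.exp(-2j * np.pi * f * tt)
        for j, c in enumerate(centers):
            lo, hi = c - half, c + half + 1
            if lo < 0 or hi > n_samp:
                continue
            # anchor phase to stimulus onset rather than the window center
            phase_shift = np.exp(-2j * np.pi * f * t[c])
            coeffs[:, i, j] = (virtual.data[:, lo:hi] @ kern) * phase_shift
    return coeffs


def itpc_from_coefficients(coeffs: np.ndarray, trial_rows=None) -> np.ndarray:
    if trial_rows is not None:
        coeffs = coeffs[list(trial_rows)]
    mag = np.abs(coeffs)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(mag > 0, coeffs / mag, np.nan + 0j)
        itpc = np.abs(unit.mean(axis=0))
    # any invalid or zero-magnitude trial cell invalidates that (f, t) cell
    itpc[np.any(~np.isfinite(mag) | (mag == 0), axis=0)] = np.nan
    valid = np.isfinite(itpc)
    itpc[valid] = np.clip(itpc[valid], 0.0, 1.0)
    return itpc


def itpc_map(virtual: VirtualChannelEpochs,
             trial_rows: np.ndarray | list | None = None,
             freqs_hz: np.ndarray = ITPC_FREQS_HZ,
             times_s: np.ndarray = ITPC_TIMES_S,
             coeffs: np.ndarray | None = None) -> SpectroTemporalMap:
    """Inter-trial phase coherence map; undefined for fewer than two trials."""
    n_used = virtual.n_trials if trial_rows is None else len(trial_rows)
    if n_used < 2:
        raise ValueError("ITPC requires at least two trials")
    if coeffs is None:
        coeffs = wavelet_coefficients(virtual, freqs_hz, times_s)
    vals = itpc_from_coefficients(coeffs, trial_rows)
    return SpectroTemporalMap(values=vals, freqs_hz=freqs_hz, times_s=times_s,
                              kind="itpc", n_trials_used=n_used)


# ---------------------------------------------------------------------------
# SNR statistics
# ---------------------------------------------------------------------------

def _band_rows(freqs: np.ndarray, bands) -> np.ndarray:
    sel = np.zeros(freqs.size, dtype=bool)
    for lo, hi in bands:
        sel |= (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return sel


def snr_from_power(tfmap: SpectroTemporalMap,
                   signal_freq_hz: float = 40.0,
                   noise_band_hz=POWER_NOISE_BAND) -> SnrResult:
    """power(40 Hz) over mean power across the noise bands, time-averaged first."""
    if tfmap.kind != "power_of_average":
        raise ValueError("snr_from_power expects a power_of_average map")
    sig_rows = np.isclose(tfmap.freqs_hz, signal_freq_hz)
    if not np.any(sig_rows):
        raise ValueError(f"no {signal_freq_hz} Hz bin in the map")
    noise_rows = _band_rows(tfmap.freqs_hz, noise_band_hz)
    if not np.any(noise_rows):
        raise ValueError("empty noise band")

    valid_t = np.all(np.isfinite(tfmap.values[sig_rows | noise_rows][:, :]), axis=0)
    if not np.any(valid_t):
        raise ValueError("no valid time points for the SNR bands")
    num = tfmap.values[sig_rows][:, valid_t].mean()
    den = tfmap.values[noise_rows][:, valid_t].mean()
    return SnrResult(snr=float(num / den), metric="power_snr",
                     n_trials=tfmap.n_trials_used, signal_freq_hz=signal_freq_hz,
                     noise_band_hz=tuple(tuple(b) for b in noise_band_hz))


def itpc_ratio(tfmap: SpectroTemporalMap,
               signal_freq_hz: float = 40.0,
               noise_band_hz=ITPC_NOISE_BAND,
               stim_times_s=ITPC_STIM_TIMES_S) -> SnrResult:
    """ITPC at 40 Hz over mean 20-30 Hz ITPC, averaged over stimulation-phase times."""
    if tfmap.kind != "itpc":
        raise ValueError("itpc_ratio expects an itpc map")
    sig_rows = np.isclose(tfmap.freqs_hz, signal_freq_hz)
    if not np.any(sig_rows):
        raise ValueError(f"no {signal_freq_hz} Hz bin in the map")
    noise_rows = _band_rows(tfmap.freqs_hz, noise_band_hz)
    if not np.any(noise_rows):
        raise ValueError("empty noise band")
    t_rows = np.zeros(tfmap.times_s.size, dtype=bool)
    for tt in stim_times_s:
        t_rows |= np.isclose(tfmap.times_s, tt)
    if not np.any(t_rows):
        raise ValueError("no stimulation-phase time points on the grid")

    num = np.nanmean(tfmap.values[np.ix_(sig_rows, t_rows)])
    den = np.nanmean(tfmap.values[np.ix_(noise_rows, t_rows)])
    if not np.isfinite(num) or not np.isfinite(den) or den <= 0:
        raise ValueError("SNR bands contain no valid values")
    return SnrResult(snr=float(num / den), metric="itpc_ratio",
                     n_trials=tfmap.n_trials_used, signal_freq_hz=signal_freq_hz,
                     noise_band_hz=tuple(tuple(b) for b in noise_band_hz))


# ---------------------------------------------------------------------------
# trial-count analysis
# ---------------------------------------------------------------------------

def trial_count_curve(virtual: VirtualChannelEpochs,
                      bins=DEFAULT_BINS,
                      metric: str = "power_snr") -> TrialCountCurve:
    """Metric as a function of trial count, always using the FIRST k retained
    trials (chronological order, as in a shorter real experiment)."""
    bins = np.asarray(sorted(set(int(b) for b in bins)), dtype=int)
    if bins.max() > virtual.n_trials:
        raise ValueError(
            f"bin {bins.max()} exceeds the {virtual.n_trials} retained trials"
        )
    if metric not in ("power_snr", "itpc_ratio"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "itpc_ratio" and bins.min() < 2:
        raise ValueError("ITPC is undefined for a single trial; bins must start at >= 2")

    results: list[SnrResult] = []
    coeffs = wavelet_coefficients(virtual) if metric == "itpc_ratio" else None
    for k in bins:
        rows = np.arange(k)
        if metric == "power_snr":
            res = snr_from_power(power_of_average(virtual, rows))
        else:
            res = itpc_ratio(itpc_map(virtual, rows, coeffs=coeffs))
        res.modality = virtual.modality
        res.participant_id = virtual.participant_id
        results.append(res)
    return TrialCountCurve(bins=bins, results=results, metric=metric,
                           participant_id=virtual.participant_id,
                           modality=virtual.modality)


def percent_increase(v_mod1: float, v_mod2: float, baseline: str = "mod2") -> float:
    """Percent SNR increase between modalities: (v1 - v2) / v_baseline * 100.

    Default baseline is the comparison (second) value, matching the scale on
    which multi-hundred-percent increases are expressed; ``baseline="mod1"``
    gives the literal first-value normalization.
    """
    ref = v_mod2 if baseline == "mod2" else v_mod1
    if baseline not in ("mod1", "mod2"):
        raise ValueError("baseline must be 'mod1' or 'mod2'")
    if ref == 0:
        raise ValueError("zero baseline value")
    return (v_mod1 - v_mod2) / ref * 100.0


def summarize_group(curves: list[TrialCountCurve]):
    """Per (modality, bin) mean, SEM (sd/sqrt(n); NaN for n=1), min and max."""
    import pandas as pd

    if not curves:
        raise ValueError("no curves to summarize")
    bins0 = curves[0].bins
    for c in curves:
        if not np.array_equal(c.bins, bins0):
            raise ValueError("all curves must share the same bins")
    rows = []
    for c in curves:
        for b, v in zip(c.bins, c.values):
            rows.append({"participant": c.participant_id, "modality": c.modality,
                         "metric": c.metric, "bin": int(b), "value": float(v)})
    df = pd.DataFrame(rows)
    g = df.groupby(["modality", "metric", "bin"])["value"]
    out = g.agg(mean="mean", sem=lambda x: np.std(x, ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
                min="min", max="max", n="count").reset_index()
    return out
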