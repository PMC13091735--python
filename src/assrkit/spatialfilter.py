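"""Canonical-correlation spatial filter, virtual channel and polarity fix.

The filter maximizes the covariance between band-limited (39-41 Hz) single
trials and the band-limited trial average within the stimulation window
(0.25-1 s). The arrangement is: X = channel-space single trials concatenated
over the fit window, Y = the time-locked average tiled per trial; only the
first canonical pair is kept. The channel-side weight vector summarizes all
channels into one virtual channel; because canonical correlation is blind to
sign, polarity is fixed afterwards against an extrema template built from the
plain (unweighted) grand average.
"""
from __future__ import annotations

import numpy as np
from scipy import linalg

from .containers import EpochSet, SpatialFilterSpec, VirtualChannelEpochs
from .preprocess import filter_array

TEMPORAL_TAGS = ("temporal_left", "temporal_right")


# ---------------------------------------------------------------------------
# channel subset selection
# ---------------------------------------------------------------------------

def select_channel_subset(epochs: EpochSet, n: int = 10,
                          topography: np.ndarray | dict | None = None) -> EpochSet:
    """Reduce to the comparison subset of ``n`` sensor positions.

    OPM/SQUID: the 5 left + 5 right temporal-tagged positions (for dual-axis
    OPM both axes of each selected site are retained, so the channel count is
    2n while the site count is n). EEG: the n electrodes with the highest
    group-average 40 Hz response amplitude (``topography``, one value per
    channel or a label->amplitude mapping; EOG excluded).
    """
    if epochs.modality in ("OPM", "SQUID"):
        n_side = n // 2
        picked: list[int] = []
        for tag in TEMPORAL_TAGS:
            if epochs.modality == "OPM":
                sites = sorted({c.site for c in epochs.channel_info if c.position_tag == tag})
                if len(sites) < n_side:
                    raise ValueError(f"only {len(sites)} {tag} sites available, need {n_side}")
                keep_sites = set(sites[:n_side])
                picked += [i for i, c in enumerate(epochs.channel_info)
                           if c.position_tag == tag and c.site in keep_sites]
            else:
                idx = [i for i, c in enumerate(epochs.channel_info) if c.position_tag == tag]
                if len(idx) < n_side:
                    raise ValueError(f"only {len(idx)} {tag} channels available, need {n_side}")
                picked += idx[:n_side]
        return epochs.pick_channels(sorted(picked))

    if epochs.modality == "EEG":
        if topography is None:
            raise ValueError("EEG subset selection requires a group-average 40 Hz topography")
        labels = epochs.channel_labels()
        if isinstance(topography, dict):
            amp = np.array([topography.get(lbl, -np.inf) for lbl in labels])
        else:
            amp = np.asarray(topography, dtype=float)
            if amp.size != epochs.n_channels:
                raise ValueError("topography length does not match channel count")
        eligible = [i for i, c in enumerate(epochs.channel_info) if c.position_tag != "eog"]
        if len(eligible) < n:
            raise ValueError(f"only {len(eligible)} scalp channels available, need {n}")
        order = sorted(eligible, key=lambda i: -amp[i])
        return epochs.pick_channels(sorted(order[:n]))

    raise ValueError(f"unknown modality {epochs.modality!r}")


def topography_40hz(epochs: EpochSet, band: tuple[float, float] = (39.0, 41.0),
                    window_s: tuple[float, float] = (0.25, 1.0)) -> np.ndarray:
    """Per-channel 40 Hz response amplitude (RMS of the band-passed trial average)."""
    avg = epochs.data.mean(axis=0)
    flt = filter_array(avg, band, epochs.sampling_rate_hz, "bandpass")
    sel = (epochs.time_axis_s >= window_s[0]) & (epochs.time_axis_s <= window_s[1])
    return np.sqrt((flt[:, sel] ** 2).mean(axis=1))


def group_topography_40hz(epochs_list: list[EpochSet]) -> np.ndarray:
    """Group-average 40 Hz amplitude topography (channels aligned across inputs)."""
    if not epochs_list:
        raise ValueError("empty epochs list")
    return np.mean([topography_40hz(e) for e in epochs_list], axis=0)


# ---------------------------------------------------------------------------
# CCA fit
# ---------------------------------------------------------------------------

def fit_cca_filter(epochs: EpochSet,
                   fit_band_hz: tuple[float, float] = (39.0, 41.0),
                   fit_window_s: tuple[float, float] = (0.25, 1.0),
                   ridge_rel: float = 1e-6) -> SpatialFilterSpec:
    """First canonical weight vector between single trials and the trial average.

    ``ridge_rel`` scales a ridge term (x mean covariance trace) added to both
    channel covariances; needed e.g. for rank-deficient average-referenced EEG.
    The returned weights are unit-norm with an arbitrary but reproducible sign
    (fixed later by the polarity algorithm).
    """
    if epochs.n_channels < 1:
        raise ValueError("need at least one channel")
    sel = (epochs.time_axis_s >= fit_window_s[0]) & (epochs.time_axis_s <= fit_window_s[1])
    if not np.any(sel):
        raise ValueError("empty fit window")

    flt = filter_array(epochs.data, fit_band_hz, epochs.sampling_rate_hz, "bandpass")
    trials = flt[:, :, sel]                       # trials x channels x T
    n_tr, n_ch, n_t = trials.shape

    if n_ch == 1:
        return SpatialFilterSpec(weights=np.array([1.0]), fit_band_hz=fit_band_hz,
                                 fit_window_s=fit_window_s, canonical_correlation_value=1.0)
    if n_tr < 2:
        raise ValueError("need at least two trials to fit the filter")

    avg = trials.mean(axis=0)                     # channels x T
    X = trials.transpose(1, 0, 2).reshape(n_ch, n_tr * n_t)
    Y = np.tile(avg, (1, n_tr))

    X = X - X.mean(axis=1, keepdims=True)
    Y = Y - Y.mean(axis=1, keepdims=True)
    m = X.shape[1]
    Cxx = X @ X.T / (m - 1)
    Cyy = Y @ Y.T / (m - 1)
    Cxy = X @ Y.T / (m - 1)

    if ridge_rel > 0:
        Cxx = Cxx + ridge_rel * (np.trace(Cxx) / n_ch) * np.eye(n_ch)
        Cyy = Cyy + ridge_rel * (np.trace(Cyy) / n_ch) * np.eye(n_ch)

    try:
        L = linalg.cholesky(Cxx, lower=True)
        W = linalg.solve_triangular(L, Cxy, lower=True)        # L^-1 Cxy
        S = W @ linalg.solve(Cyy, W.T, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "rank-deficient channel covariance; pass ridge_rel > 0 to regularize"
        ) from exc
    S = 0.5 * (S + S.T)
    vals, vecs = linalg.eigh(S)
    rho2 = float(np.clip(vals[-1], 0.0, 1.0))
    u = vecs[:, -1]
    w = linalg.solve_triangular(L, u, lower=True, trans="T")   # L^-T u

    w = w / np.linalg.norm(w)
    k = int(np.argmax(np.abs(w)))
    if w[k] < 0:                                  # reproducible provisional sign
        w = -w
    return SpatialFilterSpec(weights=w, fit_band_hz=fit_band_hz,
                             fit_window_s=fit_window_s,
                             canonical_correlation_value=float(np.sqrt(rho2)))


def apply_filter(epochs: EpochSet, spec: SpatialFilterSpec) -> VirtualChannelEpochs:
    """virtual(trial, t) = polarity_sign * sum_c w_c x_c(trial, t), full band."""
    if spec.weights.size != epochs.n_channels:
        raise ValueError(
            f"filter has {spec.weights.size} weights but epochs have "
            f"{epochs.n_channels} channels"
        )
    virt = spec.polarity_sign * np.einsum("c,tcs->ts", spec.weights, epochs.data)
    return VirtualChannelEpochs(
        data=virt,
        time_axis_s=epochs.time_axis_s,
        sampling_rate_hz=epochs.sampling_rate_hz,
        kept_trial_ids=epochs.kept_trial_ids,
        provenance={
            "filter": spec,
            "source_participant": epochs.participant_id,
            "source_modality": epochs.modality,
        },
        participant_id=epochs.participant_id,
        modality=epochs.modality,
    )


# ---------------------------------------------------------------------------
# polarity correction
# ---------------------------------------------------------------------------

def build_extrema_template(grand_average: np.ndarray, time_axis_s: np.ndarray,
                           min_separation_s: float = 0.025,
                           window_s: tuple[float, float] = (0.0, 1.0)) -> list[dict]:
    """Local extrema of the (unweighted) grand average within the stimulation window.

    Extrema are sign changes of the discrete first difference; extrema closer
    than ``min_separation_s`` (default one 40 Hz cycle) are merged keeping the
    larger magnitude. Returns ``[{"sample_index": i, "type": "min"|"max"}]``
    with indices into the epoch time axis.
    """
    x = np.asarray(grand_average, dtype=float)
    t = np.asarray(time_axis_s, dtype=float)
    if x.shape != t.shape:
        raise ValueError("grand average and time axis must be parallel")
    if np.ptp(x) == 0:
        raise ValueError("constant input has no extrema")

    # first-difference signs with flat runs backward-filled, so an extremum
    # landing exactly between two samples (d == 0) is still detected
    d = np.diff(x)
    s = np.sign(d)
    for i in range(s.size - 2, -1, -1):
        if s[i] == 0:
            s[i] = s[i + 1]

    ext: list[dict] = []
    for i in range(1, x.size - 1):
        if not (window_s[0] <= t[i] <= window_s[1]):
            continue
        if s[i - 1] > 0 and s[i] < 0:
            ext.append({"sample_index": i, "type": "max"})
        elif s[i - 1] < 0 and s[i] > 0:
            ext.append({"sample_index": i, "type": "min"})
    if not ext:
        raise ValueError("no extrema found in the stimulation window")

    # merge same-type neighbors closer than min_separation (half-sample
    # tolerance: discrete extrema of a perfect oscillation alternate between
    # floor/ceil sample gaps), keeping the larger deviation from the mean
    dt = float(np.median(np.diff(t)))
    thresh = min_separation_s - 0.51 * dt
    center = x[[e["sample_index"] for e in ext]].mean()
    merged: list[dict] = []
    for kind in ("max", "min"):
        kept: list[dict] = []
        for e in (e for e in ext if e["type"] == kind):
            if kept and (t[e["sample_index"]] - t[kept[-1]["sample_index"]]) < thresh:
                if abs(x[e["sample_index"]] - center) > abs(x[kept[-1]["sample_index"]] - center):
                    kept[-1] = e
            else:
                kept.append(e)
        merged.extend(kept)
    return sorted(merged, key=lambda e: e["sample_index"])


def fix_polarity(virtual: VirtualChannelEpochs,
                 extrema_template: list[dict]) -> VirtualChannelEpochs:
    """Flip the virtual channel if template minima average above template maxima.

    The template indices come from the grand average over all participants and
    channels (computed without canonical correlation) and are evaluated on
    this individual's trial-average virtual channel. Idempotent.
    """
    if not extrema_template:
        raise ValueError("extrema template is empty")
    idx = np.array([e["sample_index"] for e in extrema_template], dtype=int)
    if idx.min() < 0 or idx.max() >= virtual.data.shape[1]:
        raise ValueError("template index out of range for this epoch")
    kinds = np.array([e["type"] for e in extrema_template])
    if "min" not in kinds or "max" not in kinds:
        raise ValueError("template must contain both minima and maxima")

    avg = virtual.average()
    mean_min = avg[idx[kinds == "min"]].mean()
    mean_max = avg[idx[kinds == "max"]].mean()
    sign = -1 if mean_min > mean_max else 1

    prov = dict(virtual.provenance)
    prov["polarity_sign"] = sign
    spec = prov.get("filter")
    if isinstance(spec, SpatialFilterSpec):
        prov["filter"] = SpatialFilterSpec(
            weights=spec.weights,
            polarity_sign=sign * spec.polarity_sign,
            fit_band_hz=spec.fit_band_hz,
            fit_window_s=spec.fit_window_s,
            canonical_correlation_value=spec.canonical_correlation_value,
        )
    return VirtualChannelEpochs(
        data=sign * virtual.data,
        time_axis_s=virtual.time_axis_s,
        sampling_rate_hz=virtual.sampling_rate_hz,
        kept_trial_ids=virtual.kept_trial_ids,
        provenance=prov,
        participant_id=virtual.participant_id,
        modality=virtual.modality,
    )


def plot_virtual_average(virtual: VirtualChannelEpochs, ax=None):
    """Diagnostic plot of the trial-average virtual channel (polarity check)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(virtual.time_axis_s, virtual.average(), lw=0.8)
    ax.axvspan(0, 1, alpha=0.1, color="tab:orange")
    ax.set(xlabel="time (s)", ylabel="virtual channel",
           title=f"{virtual.participant_id} / {virtual.modality}")
    return ax
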