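"""HDF5-backed store for recordings, epochs and virtual channels.

Arrays are stored as datasets with named axes; channel/event metadata is
JSON-serialized into attributes so a file round-trips losslessly.
"""
from __future__ import annotations

import json

import h5py
import numpy as np

from .containers import (ChannelInfo, ContinuousRecording, EpochSet, Event,
                         VirtualChannelEpochs)


def _write_channel_info(grp, channel_info):
    grp.attrs["channel_info"] = json.dumps([c.to_dict() for c in channel_info])


def _read_channel_info(grp):
    return [ChannelInfo.from_dict(d) for d in json.loads(grp.attrs["channel_info"])]


def save_recording(path, rec: ContinuousRecording) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("recording")
        g.create_dataset("data", data=rec.data, compression="gzip", compression_opts=1)
        g.attrs["axes"] = json.dumps(["channel", "sample"])
        g.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
        g.attrs["participant_id"] = rec.participant_id
        g.attrs["events"] = json.dumps([e.to_dict() for e in rec.events])
        _write_channel_info(g, rec.channel_info)


def load_recording(path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        g = f["recording"]
        return ContinuousRecording(
            data=g["data"][()],
            sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
            channel_info=_read_channel_info(g),
            events=[Event(**d) for d in json.loads(g.attrs["events"])],
            participant_id=str(g.attrs["participant_id"]),
        )


def save_epochs(path, ep: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("epochs")
        g.create_dataset("data", data=ep.data, compression="gzip", compression_opts=1)
        g.attrs["axes"] = json.dumps(["trial", "channel", "sample"])
        g.create_dataset("time_axis_s", data=ep.time_axis_s)
        g.create_dataset("kept_trial_ids", data=ep.kept_trial_ids)
        g.create_dataset("condition_labels",
                         data=np.asarray(ep.condition_labels, dtype="S"))
        g.attrs["sampling_rate_hz"] = ep.sampling_rate_hz
        g.attrs["participant_id"] = ep.participant_id
        g.attrs["modality"] = ep.modality
        _write_channel_info(g, ep.channel_info)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        g = f["epochs"]
        return EpochSet(
            data=g["data"][()],
            time_axis_s=g["time_axis_s"][()],
            sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
            condition_labels=g["condition_labels"][()].astype(str),
            kept_trial_ids=g["kept_trial_ids"][()],
            channel_info=_read_channel_info(g),
            participant_id=str(g.attrs["participant_id"]),
            modality=str(g.attrs["modality"]),
        )


def save_virtual(path, v: VirtualChannelEpochs) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("virtual")
        g.create_dataset("data", data=v.data, compression="gzip", compression_opts=1)
        g.attrs["axes"] = json.dumps(["trial", "sample"])
        g.create_dataset("time_axis_s", data=v.time_axis_s)
        g.create_dataset("kept_trial_ids", data=v.kept_trial_ids)
        g.attrs["sampling_rate_hz"] = v.sampling_rate_hz
        g.attrs["participant_id"] = v.participant_id
        g.attrs["modality"] = v.modality
        prov = {k: val for k, val in v.provenance.items() if isinstance(val, (str, int, float))}
        spec = v.provenance.get("filter")
        if spec is not None:
            prov["filter"] = json.loads(spec.to_json())
        g.attrs["provenance"] = json.dumps(prov)


def load_virtual(path) -> VirtualChannelEpochs:
    from .containers import SpatialFilterSpec

    with h5py.File(path, "r") as f:
        g = f["virtual"]
        prov = json.loads(g.attrs["provenance"])
        if "filter" in prov:
            prov["filter"] = SpatialFilterSpec.from_json(json.dumps(prov["filter"]))
        return VirtualChannelEpochs(
            data=g["data"][()],
            time_axis_s=g["time_axis_s"][()],
            sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
            kept_trial_ids=g["kept_trial_ids"][()],
            provenance=prov,
            participant_id=str(g.attrs["participant_id"]),
            modality=str(g.attrs["modality"]),
        )


def read_continuous(path, kind: str | None = None) -> ContinuousRecording:
    """Read a continuous recording from standard interchange formats.

    Supports BrainVision (``.vhdr``) and EDF (``.edf``) through :mod:`mne`,
    plus the internal HDF5 store (``.h5``). Event markers become 40/20/60 Hz
    condition labels when annotation descriptions contain those strings.
    """
    p = str(path)
    if kind is None:
        kind = "h5" if p.endswith((".h5", ".hdf5")) else ("brainvision" if p.endswith(".vhdr") else "edf")
    if kind == "h5":
        return load_recording(p)

    import mne

    if kind == "brainvision":
        raw = mne.io.read_raw_brainvision(p, preload=True, verbose="error")
    elif kind == "edf":
        raw = mne.io.read_raw_edf(p, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown format {kind!r}")

    events = []
    for ann in raw.annotations:
        cond = next((c for c in ("40Hz", "20Hz", "60Hz") if c in ann["description"]), None)
        if cond is not None:
            events.append(Event(sample_index=int(round(ann["onset"] * raw.info["sfreq"])),
                                condition=cond))
    chs = [ChannelInfo(label=name, modality="EEG") for name in raw.ch_names]
    return ContinuousRecording(
        data=raw.get_data(), sampling_rate_hz=float(raw.info["sfreq"]),
        channel_info=chs, events=sorted(events, key=lambda e: e.sample_index),
    )
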