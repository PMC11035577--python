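"""Serialization: tab-separated event/stream tables and epoch containers.

Events, gaze/pupil streams, and RR series travel as plain TSV; epoch sets
are stored as a NumPy ``.npz`` archive with a JSON sidecar carrying labels,
time axis, channel names and the rejection log.  Continuous EEG can be
exchanged with standard formats through MNE.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (ContinuousEEG, EpochSet, GazePupilStream,
                         ParadigmEvent, PupilEpochSet, RRSeries)

__all__ = [
    "write_events_tsv", "read_events_tsv", "write_stream_tsv",
    "read_stream_tsv", "write_rr_tsv", "read_rr_tsv", "save_epochs",
    "load_epochs", "read_continuous_eeg", "export_continuous_eeg",
]


def write_events_tsv(events: list[ParadigmEvent], path) -> None:
    pd.DataFrame([{
        "onset_s": ev.onset_s, "run": ev.run_index, "condition": ev.condition,
        "direction": ev.direction, "prev_target_pass_s": ev.prev_target_pass_s,
    } for ev in events]).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[ParadigmEvent]:
    df = pd.read_csv(path, sep="\t")
    return [ParadigmEvent(int(r.run), float(r.onset_s), str(r.condition),
                          float(r.prev_target_pass_s), str(r.direction))
            for r in df.itertuples()]


def write_stream_tsv(stream: GazePupilStream, path) -> None:
    pd.DataFrame({
        "t_s": stream.t_s, "gaze_h_deg": stream.gaze_h_deg,
        "gaze_v_deg": stream.gaze_v_deg,
        "pupil_left_mm": stream.pupil_left_mm,
        "pupil_right_mm": stream.pupil_right_mm,
        "valid_left": stream.valid_left.astype(int),
        "valid_right": stream.valid_right.astype(int),
    }).to_csv(path, sep="\t", index=False)


def read_stream_tsv(path) -> GazePupilStream:
    df = pd.read_csv(path, sep="\t")
    return GazePupilStream(
        df["t_s"].to_numpy(), df["gaze_h_deg"].to_numpy(),
        df["gaze_v_deg"].to_numpy(), df["pupil_left_mm"].to_numpy(),
        df["pupil_right_mm"].to_numpy(),
        df["valid_left"].to_numpy().astype(bool),
        df["valid_right"].to_numpy().astype(bool))


def write_rr_tsv(rr: RRSeries, path) -> None:
    pd.DataFrame({"r_peak_t_s": rr.r_peak_t_s, "rr_s": rr.rr_s}).to_csv(
        path, sep="\t", index=False)


def read_rr_tsv(path) -> RRSeries:
    df = pd.read_csv(path, sep="\t")
    return RRSeries(df["r_peak_t_s"].to_numpy(), df["rr_s"].to_numpy())


def save_epochs(epochs, path) -> None:
    """Write an epoch container as .npz + .json sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=epochs.data,
                        kept_mask=epochs.kept_mask)
    sidecar = {
        "labels": [str(l) for l in epochs.labels],
        "t_axis": list(map(float, epochs.t_axis)),
        "fs_hz": float(epochs.fs_hz),
        "event_ids": [int(i) for i in epochs.event_ids],
        "rejection_log": [list(map(str, entry)) for entry in epochs.rejection_log],
        "kind": type(epochs).__name__,
    }
    if hasattr(epochs, "channel_names"):
        sidecar["channel_names"] = list(epochs.channel_names)
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_epochs(path):
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    common = dict(data=arrays["data"], labels=np.array(meta["labels"]),
                  t_axis=np.array(meta["t_axis"]), fs_hz=meta["fs_hz"],
                  event_ids=np.array(meta["event_ids"]),
                  kept_mask=arrays["kept_mask"],
                  rejection_log=[tuple(e) for e in meta["rejection_log"]])
    if meta["kind"] == "EpochSet":
        return EpochSet(channel_names=meta["channel_names"], **common)
    return PupilEpochSet(**common)


def read_continuous_eeg(path) -> ContinuousEEG:
    """Load continuous EEG from any format MNE can read (µV out)."""
    import mne

    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    return ContinuousEEG(list(raw.ch_names), float(raw.info["sfreq"]),
                         raw.get_data() * 1e6)


def export_continuous_eeg(eeg: ContinuousEEG, path) -> None:
    """Export to FIF for interchange with standard EEG tooling."""
    import mne

    info = mne.create_info(list(eeg.channel_names), eeg.fs_hz, ch_types="eeg")
    raw = mne.io.RawArray(eeg.data * 1e-6, info, verbose="error")
    raw.save(str(path), overwrite=True, verbose="error")
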