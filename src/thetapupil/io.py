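"""Readers and writers for the on-disk cohort layout.

EEG goes to BrainVision (.vhdr/.vmrk text headers + .eeg IEEE float32
multiplexed binary), readable by any EEG toolbox; events and pupil traces
are plain TSV; configuration and ground truth are JSON.  Reading continuous
EEG (BrainVision or EDF) is delegated to ``mne``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg_preprocess import EEGRecording

__all__ = [
    "write_brainvision",
    "read_raw",
    "write_events_tsv",
    "read_events_tsv",
    "write_pupil_tsv",
    "read_pupil_tsv",
    "write_ground_truth_json",
]

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by thetapupil

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_ch}
SamplingInterval={sampling_interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
; Ch<idx>=<name>,<reference>,<resolution in µV>,<unit>
{channels}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
; Mk<idx>=<type>,<description>,<position>,<points>,<channel>
Mk1=New Segment,,1,1,0
{markers}
"""


def write_brainvision(
    rec: EEGRecording, path: str | Path, events: pd.DataFrame | None = None
) -> Path:
    """Write a recording as BrainVision triplet; returns the .vhdr path.

    ``path`` may carry any of the three extensions or none.  Stimulus
    markers (``S  1`` Go / ``S  2`` Nogo) are written when an event table is
    given.
    """
    base = Path(path)
    if base.suffix in {".vhdr", ".eeg", ".vmrk"}:
        base = base.with_suffix("")
    stem = base.name
    chan_lines = "\n".join(
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(rec.ch_names)
    )
    vhdr = _VHDR_TEMPLATE.format(
        stem=stem,
        n_ch=rec.n_channels,
        sampling_interval=f"{1e6 / rec.sfreq:g}",
        channels=chan_lines,
    )
    base.with_suffix(".vhdr").write_text(vhdr, encoding="utf-8")

    marker_lines = []
    if events is not None:
        for k, (_, row) in enumerate(events.iterrows()):
            code = 1 if row["trial_type"] == "go" else 2
            marker_lines.append(
                f"Mk{k + 2}=Stimulus,S{code:>3},{int(row['onset_sample']) + 1},1,0"
            )
    vmrk = _VMRK_TEMPLATE.format(stem=stem, markers="\n".join(marker_lines))
    base.with_suffix(".vmrk").write_text(vmrk, encoding="utf-8")

    rec.data.astype("<f4").T.tofile(base.with_suffix(".eeg"))
    return base.with_suffix(".vhdr")


def read_raw(path: str | Path) -> EEGRecording:
    """Read continuous EEG (BrainVision .vhdr or EDF) through mne."""
    import mne

    path = Path(path)
    if path.suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix in {".edf", ".bdf"}:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG format: {path.suffix}")
    data = raw.get_data() * 1e6  # V → µV
    n_ch = data.shape[0]
    from .montage import equidistant_montage

    _, pos = equidistant_montage(max(8, n_ch))
    return EEGRecording(
        data=data,
        sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        ch_pos=pos[:n_ch],
        reference="unknown",
    )


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    cols = ["onset_sample", "session", "trial_type", "angle", "correct"]
    extra = [c for c in events.columns if c not in cols]
    events[cols + extra].to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    ev["correct"] = ev["correct"].astype(bool)
    return ev


def write_pupil_tsv(times: np.ndarray, diameter: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"time_s": times, "diameter_mm": diameter}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_pupil_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ground_truth_json(truth, path: str | Path) -> None:
    payload = dict(
        source_voxel_indices=truth.source_voxel_indices.tolist(),
        source_orientation=truth.source_orientation.tolist(),
        subject_factors=truth.subject_factors.tolist(),
        per_subject_theta_power=truth.per_subject_theta_power.tolist(),
        per_subject_pupil_amp=truth.per_subject_pupil_amp.tolist(),
    )
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
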