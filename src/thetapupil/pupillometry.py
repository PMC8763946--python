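"""Pupil-diameter conditioning, event-locked epoching and phasic/tonic metrics.

Phasic metrics are taken from the per-subject average of baseline-corrected
event-locked traces: the peak amplitude is the largest interior local maximum
after stimulus presentation and the latency is its time.  Tonic (resting)
pupil size is the mean absolute diameter during the task-free fixation
periods, with the 2-minute periods at the start and end of the experiment
reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "PupilTrace",
    "PupilEpochs",
    "PupilMetrics",
    "preprocess_pupil",
    "epoch_pupil",
    "peak_metrics",
    "tonic_baseline",
]


@dataclass
class PupilTrace:
    """Continuous pupil diameter (mm) on the EEG clock."""

    diameter: np.ndarray  # (n_samples,), mm
    sfreq: float
    blink_mask: np.ndarray | None = None  # True where the signal is missing

    def __post_init__(self) -> None:
        self.diameter = np.asarray(self.diameter, float)
        if self.blink_mask is None:
            self.blink_mask = np.zeros(self.diameter.shape, bool)
        self.blink_mask = np.asarray(self.blink_mask, bool)
        if self.blink_mask.shape != self.diameter.shape:
            raise ValueError("blink mask shape mismatch")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.diameter.size) / self.sfreq


@dataclass
class PupilEpochs:
    """Baseline-corrected event-locked pupil traces (trials × samples, mm)."""

    data: np.ndarray
    times: np.ndarray
    meta: pd.DataFrame
    sfreq: float


@dataclass
class PupilMetrics:
    """Phasic peak metrics of an averaged trace; NaN when no interior peak."""

    peak_amp: float  # mm
    peak_latency: float  # s


def preprocess_pupil(trace: PupilTrace, lp: float = 20.0, order: int = 4) -> PupilTrace:
    """Interpolate blink gaps linearly, then zero-phase low-pass at ``lp`` Hz.

    A 4th-order Butterworth applied forward and backward gives the 48 dB/oct
    roll-off used for the EEG channels.  Blink segments longer than 1 s are
    logged (they may invalidate overlapping trials).
    """
    if trace.sfreq <= 2 * lp:
        raise ValueError("sampling rate too low for the requested low-pass")
    d = trace.diameter.copy()
    mask = trace.blink_mask
    if mask.any():
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0])))[::2]
        if runs.size and runs.max() > trace.sfreq:
            logger.warning("blink segment longer than 1 s interpolated")
        good = ~mask
        d[mask] = np.interp(np.flatnonzero(mask), np.flatnonzero(good), d[good])
    sos = signal.butter(order, lp, btype="lowpass", fs=trace.sfreq, output="sos")
    d = signal.sosfiltfilt(sos, d)
    return replace(trace, diameter=d, blink_mask=np.zeros_like(mask))


def epoch_pupil(
    trace: PupilTrace,
    events: pd.DataFrame,
    tmin: float = -0.2,
    tmax: float = 3.0,
    baseline: tuple[float, float] = (-0.2, 0.0),
    correct_only: bool = True,
) -> PupilEpochs:
    """Baseline-corrected event-locked pupil epochs for correct trials.

    Mirrors the EEG segmentation: epochs at the trace's sampling rate,
    baseline −200 to 0 ms.  Trials at the recording edge or overlapping a
    blink-masked gap are dropped with a log entry.
    """
    n_samp = int(round((tmax - tmin) * trace.sfreq))
    offset = int(round(tmin * trace.sfreq))
    times = tmin + np.arange(n_samp) / trace.sfreq
    ev = events[events["correct"].astype(bool)] if correct_only else events
    rows, chunks = [], []
    for _, row in ev.iterrows():
        start = int(row["onset_sample"]) + offset
        stop = start + n_samp
        if start < 0 or stop > trace.diameter.size:
            logger.warning("dropping pupil trial at sample %d: out of bounds", row["onset_sample"])
            continue
        if trace.blink_mask[start:stop].any():
            logger.warning("dropping pupil trial at sample %d: blink overlap", row["onset_sample"])
            continue
        chunks.append(trace.diameter[start:stop])
        rows.append(row)
    if not chunks:
        raise ValueError("no pupil epochs inside the recording")
    data = np.stack(chunks)
    bl = (times >= baseline[0]) & (times < baseline[1])
    data = data - data[:, bl].mean(axis=1, keepdims=True)
    meta = pd.DataFrame(rows).reset_index(drop=True)
    return PupilEpochs(data=data, times=times, meta=meta, sfreq=trace.sfreq)


def peak_metrics(
    avg: np.ndarray,
    times: np.ndarray,
    search: tuple[float, float] = (0.0, 3.0),
    min_prominence: float = 0.005,
) -> PupilMetrics:
    """Largest interior local maximum of an averaged trace within ``search``.

    Monotone traces with no interior local maximum yield NaN metrics rather
    than an endpoint value.  ``min_prominence`` (mm) suppresses noise peaks.
    """
    avg = np.asarray(avg, float)
    sl = np.flatnonzero((times >= search[0]) & (times <= search[1]))
    seg = avg[sl]
    if seg.size < 3 or np.ptp(seg) == 0:
        logger.warning("flat or empty search window: peak metrics missing")
        return PupilMetrics(np.nan, np.nan)
    peaks, _ = signal.find_peaks(seg, prominence=min_prominence)
    if peaks.size == 0:
        logger.warning("no interior local maximum: peak metrics missing")
        return PupilMetrics(np.nan, np.nan)
    best = peaks[np.argmax(seg[peaks])]
    return PupilMetrics(float(seg[best]), float(times[sl[best]]))


def metrics_table(
    ep: PupilEpochs,
    search: tuple[float, float] = (0.0, 3.0),
    min_prominence: float = 0.005,
    by: tuple[str, ...] = ("session", "trial_type", "angle"),
) -> pd.DataFrame:
    """Per-condition phasic peak metrics from condition-averaged epochs."""
    rows = []
    for key, grp in ep.meta.groupby(list(by), sort=True):
        avg = ep.data[grp.index.to_numpy()].mean(axis=0)
        met = peak_metrics(avg, ep.times, search, min_prominence)
        rec = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        rec.update(peak_amp_mm=met.peak_amp, peak_latency_s=met.peak_latency, n_trials=len(grp))
        rows.append(rec)
    return pd.DataFrame(rows)


def tonic_baseline(trace: PupilTrace, fixations: pd.DataFrame) -> pd.DataFrame:
    """Mean absolute diameter per task-free fixation period.

    ``fixations`` needs columns ``kind`` ('start'/'short'/'end'), ``t_start``
    and ``t_end`` in seconds.  Returns one row per period with its mean
    diameter; the start/end 2-minute means are recovered by filtering on
    ``kind``.
    """
    rows = []
    for _, row in fixations.iterrows():
        i0 = int(round(row["t_start"] * trace.sfreq))
        i1 = int(round(row["t_end"] * trace.sfreq))
        if i0 < 0 or i1 > trace.diameter.size:
            raise ValueError("fixation window outside the recording")
        rows.append(
            dict(
                kind=row["kind"],
                t_start=row["t_start"],
                t_end=row["t_end"],
                mean_diameter_mm=float(trace.diameter[i0:i1].mean()),
            )
        )
    return pd.DataFrame(rows)
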