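"""Cross-modal theta × pupil correlation-cluster statistic.

Every source-level theta time bin (0–1 s post-stimulus) is correlated with
every phasic pupil time bin (0–2 s) across subjects, using per-subject
condition averages (single-trial EEG is too noisy for within-subject
coupling).  Cells with p ≤ 0.05 are retained, 4-connected components of
significant negative cells are extracted, components whose centroid falls in
the window of interest (theta 0–1 s × pupil 1–2 s, where the pupil response
peaks and lags the frontal theta burst) are kept, and cluster sizes are
normalised so the largest cluster across all compared condition × session
cells equals 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingMatrix",
    "CouplingCluster",
    "correlate_theta_pupil",
    "mask_significant",
    "extract_negative_clusters",
    "normalize_cluster_sizes",
]


@dataclass
class CouplingMatrix:
    """Across-subject Pearson r (theta bins × pupil bins) with p-values."""

    r: np.ndarray
    p: np.ndarray
    theta_times: np.ndarray
    pupil_times: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        if self.r.shape != self.p.shape:
            raise ValueError("r and p shapes must match")


@dataclass
class CouplingCluster:
    """A 4-connected block of significant negative correlation cells."""

    bins: np.ndarray  # (k, 2) of (theta_bin, pupil_bin)
    size_raw: int
    mean_r: float
    peak_r: float
    centroid_theta_s: float
    centroid_pupil_s: float
    area_s2: float
    size_norm: float = np.nan
    label: tuple = field(default_factory=tuple)  # e.g. (condition, session)


def _decimate_bins(x: np.ndarray, times: np.ndarray, step: int) -> tuple[np.ndarray, np.ndarray]:
    if step <= 1:
        return x, times
    n = (x.shape[1] // step) * step
    xb = x[:, :n].reshape(x.shape[0], -1, step).mean(axis=2)
    tb = times[:n].reshape(-1, step).mean(axis=1)
    return xb, tb


def correlate_theta_pupil(
    theta: np.ndarray,
    theta_times: np.ndarray,
    pupil: np.ndarray,
    pupil_times: np.ndarray,
    theta_window: tuple[float, float] = (0.0, 1.0),
    pupil_window: tuple[float, float] = (0.0, 2.0),
    decim: int = 1,
) -> CouplingMatrix:
    """Across-subject Pearson r of every theta bin with every pupil bin.

    ``theta`` is (subjects, times) source theta power (dB), ``pupil`` is
    (subjects, times) baseline-corrected diameter.  ``decim`` averages
    consecutive samples into wider bins (recorded in the returned time
    vectors).  Cells with zero variance are masked (r = NaN, p = 1).
    Per-cell p-values are two-sided and uncorrected; significance masking is
    applied downstream.
    """
    theta = np.asarray(theta, float)
    pupil = np.asarray(pupil, float)
    n = theta.shape[0]
    if pupil.shape[0] != n:
        raise ValueError("subject dimension mismatch")
    if n < 4:
        raise ValueError("need at least 4 subjects")
    tm = (theta_times >= theta_window[0]) & (theta_times <= theta_window[1])
    pm = (pupil_times >= pupil_window[0]) & (pupil_times <= pupil_window[1])
    th, t_t = _decimate_bins(theta[:, tm], theta_times[tm], decim)
    pu, t_p = _decimate_bins(pupil[:, pm], pupil_times[pm], decim)

    th_c = th - th.mean(axis=0)
    pu_c = pu - pu.mean(axis=0)
    th_sd = th_c.std(axis=0)
    pu_sd = pu_c.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (th_c.T @ pu_c) / n / np.outer(th_sd, pu_sd)
    bad = ~np.isfinite(r)
    if bad.any():
        logger.warning("%d zero-variance cells masked", int(bad.sum()))
    r = np.clip(np.where(bad, np.nan, r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t_stat), n - 2)
    p = np.where(np.isfinite(p), p, 1.0)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(bad, 1.0, p)
    return CouplingMatrix(r=r, p=p, theta_times=t_t, pupil_times=t_p, n_subjects=n)


def mask_significant(cm: CouplingMatrix, alpha: float = 0.05) -> np.ndarray:
    """Correlation matrix with non-significant cells set to NaN (idempotent)."""
    return np.where(cm.p <= alpha, cm.r, np.nan)


def extract_negative_clusters(
    masked: np.ndarray,
    cm: CouplingMatrix,
    window_of_interest: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (1.0, 2.0)),
    rule: str = "centroid",
    label: tuple = (),
) -> list[CouplingCluster]:
    """4-connected components of significant negative cells in the window.

    ``window_of_interest`` is (theta (lo, hi) s, pupil (lo, hi) s); a
    component is kept when its centroid falls inside (``rule='centroid'``)
    or when it overlaps the window at all (``rule='overlap'``).
    """
    neg = np.isfinite(masked) & (masked < 0)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, n_comp = ndimage.label(neg, structure=structure)
    (t_lo, t_hi), (p_lo, p_hi) = window_of_interest
    out: list[CouplingCluster] = []
    dt = np.median(np.diff(cm.theta_times)) if cm.theta_times.size > 1 else 0.0
    dp = np.median(np.diff(cm.pupil_times)) if cm.pupil_times.size > 1 else 0.0
    for c in range(1, n_comp + 1):
        bins = np.argwhere(labels == c)
        ct = float(cm.theta_times[bins[:, 0]].mean())
        cp = float(cm.pupil_times[bins[:, 1]].mean())
        if rule == "centroid":
            keep = (t_lo <= ct <= t_hi) and (p_lo <= cp <= p_hi)
        elif rule == "overlap":
            keep = bool(
                (
                    (cm.theta_times[bins[:, 0]] >= t_lo)
                    & (cm.theta_times[bins[:, 0]] <= t_hi)
                    & (cm.pupil_times[bins[:, 1]] >= p_lo)
                    & (cm.pupil_times[bins[:, 1]] <= p_hi)
                ).any()
            )
        else:
            raise ValueError("rule must be 'centroid' or 'overlap'")
        if not keep:
            continue
        vals = masked[bins[:, 0], bins[:, 1]]
        out.append(
            CouplingCluster(
                bins=bins,
                size_raw=len(bins),
                mean_r=float(vals.mean()),
                peak_r=float(vals.min()),
                centroid_theta_s=ct,
                centroid_pupil_s=cp,
                area_s2=float(len(bins) * dt * dp),
                label=label,
            )
        )
    return out


def normalize_cluster_sizes(clusters: list[CouplingCluster]) -> list[CouplingCluster]:
    """Scale sizes so the largest cluster across the compared set equals 1."""
    if not clusters:
        raise ValueError("no clusters to normalise")
    biggest = max(c.size_raw for c in clusters)
    for c in clusters:
        c.size_norm = c.size_raw / biggest
    return clusters


def largest_cluster_size(clusters: list[CouplingCluster]) -> int:
    """Raw size of the largest cluster, 0 when the list is empty."""
    return max((c.size_raw for c in clusters), default=0)
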