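"""DICS and LCMV beamforming on the spherical-head source grid.

The source analysis follows a two-stage scheme.  A frequency-domain DICS
beamformer is computed from the theta-band (4–7 Hz) sensor cross-spectral
density: one common spatial filter per subject is built from the pooled
pre-stimulus (−750 to 0 ms) and post-stimulus (250 to 1000 ms) data of both
compared sessions, with 5% diagonal loading and scalar orientation along the
dominant direction of the per-voxel source CSD.  Applying the common filter
to each session/window CSD yields per-voxel power, each session's
post-stimulus power is normalised by its own pre-stimulus power, and the
session contrast is the normalised power difference

    P_diff = (R4 − R1) / (R4 + R1),      R_s = P_s_post / P_s_pre,

which is bounded in [−1, 1] and antisymmetric under exchanging the sessions.
Voxels in the top 1% of |P_diff| define the region of interest; an LCMV
beamformer (broadband covariance averaged over single trials, unit-gain
constraint, same orientation convention) then reconstructs trial-wise source
time courses averaged over the ROI, from which theta power time courses are
derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss

from .eeg_preprocess import EpochSet
from .forward import Leadfield
from .timefreq import MorletParams, band_average, db_baseline, morlet_decompose

__all__ = [
    "CSDMatrix",
    "SpatialFilter",
    "ContrastMap",
    "compute_csd",
    "dics_filter",
    "dics_power",
    "dics_contrast",
    "select_top_voxels",
    "lcmv_reconstruct",
    "ROI_BOXES",
]


@dataclass
class CSDMatrix:
    """Hermitian sensor cross-spectral density averaged over a band."""

    csd: np.ndarray  # (n_channels, n_channels) complex
    window: str  # 'pre' | 'post' | 'combined'
    band: tuple[float, float]
    n_trials: int

    def __post_init__(self) -> None:
        c = np.asarray(self.csd, complex)
        if not np.allclose(c, c.conj().T, atol=1e-10 * max(1.0, np.abs(c).max())):
            raise ValueError("CSD must be Hermitian")
        self.csd = 0.5 * (c + c.conj().T)

    def __add__(self, other: "CSDMatrix") -> "CSDMatrix":
        w = self.n_trials + other.n_trials
        csd = (self.csd * self.n_trials + other.csd * other.n_trials) / w
        return CSDMatrix(csd=csd, window="combined", band=self.band, n_trials=w)


@dataclass
class SpatialFilter:
    """Per-voxel scalar beamformer weights (voxels × channels)."""

    weights: np.ndarray
    orientations: np.ndarray  # (voxels, 3) chosen dipole orientation
    regularization: float
    kind: str  # 'DICS' | 'LCMV'


@dataclass
class ContrastMap:
    """Per-voxel session power contrast (Eq. form above), in [−1, 1]."""

    p_diff: np.ndarray
    valid: np.ndarray  # False where pre-stimulus power vanished
    grid: np.ndarray


def compute_csd(
    ep: EpochSet,
    window: tuple[float, float],
    band: tuple[float, float] = (4.0, 7.0),
    bandwidth: float = 3.0,
) -> CSDMatrix:
    """Multitaper (Slepian) cross-spectral density over trials and tapers.

    ``bandwidth`` is the full spectral smoothing width (±bandwidth/2 around
    each frequency bin); the window must be long enough to resolve it.
    """
    if ep.data.shape[0] == 0:
        raise ValueError("no epochs to compute a CSD from")
    tmask = (ep.times >= window[0]) & (ep.times < window[1])
    n_t = int(tmask.sum())
    if n_t < 2:
        raise ValueError("empty CSD window")
    dur = n_t / ep.sfreq
    if dur < 2.0 / bandwidth:
        raise ValueError("window shorter than the inverse spectral bandwidth")
    x = ep.data[:, :, tmask]
    x = x - x.mean(axis=-1, keepdims=True)
    nw = dur * bandwidth / 2.0
    k = max(1, int(np.floor(2 * nw - 1)))
    tapers = dpss(n_t, nw, Kmax=k)
    if tapers.ndim == 1:
        tapers = tapers[None, :]
    freqs = np.fft.rfftfreq(n_t, 1.0 / ep.sfreq)
    fmask = (freqs >= band[0]) & (freqs <= band[1])
    if not fmask.any():  # short windows: take the bin nearest the band centre
        fmask = np.zeros_like(freqs, bool)
        fmask[np.argmin(np.abs(freqs - np.mean(band)))] = True
    # (trials, tapers, channels, freqs)
    spec = np.fft.rfft(x[:, None, :, :] * tapers[None, :, None, :], axis=-1)
    spec = spec[..., fmask]
    csd = np.einsum("tkcf,tkdf->cd", spec, spec.conj()) / (
        x.shape[0] * tapers.shape[0] * int(fmask.sum())
    )
    return CSDMatrix(csd=csd, window="pre" if window[1] <= 0 else "post", band=band, n_trials=x.shape[0])


def _regularized_inverse(c: np.ndarray, reg: float) -> np.ndarray:
    n = c.shape[0]
    loading = reg * np.real(np.trace(c)) / n
    c_reg = c + loading * np.eye(n)
    return np.linalg.inv(c_reg)


def _scalar_weights(
    gain: np.ndarray, c: np.ndarray, c_inv: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-gain scalar weights along the dominant orientation per voxel.

    ``gain`` is (voxels, 3, channels).  Returns (weights (V, C) possibly
    complex-real, orientations (V, 3)).
    """
    lt = gain  # (V, 3, C)
    l_ci = np.einsum("voc,cd->vod", lt, c_inv)  # L^T C^-1
    gram = np.einsum("vod,vpd->vop", l_ci, lt.conj())  # L^T C^-1 L, (V,3,3)
    gram_inv = np.linalg.inv(gram)
    w3 = np.einsum("vop,vpd->vod", gram_inv, l_ci)  # (V, 3, C), W3 L^T = I
    s = np.einsum("voc,cd,vpd->vop", w3, c, w3.conj())  # 3×3 source CSD
    s = 0.5 * np.real(s + np.swapaxes(s, 1, 2))
    eigvals, eigvecs = np.linalg.eigh(s)
    ori = eigvecs[:, :, -1]  # dominant direction
    # deterministic sign: largest-magnitude component positive
    lead = np.take_along_axis(ori, np.abs(ori).argmax(axis=1)[:, None], axis=1)
    ori = ori * np.sign(lead)
    w = np.einsum("vo,voc->vc", ori, w3)
    return w, ori


def dics_filter(csd_combined: CSDMatrix, lf: Leadfield, reg: float = 0.05) -> SpatialFilter:
    """Common DICS spatial filter from a pooled (pre+post, both sessions) CSD.

    Diagonal loading is ``reg × trace(C)/n_channels``; weights minimise
    output power under a unit-gain constraint and the per-voxel orientation
    is the dominant direction of the 3×3 source CSD.
    """
    c = csd_combined.csd
    c_inv = _regularized_inverse(c, reg)
    w, ori = _scalar_weights(lf.gain, c, c_inv)
    return SpatialFilter(weights=w, orientations=ori, regularization=reg, kind="DICS")


def dics_power(filt: SpatialFilter, csd: CSDMatrix) -> np.ndarray:
    """Per-voxel source power of a session/window CSD under a fixed filter."""
    return np.real(np.einsum("vc,cd,vd->v", filt.weights, csd.csd, filt.weights.conj()))


def dics_contrast(
    filt: SpatialFilter,
    csd_s1_pre: CSDMatrix,
    csd_s1_post: CSDMatrix,
    csd_s4_pre: CSDMatrix,
    csd_s4_post: CSDMatrix,
    lf: Leadfield,
    eq2_literal: bool = False,
) -> ContrastMap:
    """Normalised S1-vs-S4 power difference per voxel.

    Default: each session's post-stimulus power is normalised by its own
    pre-stimulus power, R_s = P_post/P_pre, and
    P_diff = (R4 − R1)/(R4 + R1).  With ``eq2_literal=True`` both session
    ratios share the S4 pre-stimulus denominator, in which case the
    pre-stimulus power cancels and the contrast reduces to
    (P4_post − P1_post)/(P4_post + P1_post).
    """
    p1_pre = dics_power(filt, csd_s1_pre)
    p1_post = dics_power(filt, csd_s1_post)
    p4_pre = dics_power(filt, csd_s4_pre)
    p4_post = dics_power(filt, csd_s4_post)
    p_diff, ok = contrast_from_powers(p1_pre, p1_post, p4_pre, p4_post, eq2_literal)
    return ContrastMap(p_diff=p_diff, valid=ok, grid=lf.grid)


def contrast_from_powers(
    p1_pre: np.ndarray,
    p1_post: np.ndarray,
    p4_pre: np.ndarray,
    p4_post: np.ndarray,
    eq2_literal: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised power-difference contrast from the four power maps.

    Returns ``(p_diff, valid)``; ``p_diff`` lies in [−1, 1] wherever all
    powers are positive (mediant inequality) and is antisymmetric under the
    S1 ↔ S4 exchange.
    """
    p1_pre, p1_post, p4_pre, p4_post = map(
        lambda a: np.asarray(a, float), (p1_pre, p1_post, p4_pre, p4_post)
    )
    denom_pre_1 = p4_pre if eq2_literal else p1_pre
    valid = (denom_pre_1 > 0) & (p4_pre > 0)
    r1 = np.divide(p1_post, denom_pre_1, out=np.zeros_like(p1_post), where=valid)
    r4 = np.divide(p4_post, p4_pre, out=np.zeros_like(p4_post), where=valid)
    denom = r4 + r1
    ok = valid & (denom > 0)
    p_diff = np.divide(r4 - r1, denom, out=np.zeros_like(denom), where=ok)
    return p_diff, ok


#: built-in ROI boxes in head-grid coordinates (m), checked in order.
ROI_BOXES: list[tuple[str, tuple[float, float], tuple[float, float], tuple[float, float]]] = [
    ("sma", (-0.012, 0.012), (-0.005, 0.02), (0.05, 0.09)),
    ("superior_frontal", (-0.035, 0.035), (0.01, 0.055), (0.035, 0.08)),
    ("precentral", (-0.045, 0.045), (-0.03, 0.01), (0.04, 0.08)),
]


def roi_label(point: np.ndarray) -> str:
    for name, xr, yr, zr in ROI_BOXES:
        if xr[0] <= point[0] <= xr[1] and yr[0] <= point[1] <= yr[1] and zr[0] <= point[2] <= zr[1]:
            return name
    return "other"


def select_top_voxels(
    cmap: ContrastMap, fraction: float = 0.01, spacing: float | None = None
) -> dict:
    """Voxels with |P_diff| in the top ``fraction``, grouped into clusters.

    Returns a dict with ``mask`` (boolean per voxel), ``indices``,
    ``clusters`` (list of index arrays, grid-contiguous groups), and per
    cluster centroid coordinates and ROI labels.  Ties are broken
    deterministically toward the lowest voxel index.
    """
    import logging

    vals = np.abs(np.where(cmap.valid, cmap.p_diff, -np.inf))
    n_valid = int(cmap.valid.sum())
    if n_valid == 0:
        raise ValueError("no valid voxels in the contrast map")
    n_keep = max(1, int(np.floor(fraction * n_valid)))
    # stable selection: sort by (-value, index)
    order = np.lexsort((np.arange(vals.size), -vals))
    if vals[order[n_keep - 1]] == vals[order[n_keep]] if n_keep < vals.size else False:
        logging.getLogger(__name__).info("tie at the top-voxel cutoff; keeping lowest indices")
    indices = np.sort(order[:n_keep])
    mask = np.zeros(vals.size, bool)
    mask[indices] = True

    if spacing is None:
        d = np.linalg.norm(cmap.grid[1] - cmap.grid[0], axis=-1)
        spacing = float(d) if np.isfinite(d) and d > 0 else 0.01
    pts = cmap.grid[indices]
    from scipy.sparse import csgraph, csr_matrix
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    pairs = tree.query_pairs(spacing * 1.01, output_type="ndarray")
    n = len(indices)
    if pairs.size:
        adj = csr_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_comp, labels = csgraph.connected_components(adj, directed=False)
    else:
        n_comp, labels = n, np.arange(n)
    clusters, centroids, rois = [], [], []
    for c in range(n_comp):
        members = indices[labels == c]
        clusters.append(members)
        cen = cmap.grid[members].mean(axis=0)
        centroids.append(cen)
        rois.append(roi_label(cen))
    return dict(
        mask=mask,
        indices=indices,
        clusters=clusters,
        centroids=np.asarray(centroids),
        roi_labels=rois,
    )


def lcmv_reconstruct(
    ep: EpochSet,
    lf: Leadfield,
    roi: np.ndarray,
    reg: float = 0.05,
    cov_mode: str = "single_trials",
    theta_band: tuple[float, float] = (4.0, 7.0),
    baseline: tuple[float, float] = (-0.2, 0.0),
    params: MorletParams | None = None,
    return_timecourse: bool = False,
):
    """ROI theta power time course from an LCMV beamformer.

    The broadband covariance is the average of single-trial covariances
    (``cov_mode='single_trials'``; ``'evoked'`` uses the covariance of the
    trial average instead).  Unit-gain scalar weights with the dominant-
    orientation convention are built per ROI voxel; trial-wise source time
    series are averaged over ROI voxels, Morlet-decomposed, averaged across
    the theta band and trials, and dB-baselined.

    Returns ``(theta_db (n_times,), times)`` — or, with
    ``return_timecourse=True``, also the raw (n_trials, n_times) source
    series.
    """
    roi = np.asarray(roi)
    if roi.dtype == bool:
        roi = np.flatnonzero(roi)
    if roi.size == 0:
        raise ValueError("ROI is empty")
    x = ep.data  # (T, C, S)
    if cov_mode == "single_trials":
        xc = x - x.mean(axis=-1, keepdims=True)
        cov = np.einsum("tcs,tds->cd", xc, xc) / (x.shape[0] * x.shape[2])
    elif cov_mode == "evoked":
        avg = x.mean(axis=0)
        avg = avg - avg.mean(axis=-1, keepdims=True)
        cov = avg @ avg.T / avg.shape[1]
    else:
        raise ValueError("cov_mode must be 'single_trials' or 'evoked'")
    if reg == 0 and np.linalg.matrix_rank(cov) < cov.shape[0]:
        raise ValueError("rank-deficient covariance requires regularization")
    c_inv = _regularized_inverse(cov, reg)
    w, _ = _scalar_weights(lf.gain[roi], cov, c_inv)
    w = np.real(w)
    src = np.einsum("vc,tcs->tvs", w, x).mean(axis=1)  # ROI-averaged series

    from dataclasses import replace as _replace

    src_ep = _replace(ep, data=src[:, None, :], ch_names=["roi"], ch_pos=np.zeros((1, 3)))
    tfr = morlet_decompose(src_ep, params or MorletParams(), average=True)
    tfr_db = db_baseline(tfr, baseline)
    theta = band_average(tfr_db, band=theta_band)  # (1, 1, times)
    theta_db = theta[0, 0]
    if return_timecourse:
        return theta_db, ep.times, src
    return theta_db, ep.times
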