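"""Cohort-level orchestration: generator → preprocessing → source/pupil → coupling.

Ties the modules together the way the analysis scripts and recovery tests
use them.  The EEG path per subject: band-pass/notch filtering, average
reference, stimulus-locked 5 s epochs of correct trials, automated artifact
flags, baseline correction; a DICS contrast between the first and last
analysed session localises the theta modulation, the group-mean contrast's
top-1% voxels define the ROI, and an LCMV beamformer reconstructs each
subject's ROI theta power time course.  The pupil path mirrors the EEG
segmentation and yields per-subject average phasic traces and peak metrics.
Because the region of interest is defined on the group contrast, the EEG
pass runs twice (the generator is deterministic, so re-simulation is exact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import beamformer as bf
from .cluster_perm import build_neighbors, cluster_permutation_test
from .coupling import (
    correlate_theta_pupil,
    extract_negative_clusters,
    largest_cluster_size,
    mask_significant,
    normalize_cluster_sizes,
)
from .eeg_preprocess import (
    EpochSet,
    apply_filters,
    baseline_correct,
    csd_transform,
    epoch,
    reject_artifacts,
    rereference_average,
)
from .pupillometry import epoch_pupil, peak_metrics, preprocess_pupil
from .synthetic_data import Cohort, SimConfig
from .timefreq import MorletParams, band_average, db_baseline, morlet_decompose

__all__ = ["CohortResult", "preprocess_subject", "run_cohort", "coupling_cluster_sizes"]

PRE_WINDOW = (-0.75, 0.0)
POST_WINDOW = (0.25, 1.0)


@dataclass
class CohortResult:
    sessions: tuple[int, int]  # compared (first, last) session labels
    times: np.ndarray  # epoch time axis
    theta_tc: np.ndarray  # (n_subjects, 2, n_times) ROI theta dB
    contrast_mean: np.ndarray  # group-mean DICS contrast per voxel
    contrast_subj: np.ndarray  # (n_subjects, n_voxels)
    roi: dict  # output of select_top_voxels on the mean contrast
    pupil_times: np.ndarray
    pupil_avg: np.ndarray  # (n_subjects, n_sessions, n_ptimes)
    pupil_peak: np.ndarray  # (n_subjects, n_sessions) mm
    pupil_latency: np.ndarray  # (n_subjects, n_sessions) s
    sensor_theta: np.ndarray | None = None  # (n_subjects, 2, n_ch, n_bins)
    sensor_times: np.ndarray | None = None


def preprocess_subject(
    rec,
    events,
    tmin: float = -2.0,
    tmax: float = 3.0,
    csd: bool = False,
    reject: bool = True,
) -> EpochSet:
    """Standard conditioning chain for one subject's continuous recording.

    ``reject=False`` skips the automated artifact flags (useful for
    noise-free simulations whose amplitudes sit below the dead-channel
    criterion by construction).
    """
    rec = apply_filters(rec)
    rec = rereference_average(rec)
    ep = epoch(rec, events, tmin=tmin, tmax=tmax)
    if reject:
        ep = reject_artifacts(ep).kept()
    ep = baseline_correct(ep)
    if csd:
        ep = csd_transform(ep)
    return ep


def _session_csds(ep: EpochSet, sessions: tuple[int, int]):
    out = {}
    for s in sessions:
        eps = ep.select(session=s)
        out[s] = (
            bf.compute_csd(eps, PRE_WINDOW),
            bf.compute_csd(eps, POST_WINDOW),
        )
    return out


def run_cohort(
    cfg: SimConfig,
    leadfield=None,
    sessions: tuple[int, int] | None = None,
    theta_params: MorletParams | None = None,
    sensor_maps: bool = False,
    sensor_decim: int = 16,
    reg: float = 0.05,
    top_fraction: float = 0.01,
) -> CohortResult:
    """Run the full recovery pipeline on one synthetic cohort.

    ``sessions`` defaults to the first and last session of the design (the
    maximal time-on-task contrast).  With ``sensor_maps=True`` the per-
    subject sensor-level theta maps (CSD-transformed, dB, 0–1 s, decimated
    in time) needed for the cluster permutation test are computed as well.
    """
    cohort = Cohort(cfg, leadfield=leadfield)
    lf = cohort.leadfield
    if sessions is None:
        sessions = (1, cfg.n_sessions)
    s_first, s_last = sessions
    params = theta_params or MorletParams()

    n_sub = cfg.n_subjects
    contrast_subj = np.empty((n_sub, lf.n_voxels))
    sensor_theta = None
    sensor_times = None

    # cache preprocessed epochs for the LCMV pass when they fit comfortably
    # in memory; otherwise re-simulate (the generator is deterministic)
    est_bytes = (
        n_sub
        * cfg.n_sessions
        * cfg.trials_per_session
        * cfg.n_channels
        * int(5 * cfg.sfreq)
        * 8
    )
    cache: list | None = [] if est_bytes < 1.5e9 else None

    # pass 1: per-subject DICS contrasts (and optional sensor maps)
    for i in range(n_sub):
        ep = preprocess_subject(cohort.subject_eeg(i), cohort.events)
        if cache is not None:
            cache.append(ep)
        csds = _session_csds(ep, sessions)
        combined = csds[s_first][0] + csds[s_first][1] + csds[s_last][0] + csds[s_last][1]
        filt = bf.dics_filter(combined, lf, reg=reg)
        cmap = bf.dics_contrast(
            filt, csds[s_first][0], csds[s_first][1], csds[s_last][0], csds[s_last][1], lf
        )
        contrast_subj[i] = cmap.p_diff

        if sensor_maps:
            # the spherical-spline Laplacian needs a dense montage; on
            # reduced (scaled-down) montages the plain potentials are used
            ep_csd = csd_transform(ep) if len(ep.ch_names) >= 32 else ep
            maps = []
            for s in sessions:
                tfr = morlet_decompose(ep_csd.select(session=s), params, average=True)
                tfr = db_baseline(tfr)
                theta = band_average(tfr)  # (1, n_ch, n_times)
                tm = (tfr.times >= 0.0) & (tfr.times <= 1.0)
                m = theta[0][:, tm]
                n_bins = m.shape[1] // sensor_decim
                m = m[:, : n_bins * sensor_decim].reshape(m.shape[0], n_bins, sensor_decim).mean(-1)
                maps.append(m)
                if sensor_times is None:
                    tt = tfr.times[tm][: n_bins * sensor_decim]
                    sensor_times = tt.reshape(n_bins, sensor_decim).mean(-1)
            if sensor_theta is None:
                sensor_theta = np.empty((n_sub, 2) + maps[0].shape)
            sensor_theta[i] = np.stack(maps)

    mean_map = bf.ContrastMap(
        p_diff=contrast_subj.mean(axis=0),
        valid=np.ones(lf.n_voxels, bool),
        grid=lf.grid,
    )
    roi = bf.select_top_voxels(mean_map, fraction=top_fraction, spacing=lf.spacing)

    # pass 2: LCMV ROI theta time courses
    theta_tc = None
    times = None
    for i in range(n_sub):
        ep = cache[i] if cache is not None else preprocess_subject(
            cohort.subject_eeg(i), cohort.events
        )
        for j, s in enumerate(sessions):
            theta_db, tt = bf.lcmv_reconstruct(
                ep.select(session=s), lf, roi["indices"], reg=reg, params=params
            )
            if theta_tc is None:
                times = tt
                theta_tc = np.empty((n_sub, 2, tt.size))
            theta_tc[i, j] = theta_db

    # pupil path
    pupil_avg = None
    pupil_times = None
    pupil_peak = np.full((n_sub, cfg.n_sessions), np.nan)
    pupil_latency = np.full((n_sub, cfg.n_sessions), np.nan)
    for i in range(n_sub):
        trace = preprocess_pupil(cohort.subject_pupil(i))
        pep = epoch_pupil(trace, cohort.events)
        for s in range(1, cfg.n_sessions + 1):
            sel = pep.meta["session"] == s
            if not sel.any():
                continue
            avg = pep.data[sel.to_numpy()].mean(axis=0)
            if pupil_avg is None:
                pupil_times = pep.times
                pupil_avg = np.empty((n_sub, cfg.n_sessions, pep.times.size))
            pupil_avg[i, s - 1] = avg
            met = peak_metrics(avg, pep.times)
            pupil_peak[i, s - 1] = met.peak_amp
            pupil_latency[i, s - 1] = met.peak_latency

    return CohortResult(
        sessions=sessions,
        times=times,
        theta_tc=theta_tc,
        contrast_mean=mean_map.p_diff,
        contrast_subj=contrast_subj,
        roi=roi,
        pupil_times=pupil_times,
        pupil_avg=pupil_avg,
        pupil_peak=pupil_peak,
        pupil_latency=pupil_latency,
        sensor_theta=sensor_theta,
        sensor_times=sensor_times,
    )


def coupling_cluster_sizes(
    res: CohortResult,
    decim: int = 8,
    alpha: float = 0.05,
) -> dict:
    """Theta × pupil coupling clusters for the two compared sessions.

    Returns per-session normalised in-window negative-cluster sizes (the
    largest cluster across the compared set has size 1) plus the raw sizes
    and matrices.
    """
    s_first, s_last = res.sessions
    clusters_all = []
    mats = {}
    raw = {}
    for j, s in enumerate(res.sessions):
        cm = correlate_theta_pupil(
            res.theta_tc[:, j, :],
            res.times,
            res.pupil_avg[:, s - 1, :],
            res.pupil_times,
            decim=decim,
        )
        masked = mask_significant(cm, alpha)
        cls = extract_negative_clusters(masked, cm, label=("all", s))
        mats[s] = cm
        raw[s] = largest_cluster_size(cls)
        clusters_all.extend(cls)
    norm = {s: 0.0 for s in res.sessions}
    if clusters_all:
        normalize_cluster_sizes(clusters_all)
        for c in clusters_all:
            s = c.label[1]
            norm[s] = max(norm[s], c.size_norm)
    return dict(size_norm=norm, size_raw=raw, matrices=mats, clusters=clusters_all)


def sensor_cluster_test(res: CohortResult, max_dist: float = 0.6, n_perm: int = 500, seed: int = 0):
    """S1-vs-S4 sensor theta cluster permutation test from stored maps."""
    if res.sensor_theta is None:
        raise ValueError("run_cohort(..., sensor_maps=True) required")
    # positions from the stored montage size
    from .montage import equidistant_montage

    _, pos = equidistant_montage(res.sensor_theta.shape[2])
    graph = build_neighbors(pos, max_dist=max_dist)
    return cluster_permutation_test(
        res.sensor_theta[:, 0], res.sensor_theta[:, 1], graph, n_perm=n_perm, seed=seed
    )
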