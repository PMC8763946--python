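"""Synthetic cohort generator for the working-memory modulated Go/Nogo task.

Emulates the data structure of a time-on-task experiment: ``n_subjects``
perform one continuous session of ``n_sessions × trials_per_session`` trials
(7:3 Go:Nogo, equal 30°/150° rotation counts within each trial type, fixation
900–1300 ms, stimulus 1100 ms), flanked by 2-minute resting-fixation periods
and interleaved with 19 ten-second fixation periods.  The physiological
ground truth is programmable:

* event-locked theta bursts (Hanning-windowed oscillation at ``theta_freq``
  over 0–1 s post-stimulus) emitted by superior-frontal grid dipoles whose
  source amplitude declines across sessions (``theta_amp_by_session``),
  forward-projected through the three-shell spherical head model, on top of
  1/f background activity (scaled to a target theta-band SNR) and white
  sensor noise;
* event-locked pupil dilations (Erlang-shaped kernel peaking near 1.2 s,
  larger for 150° than 30° trials) whose per-subject amplitude has a
  programmed across-subject correlation with per-subject theta power in each
  session (``coupling_by_session``), plus a slow tonic drift and measurement
  noise.

Identical seeds produce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd

from .eeg_preprocess import EEGRecording
from .forward import HeadModel, Leadfield, compute_leadfield
from .montage import equidistant_montage
from .pupillometry import PupilTrace

__all__ = ["SimConfig", "GroundTruth", "make_events", "Cohort"]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass(frozen=True)
class SimConfig:
    """Study-design and ground-truth parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 4 sessions × 1200 trials
    (840 Go / 360 Nogo), 256 Hz, 60-channel equidistant montage, theta bursts
    at 5.5 Hz declining 20% from S1 to S4, theta–pupil coupling fading from
    −0.65 (S1) to 0 (S4), phasic pupil peaks shrinking from 0.070 to
    0.052 mm, tonic baseline 3.62 mm drifting upward 0.065 mm/h.
    """

    n_subjects: int = 27
    n_sessions: int = 4
    trials_per_session: int = 1200
    go_fraction: float = 0.7
    angle_split: float = 0.5
    sfreq: float = 256.0
    fixation_range: tuple[float, float] = (900.0, 1300.0)  # ms
    stimulus_duration: float = 1100.0  # ms
    long_fixation_s: float = 120.0
    short_fixation_s: float = 10.0
    n_short_fixations: int = 19
    error_rate: float = 0.0
    # EEG ground truth
    n_channels: int = 60
    theta_freq: float = 5.5  # Hz
    theta_amp_by_session: tuple[float, ...] = (60.0, 56.0, 52.0, 48.0)  # nA·m
    burst_duration: float = 1.0  # s, Hanning envelope 0..1 s post-stimulus
    subject_amp_sigma: float = 0.35  # log-normal sd of subject factors
    trial_amp_sigma: float = 0.10  # log-normal sd of trial jitter
    background_snr: float = 5.0  # burst theta power / background theta power
    sensor_noise_sd: float = 2.0  # µV white noise
    grid_spacing: float = 0.01  # m
    #: superior-frontal dipole target positions (m); nearest grid voxels used
    source_targets: tuple[tuple[float, float, float], ...] = (
        (-0.02, 0.03, 0.055),
        (0.02, 0.03, 0.055),
    )
    # pupil ground truth
    coupling_by_session: tuple[float, ...] = (-0.65, -0.45, -0.25, 0.0)
    pupil_amp_by_session: tuple[float, ...] = (0.070, 0.064, 0.058, 0.052)  # mm
    pupil_angle_ratio: float = 1.19  # 150° / 30° phasic amplitude
    pupil_amp_cv: float = 0.30  # across-subject amplitude spread
    pupil_peak_latency: float = 1.2  # s, kernel peak
    pupil_kernel_shape: float = 10.1  # Erlang shape
    pupil_baseline_mm: float = 3.62
    pupil_baseline_drift: float = 0.065  # mm per hour
    pupil_noise_sd: float = 0.010  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        n_go = self.go_fraction * self.trials_per_session
        if abs(n_go - round(n_go)) > 1e-9:
            raise ValueError("go_fraction × trials_per_session must be an integer")
        if not 0.0 < self.angle_split < 1.0:
            raise ValueError("angle_split must lie in (0, 1)")
        if len(self.theta_amp_by_session) != self.n_sessions:
            raise ValueError("theta_amp_by_session length must equal n_sessions")
        if np.any(np.diff(self.theta_amp_by_session) > 1e-12):
            raise ValueError("theta_amp_by_session must be non-increasing")
        for name in ("coupling_by_session", "pupil_amp_by_session"):
            if len(getattr(self, name)) != self.n_sessions:
                raise ValueError(f"{name} length must equal n_sessions")
        if np.any(np.abs(self.coupling_by_session) > 1.0):
            raise ValueError("coupling values must lie in [-1, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")

    @property
    def n_go(self) -> int:
        return int(round(self.go_fraction * self.trials_per_session))

    @property
    def n_nogo(self) -> int:
        return self.trials_per_session - self.n_go

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {k: v for k, v in self.__dict__.items()}, fh, indent=2, default=list
            )


@dataclass
class GroundTruth:
    """Programmed physiology of a cohort, for recovery checks."""

    source_voxel_indices: np.ndarray  # active dipoles, grid indices
    source_orientation: np.ndarray  # common unit orientation
    subject_factors: np.ndarray  # (n_subjects,) log-normal gains
    per_subject_theta_power: np.ndarray  # (n_subjects, n_sessions), (nA·m)²
    per_subject_pupil_amp: np.ndarray  # (n_subjects, n_sessions), mm
    event_table: pd.DataFrame
    fixations: pd.DataFrame


def make_events(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the shared trial and fixation-period tables of the experiment.

    The stimulus order is randomised once (identical for every subject, as in
    the study).  Returns ``(trials, fixations)``: trials with columns
    ``trial``, ``session``, ``trial_type``, ``angle``, ``onset_s``,
    ``onset_sample``, ``correct``; fixation periods with ``kind``
    ('start'/'short'/'end'), ``t_start``, ``t_end``.
    """
    rng = _rng(cfg.seed, 0)
    n_total = cfg.n_sessions * cfg.trials_per_session
    trial_rows = []
    for sess in range(1, cfg.n_sessions + 1):
        n_go_30 = int(round(cfg.n_go * cfg.angle_split))
        n_nogo_30 = int(round(cfg.n_nogo * cfg.angle_split))
        combos = (
            [("go", 30)] * n_go_30
            + [("go", 150)] * (cfg.n_go - n_go_30)
            + [("nogo", 30)] * n_nogo_30
            + [("nogo", 150)] * (cfg.n_nogo - n_nogo_30)
        )
        order = rng.permutation(len(combos))
        for idx in order:
            ttype, ang = combos[idx]
            trial_rows.append((sess, ttype, ang))

    # 19 short fixation periods evenly interleaved over the trial sequence
    n_breaks = cfg.n_short_fixations
    break_after = {
        int(round((k + 1) * n_total / (n_breaks + 1))) for k in range(n_breaks)
    }

    fix_durs = rng.uniform(*cfg.fixation_range, size=n_total) / 1000.0
    stim_s = cfg.stimulus_duration / 1000.0

    t = cfg.long_fixation_s
    fixations = [dict(kind="start", t_start=0.0, t_end=cfg.long_fixation_s)]
    onsets = np.empty(n_total)
    for i in range(n_total):
        t += fix_durs[i]
        onsets[i] = t
        t += stim_s
        if (i + 1) in break_after:
            fixations.append(dict(kind="short", t_start=t, t_end=t + cfg.short_fixation_s))
            t += cfg.short_fixation_s
    fixations.append(dict(kind="end", t_start=t, t_end=t + cfg.long_fixation_s))

    correct = np.ones(n_total, bool)
    if cfg.error_rate > 0:
        correct = rng.random(n_total) >= cfg.error_rate

    trials = pd.DataFrame(
        dict(
            trial=np.arange(n_total),
            session=[r[0] for r in trial_rows],
            trial_type=[r[1] for r in trial_rows],
            angle=[r[2] for r in trial_rows],
            onset_s=onsets,
            onset_sample=np.round(onsets * cfg.sfreq).astype(int),
            correct=correct,
        )
    )
    return trials, pd.DataFrame(fixations)


def _one_over_f_noise(
    rng: np.random.Generator, n_ch: int, n_samp: int, sfreq: float, band=(4.0, 7.0)
) -> tuple[np.ndarray, float]:
    """Channel-independent noise with a 1/f power spectrum, unit variance.

    Returns ``(noise, theta_fraction)`` where ``theta_fraction`` is the
    standard deviation of the noise restricted to ``band`` (exact for the
    shaping filter, no extra transform needed).
    """
    from scipy import fft as sfft

    n_fast = sfft.next_fast_len(n_samp, real=True)
    white = rng.standard_normal((n_ch, n_fast))
    spec = sfft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_fast, 1.0 / sfreq)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = 1.0 / np.sqrt(freqs[nz])  # power ∝ 1/f
    out = sfft.irfft(spec * amp, n=n_fast, axis=1)[:, :n_samp]
    sd = out.std(axis=1, keepdims=True)
    out /= sd
    power = amp**2
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    band_sd = float(np.sqrt(power[in_band].sum() / power.sum()))
    return out, band_sd


def null_theta_maps(
    n_subjects: int,
    positions: np.ndarray,
    n_bins: int,
    rng: np.random.Generator,
    spatial_scale: float = 0.5,
    ar: float = 0.7,
) -> np.ndarray:
    """Per-subject sensor theta maps with no condition effect.

    Map-level null model of the generator's background: Gaussian fields with
    squared-exponential spatial covariance over the montage (length scale in
    radians of arc) and AR(1) temporal correlation.  Used to calibrate the
    family-wise error of the cluster permutation machinery without
    synthesising full recordings.
    """
    pos = np.asarray(positions, float)
    d = np.arccos(np.clip(pos @ pos.T, -1.0, 1.0))
    k = np.exp(-(d**2) / (2.0 * spatial_scale**2)) + 1e-8 * np.eye(pos.shape[0])
    chol = np.linalg.cholesky(k)
    z = rng.standard_normal((n_subjects, pos.shape[0], n_bins))
    out = np.einsum("cd,sdt->sct", chol, z)
    for t in range(1, n_bins):
        out[:, :, t] = ar * out[:, :, t - 1] + np.sqrt(1 - ar**2) * out[:, :, t]
    return out


class Cohort:
    """Lazy synthetic cohort: ground truth up front, per-subject data on demand.

    Subject recordings are generated independently from per-subject random
    streams derived from ``cfg.seed``, so any subject can be produced in any
    order with bit-identical results.
    """

    def __init__(self, cfg: SimConfig, leadfield: Leadfield | None = None):
        self.cfg = cfg
        if leadfield is None:
            names, pos = equidistant_montage(cfg.n_channels)
            leadfield = compute_leadfield(
                HeadModel(), pos, spacing=cfg.grid_spacing, ch_names=names
            )
        self.leadfield = leadfield
        if leadfield.ch_pos is None:
            raise ValueError("leadfield must carry electrode positions")
        self.events, self.fixations = make_events(cfg)
        self.truth = self._make_ground_truth()

    # -- ground truth -----------------------------------------------------
    def _make_ground_truth(self) -> GroundTruth:
        cfg = self.cfg
        rng = _rng(cfg.seed, 1)
        grid = self.leadfield.grid
        targets = np.asarray(cfg.source_targets, float)
        idx = np.unique(
            [int(np.argmin(np.linalg.norm(grid - t, axis=1))) for t in targets]
        )
        ori = np.array([0.0, 0.35, 0.937])
        ori /= np.linalg.norm(ori)

        g = rng.lognormal(mean=0.0, sigma=cfg.subject_amp_sigma, size=cfg.n_subjects)
        g /= np.exp(cfg.subject_amp_sigma**2 / 2)  # unit-mean gains
        amps = np.asarray(cfg.theta_amp_by_session)
        theta_power = (g[:, None] * amps[None, :]) ** 2

        pupil_amp = np.empty((cfg.n_subjects, cfg.n_sessions))
        mus = np.asarray(cfg.pupil_amp_by_session)
        rhos = np.asarray(cfg.coupling_by_session)
        for s in range(cfg.n_sessions):
            # couple against log-power: subject factors are log-normal, and
            # the analysis correlates dB (log-scale) theta, so the target
            # correlation is defined on the scale the method measures
            z = np.log(theta_power[:, s])
            z = z - z.mean()
            z /= z.std() if z.std() > 0 else 1.0
            eps = rng.standard_normal(cfg.n_subjects)
            raw = rhos[s] * z + np.sqrt(1.0 - rhos[s] ** 2) * eps
            pupil_amp[:, s] = np.clip(mus[s] * (1.0 + cfg.pupil_amp_cv * raw), 0.1 * mus[s], None)
        return GroundTruth(
            source_voxel_indices=idx,
            source_orientation=ori,
            subject_factors=g,
            per_subject_theta_power=theta_power,
            per_subject_pupil_amp=pupil_amp,
            event_table=self.events,
            fixations=self.fixations,
        )

    @property
    def n_samples(self) -> int:
        t_end = float(self.fixations["t_end"].iloc[-1]) + 3.5  # room for +3 s epochs
        return int(np.ceil(t_end * self.cfg.sfreq))

    # -- EEG ---------------------------------------------------------------
    def _source_waveform(self, subject: int, rng: np.random.Generator) -> np.ndarray:
        """Summed dipole moment time series (nA·m) of one subject."""
        cfg = self.cfg
        n_samp = self.n_samples
        n_burst = int(round(cfg.burst_duration * cfg.sfreq))
        env = np.hanning(n_burst)
        t_burst = np.arange(n_burst) / cfg.sfreq
        gain_subj = self.truth.subject_factors[subject]
        amps = np.asarray(cfg.theta_amp_by_session)

        waveform = np.zeros(n_samp)
        ev = self.events
        onsets = ev["onset_sample"].to_numpy()
        sessions = ev["session"].to_numpy()
        phases = rng.uniform(0, 2 * np.pi, size=len(ev))
        jitter = rng.lognormal(0.0, cfg.trial_amp_sigma, size=len(ev))
        jitter /= np.exp(cfg.trial_amp_sigma**2 / 2)
        for k in range(len(ev)):
            o = onsets[k]
            if o + n_burst > n_samp:
                continue
            amp = amps[sessions[k] - 1] * gain_subj * jitter[k]
            waveform[o : o + n_burst] += amp * env * np.sin(
                2 * np.pi * cfg.theta_freq * t_burst + phases[k]
            )
        return waveform

    def subject_source_waveform(self, subject: int) -> np.ndarray:
        """Ground-truth source moment time series (nA·m) of one subject.

        Identical to the waveform embedded in :meth:`subject_eeg` for the
        same subject (same random stream).
        """
        if not 0 <= subject < self.cfg.n_subjects:
            raise ValueError("subject index out of range")
        return self._source_waveform(subject, _rng(self.cfg.seed, 2, subject))

    def sensor_pattern(self) -> np.ndarray:
        """Scalp pattern (µV per nA·m) of the summed active dipoles."""
        ori = self.truth.source_orientation
        pattern = np.zeros(self.leadfield.gain.shape[2])
        for v in self.truth.source_voxel_indices:
            pattern += ori @ self.leadfield.gain[v]
        return pattern * 1e-3  # V/(A·m) → µV/(nA·m)

    def subject_eeg(self, subject: int) -> EEGRecording:
        """Continuous EEG (µV) of one subject over the full timeline."""
        cfg = self.cfg
        if not 0 <= subject < cfg.n_subjects:
            raise ValueError("subject index out of range")
        rng = _rng(cfg.seed, 2, subject)
        lf = self.leadfield
        n_samp = self.n_samples
        n_ch = lf.gain.shape[2]
        pattern = self.sensor_pattern()
        n_burst = int(round(cfg.burst_duration * cfg.sfreq))
        env = np.hanning(n_burst)
        amps = np.asarray(cfg.theta_amp_by_session)
        signal_only = self._source_waveform(subject, rng)
        data = pattern[:, None] * signal_only[None, :]

        # 1/f background scaled to the target theta-band SNR.  The reference
        # burst power is the NOMINAL session-1 amplitude (subject factor 1),
        # so the background level is identical for all subjects and sessions
        # and programmed amplitude differences survive baseline normalisation.
        if cfg.background_snr > 0 and np.abs(pattern).max() > 0:
            bg, bg_theta_frac = _one_over_f_noise(rng, n_ch, n_samp, cfg.sfreq)
            env_rms = float(np.sqrt(np.mean(env**2) / 2.0))  # Hanning × sinusoid
            sig_theta_rms = float(np.abs(pattern).mean()) * env_rms * amps[0]
            scale = sig_theta_rms / (np.sqrt(cfg.background_snr) * bg_theta_frac)
            data += scale * bg
        if cfg.sensor_noise_sd > 0:
            data += rng.normal(0.0, cfg.sensor_noise_sd, size=data.shape)
        return EEGRecording(
            data=data,
            sfreq=cfg.sfreq,
            ch_names=list(lf.ch_names),
            ch_pos=lf.ch_pos,
            reference="none",
        )

    # -- pupil ---------------------------------------------------------------
    def pupil_kernel(self, n_samp: int | None = None) -> np.ndarray:
        """Erlang-family phasic response kernel, unit peak at the peak latency."""
        cfg = self.cfg
        if n_samp is None:
            n_samp = int(round(4.0 * cfg.sfreq))
        t = np.arange(n_samp) / cfg.sfreq
        tp, k = cfg.pupil_peak_latency, cfg.pupil_kernel_shape
        with np.errstate(divide="ignore", invalid="ignore"):
            h = (t / tp) ** k * np.exp(k * (1.0 - t / tp))
        h[0] = 0.0
        return h

    def subject_pupil(self, subject: int) -> PupilTrace:
        """Continuous pupil diameter (mm) of one subject, on the EEG clock."""
        cfg = self.cfg
        if not 0 <= subject < cfg.n_subjects:
            raise ValueError("subject index out of range")
        rng = _rng(cfg.seed, 3, subject)
        n_samp = self.n_samples
        t = np.arange(n_samp) / cfg.sfreq
        d = cfg.pupil_baseline_mm + cfg.pupil_baseline_drift * t / 3600.0

        kern = self.pupil_kernel()
        amps_subj = self.truth.per_subject_pupil_amp[subject]
        ratio = cfg.pupil_angle_ratio
        mult = {30: 2.0 / (1.0 + ratio), 150: 2.0 * ratio / (1.0 + ratio)}
        ev = self.events
        jitter = rng.lognormal(0.0, 0.2, size=len(ev))
        jitter /= np.exp(0.2**2 / 2)
        onsets = ev["onset_sample"].to_numpy()
        sessions = ev["session"].to_numpy()
        angles = ev["angle"].to_numpy()
        for k in range(len(ev)):
            o = onsets[k]
            stop = min(o + kern.size, n_samp)
            a = amps_subj[sessions[k] - 1] * mult[int(angles[k])] * jitter[k]
            d[o:stop] += a * kern[: stop - o]
        if cfg.pupil_noise_sd > 0:
            d += rng.normal(0.0, cfg.pupil_noise_sd, size=n_samp)
        return PupilTrace(diameter=d, sfreq=cfg.sfreq)
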