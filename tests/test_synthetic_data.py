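"""Cohort generator: design counts, determinism, programmed physiology."""

import numpy as np
import pytest

from thetapupil.synthetic_data import Cohort, SimConfig, make_events
from thetapupil.pupillometry import preprocess_pupil, tonic_baseline

from conftest import small_cfg


class TestMakeEvents:
    def test_default_design_counts(self):
        """Full design: 4 × 1200 trials with 840 Go / 360 Nogo per session."""
        trials, fixations = make_events(SimConfig())
        per = trials.groupby(["session", "trial_type"]).size().unstack()
        assert (per["go"] == 840).all() and (per["nogo"] == 360).all()
        assert len(trials) == 4800
        # equal rotation-angle counts within each trial type and session
        ang = trials.groupby(["session", "trial_type", "angle"]).size().unstack()
        assert (ang[30] == ang[150]).all()

    def test_seven_three_ratio_small(self):
        cfg = small_cfg(trials_per_session=10)
        trials, _ = make_events(cfg)
        one = trials[trials.session == 1]
        assert (one.trial_type == "go").sum() == 7
        assert (one.trial_type == "nogo").sum() == 3

    def test_fixation_schedule(self):
        trials, fx = make_events(SimConfig())
        kinds = fx["kind"].value_counts()
        assert kinds["short"] == 19 and kinds["start"] == 1 and kinds["end"] == 1
        assert fx.iloc[0]["t_end"] - fx.iloc[0]["t_start"] == pytest.approx(120.0)
        # short periods are spread over the middle of the run
        short = fx[fx.kind == "short"]["t_start"].to_numpy()
        assert np.all(np.diff(short) > 0)

    def test_onsets_strictly_increasing_with_min_gap(self):
        cfg = small_cfg(trials_per_session=20)
        trials, _ = make_events(cfg)
        gaps = np.diff(trials["onset_s"].to_numpy())
        min_gap = (cfg.fixation_range[0] + cfg.stimulus_duration) / 1000.0
        assert np.all(gaps >= min_gap - 1e-9)

    def test_determinism_and_seed_sensitivity(self):
        cfg = small_cfg(seed=1)
        t1, _ = make_events(cfg)
        t2, _ = make_events(small_cfg(seed=1))
        t3, _ = make_events(small_cfg(seed=2))
        assert t1.equals(t2)
        assert not t1.equals(t3)

    def test_error_rate_flags_trials(self):
        trials, _ = make_events(small_cfg(error_rate=0.3, trials_per_session=100))
        frac = 1.0 - trials["correct"].mean()
        assert 0.2 < frac < 0.4

    @pytest.mark.parametrize(
        "kw",
        [
            dict(go_fraction=0.66),  # non-integer Go count
            dict(theta_amp_by_session=(48.0, 60.0)),  # increasing amplitude
            dict(coupling_by_session=(-1.5, 0.0)),  # |rho| > 1
            dict(coupling_by_session=(-0.65, 0.0, 0.0)),  # length mismatch
        ],
    )
    def test_invalid_configuration_raises(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)


class TestGroundTruth:
    def test_sources_inside_brain(self, tiny_cohort):
        lf = tiny_cohort.leadfield
        r = np.linalg.norm(lf.grid[tiny_cohort.truth.source_voxel_indices], axis=1)
        assert np.all(r < lf.head.brain_radius)

    def test_theta_power_follows_session_amplitudes(self, tiny_cohort):
        tp = tiny_cohort.truth.per_subject_theta_power
        assert np.all(tp[:, 0] > tp[:, 1])  # programmed decline

    def test_coupling_construction_recovers_target_r(self, leadfield16):
        """Across 30 regenerations the realised S1 coupling sits near −0.8.

        The coupling is defined on the log-power scale (the scale the dB
        analysis measures), so that is where the target is checked.
        """
        rs = []
        for seed in range(30):
            cfg = small_cfg(
                n_subjects=27, seed=seed, coupling_by_session=(-0.8, 0.0)
            )
            t = Cohort(cfg, leadfield=leadfield16).truth
            rs.append(
                np.corrcoef(
                    np.log(t.per_subject_theta_power[:, 0]), t.per_subject_pupil_amp[:, 0]
                )[0, 1]
            )
        assert abs(np.mean(rs) - (-0.8)) < 0.1

    def test_zero_coupling_gives_small_r(self, leadfield16):
        rs = []
        for seed in range(30):
            t = Cohort(small_cfg(n_subjects=27, seed=seed), leadfield=leadfield16).truth
            rs.append(
                np.corrcoef(
                    np.log(t.per_subject_theta_power[:, 1]), t.per_subject_pupil_amp[:, 1]
                )[0, 1]
            )
        assert abs(np.mean(rs)) < 0.1


class TestSubjectData:
    def test_eeg_deterministic_and_order_free(self, tiny_cohort, leadfield16):
        a = tiny_cohort.subject_eeg(1)
        fresh = Cohort(tiny_cohort.cfg, leadfield=leadfield16)
        b = fresh.subject_eeg(1)  # generated without touching subject 0
        assert np.array_equal(a.data, b.data)

    def test_noiseless_bursts_dominate_poststimulus(self, leadfield16):
        """Without noise, theta power after stimulus dwarfs the pre-stimulus level."""
        cfg = small_cfg(background_snr=0.0, sensor_noise_sd=0.0, n_subjects=1)
        co = Cohort(cfg, leadfield=leadfield16)
        rec = co.subject_eeg(0)
        ev = co.events.iloc[0]
        sf = int(cfg.sfreq)
        o = int(ev.onset_sample)
        ch = np.argmax(np.abs(co.sensor_pattern()))
        post = rec.data[ch, o : o + sf].std()
        pre = rec.data[ch, o - sf // 2 : o].std()
        assert post > 100 * max(pre, 1e-12)

    def test_equal_session_amplitudes_give_equal_truth(self, leadfield16):
        cfg = small_cfg(theta_amp_by_session=(50.0, 50.0))
        co = Cohort(cfg, leadfield=leadfield16)
        tp = co.truth.per_subject_theta_power
        assert np.allclose(tp[:, 0], tp[:, 1])

    def test_source_waveform_matches_embedded_signal(self, leadfield16):
        cfg = small_cfg(background_snr=0.0, sensor_noise_sd=0.0, n_subjects=1)
        co = Cohort(cfg, leadfield=leadfield16)
        rec = co.subject_eeg(0)
        expect = co.sensor_pattern()[:, None] * co.subject_source_waveform(0)[None, :]
        assert np.abs(rec.data - expect).max() == 0.0

    def test_subject_index_out_of_range(self, tiny_cohort):
        with pytest.raises(ValueError):
            tiny_cohort.subject_eeg(99)
        with pytest.raises(ValueError):
            tiny_cohort.subject_pupil(-1)


class TestPupil:
    def test_pupil_deterministic(self, tiny_cohort, leadfield16):
        a = tiny_cohort.subject_pupil(2).diameter
        b = Cohort(tiny_cohort.cfg, leadfield=leadfield16).subject_pupil(2).diameter
        assert np.array_equal(a, b)

    def test_drift_recovered_from_resting_baseline(self, leadfield16):
        """0.1 mm/h programmed drift appears between start and end fixation."""
        cfg = small_cfg(
            pupil_baseline_drift=0.1, pupil_noise_sd=0.001, trials_per_session=40
        )
        co = Cohort(cfg, leadfield=leadfield16)
        trace = preprocess_pupil(co.subject_pupil(0))
        tb = tonic_baseline(trace, co.fixations)
        start = tb[tb.kind == "start"]["mean_diameter_mm"].iloc[0]
        end = tb[tb.kind == "end"]["mean_diameter_mm"].iloc[0]
        dur_h = (co.fixations["t_end"].iloc[-1] - 60.0) / 3600.0
        assert end - start == pytest.approx(0.1 * dur_h, abs=0.02)

    def test_zero_drift_start_equals_end(self, leadfield16):
        cfg = small_cfg(pupil_baseline_drift=0.0, pupil_noise_sd=0.001)
        co = Cohort(cfg, leadfield=leadfield16)
        trace = preprocess_pupil(co.subject_pupil(0))
        tb = tonic_baseline(trace, co.fixations)
        start = tb[tb.kind == "start"]["mean_diameter_mm"].iloc[0]
        end = tb[tb.kind == "end"]["mean_diameter_mm"].iloc[0]
        assert end == pytest.approx(start, abs=0.01)

    def test_angle_modulation(self, tiny_cohort):
        """150°-rotated trials carry larger phasic responses than 30° ones."""
        cfg = tiny_cohort.cfg
        ratio = cfg.pupil_angle_ratio
        assert ratio > 1.0  # generator condition for the working-memory effect
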