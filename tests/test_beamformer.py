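"""CSD estimation, DICS/LCMV filters, session contrast, ROI selection."""

import numpy as np
import pandas as pd
import pytest

from thetapupil import beamformer as bf
from thetapupil.eeg_preprocess import EpochSet
from thetapupil.montage import equidistant_montage
from thetapupil.synthetic_data import Cohort

from conftest import small_cfg


def _epochs(data, sfreq=256.0, tmin=-2.0):
    names, pos = equidistant_montage(max(8, data.shape[1]))
    times = tmin + np.arange(data.shape[2]) / sfreq
    return EpochSet(
        data=data,
        times=times,
        meta=pd.DataFrame(dict(session=[1] * data.shape[0])),
        sfreq=sfreq,
        ch_names=names[: data.shape[1]],
        ch_pos=pos[: data.shape[1]],
    )


class TestCSD:
    def test_identical_sinusoids_full_coherence(self):
        t = np.arange(int(5 * 256)) / 256.0
        x = np.sin(2 * np.pi * 5.5 * t)
        data = np.stack([x, x])[None, :, :]
        csd = bf.compute_csd(_epochs(data, tmin=-2.0), (0.0, 1.0))
        c = csd.csd
        coh = np.abs(c[0, 1]) / np.sqrt(c[0, 0].real * c[1, 1].real)
        assert coh == pytest.approx(1.0, abs=1e-6)

    def test_hermitian_exact(self, rng):
        data = rng.normal(size=(6, 4, 1280))
        csd = bf.compute_csd(_epochs(data), (0.25, 1.0))
        assert np.allclose(csd.csd, csd.csd.conj().T)
        assert np.all(np.diagonal(csd.csd).real >= 0)

    def test_independent_noise_low_coherence(self, rng):
        data = rng.normal(size=(500, 2, 1280))
        csd = bf.compute_csd(_epochs(data), (0.0, 1.0)).csd
        coh = np.abs(csd[0, 1]) / np.sqrt(csd[0, 0].real * csd[1, 1].real)
        assert coh < 0.1

    def test_agrees_with_mne_multitaper(self, rng):
        """mne's csd_array_multitaper as an independent route (same tapers)."""
        mne = pytest.importorskip("mne")
        from mne.time_frequency import csd_array_multitaper

        data = rng.normal(size=(20, 4, 256)) + 1.0
        ep = _epochs(data, tmin=0.0)
        mine = bf.compute_csd(ep, (0.0, 1.0), band=(4.0, 7.0), bandwidth=3.0).csd
        res = csd_array_multitaper(
            data, 256.0, fmin=4.0, fmax=7.0, bandwidth=3.0, verbose="error"
        ).mean()
        theirs = res.get_data()
        # compare normalised shapes (scaling conventions differ)
        corr = np.corrcoef(np.abs(mine).ravel(), np.abs(theirs).ravel())[0, 1]
        assert corr > 0.95

    def test_window_too_short_raises(self, rng):
        ep = _epochs(rng.normal(size=(3, 4, 1280)))
        with pytest.raises(ValueError):
            bf.compute_csd(ep, (0.0, 0.2), bandwidth=3.0)


class TestDICS:
    def test_unit_gain_at_own_voxel(self, leadfield16, rng):
        lf = leadfield16
        c = rng.normal(size=(16, 16))
        c = c @ c.T + 16 * np.eye(16)
        filt = bf.dics_filter(
            bf.CSDMatrix(csd=c.astype(complex), window="combined", band=(4, 7), n_trials=10),
            lf,
        )
        v = 123
        gain_along_ori = filt.orientations[v] @ lf.gain[v]
        assert filt.weights[v] @ gain_along_ori == pytest.approx(1.0, abs=1e-8)

    def test_localizes_single_dipole(self, leadfield16_1cm):
        """DICS power map peaks within one grid step of a simulated source."""
        cfg = small_cfg(
            n_subjects=1,
            trials_per_session=10,
            background_snr=10.0,
            sensor_noise_sd=0.5,
            source_targets=((0.0, 0.03, 0.05),),
            grid_spacing=0.01,
        )
        co = Cohort(cfg, leadfield=leadfield16_1cm)
        from thetapupil.pipeline import preprocess_subject

        ep = preprocess_subject(co.subject_eeg(0), co.events, reject=False)
        csd_pre = bf.compute_csd(ep, (-0.75, 0.0))
        csd_post = bf.compute_csd(ep, (0.25, 1.0))
        filt = bf.dics_filter(csd_pre + csd_post, leadfield16_1cm)
        ratio = bf.dics_power(filt, csd_post) / bf.dics_power(filt, csd_pre)
        peak = int(np.argmax(ratio))
        truth = co.truth.source_voxel_indices[0]
        dist = np.linalg.norm(leadfield16_1cm.grid[peak] - leadfield16_1cm.grid[truth])
        assert dist <= 0.01 + 1e-9


class TestContrast:
    def test_hand_evaluated_examples(self):
        one = np.ones(1)
        p, ok = bf.contrast_from_powers(one, 2 * one, one, 6 * one)
        assert p[0] == pytest.approx(0.5)  # R4 = 3 R1
        p, _ = bf.contrast_from_powers(one, 3 * one, one, 3 * one)
        assert p[0] == 0.0

    def test_bounded_and_antisymmetric(self, rng):
        q = rng.uniform(1e-6, 1e3, size=(4, 10_000))
        p, ok = bf.contrast_from_powers(*q)
        assert ok.all()
        assert np.all(np.abs(p) <= 1.0)
        p_swapped, _ = bf.contrast_from_powers(q[2], q[3], q[0], q[1])
        assert np.allclose(p_swapped, -p)

    def test_literal_form_cancels_prestimulus(self, rng):
        q = rng.uniform(0.1, 10.0, size=(4, 100))
        p, _ = bf.contrast_from_powers(*q, eq2_literal=True)
        expect = (q[3] - q[1]) / (q[3] + q[1])
        assert np.allclose(p, expect)

    def test_zero_prestimulus_flagged_invalid(self):
        p, ok = bf.contrast_from_powers(
            np.zeros(3), np.ones(3), np.ones(3), np.ones(3)
        )
        assert not ok.any()


class TestTopVoxels:
    def _map(self, vals, grid=None):
        vals = np.asarray(vals, float)
        if grid is None:
            grid = np.column_stack(
                [np.arange(vals.size) * 0.01, np.zeros(vals.size), np.zeros(vals.size)]
            )
        return bf.ContrastMap(p_diff=vals, valid=np.ones(vals.size, bool), grid=grid)

    def test_fraction_arithmetic(self, rng):
        sel = bf.select_top_voxels(self._map(rng.normal(size=200)), fraction=0.01)
        assert len(sel["indices"]) == 2

    def test_keeps_at_least_one_voxel(self, rng):
        sel = bf.select_top_voxels(self._map(rng.normal(size=20)), fraction=0.01)
        assert len(sel["indices"]) == 1

    def test_all_equal_tie_break_lowest_index(self):
        sel = bf.select_top_voxels(self._map(np.ones(100)), fraction=0.02)
        assert list(sel["indices"]) == [0, 1]

    def test_roi_labeling(self):
        grid = np.array([[0.0, 0.03, 0.055], [0.0, -0.05, 0.0]])
        vals = np.array([1.0, 0.9])
        cmap = bf.ContrastMap(p_diff=vals, valid=np.ones(2, bool), grid=grid)
        sel = bf.select_top_voxels(cmap, fraction=0.5, spacing=0.01)
        assert sel["roi_labels"] == ["superior_frontal"]


class TestLCMV:
    def test_noiseless_reconstruction_correlates_with_truth(self, leadfield16):
        cfg = small_cfg(
            n_subjects=1,
            trials_per_session=10,
            background_snr=0.0,
            sensor_noise_sd=0.0,
            source_targets=((0.0, 0.03, 0.05),),
        )
        co = Cohort(cfg, leadfield=leadfield16)
        rec = co.subject_eeg(0)
        from thetapupil.eeg_preprocess import epoch

        ep = epoch(rec, co.events)
        truth_wave = co.subject_source_waveform(0)
        _, times, src = bf.lcmv_reconstruct(
            ep,
            leadfield16,
            np.asarray(co.truth.source_voxel_indices),
            return_timecourse=True,
        )
        onsets = ep.meta["onset_sample"].to_numpy()
        offs = int(round(-ep.times[0] * cfg.sfreq))
        corrs = []
        for k, o in enumerate(onsets):
            w = truth_wave[o - offs : o - offs + src.shape[1]]
            corrs.append(abs(np.corrcoef(src[k], w)[0, 1]))
        assert min(corrs) > 0.99

    def test_unit_gain_property(self, leadfield16, rng):
        data = rng.normal(size=(10, 16, 512))
        ep = _epochs(data)
        _, _, src = bf.lcmv_reconstruct(
            ep, leadfield16, np.array([50]), return_timecourse=True
        )
        # unit gain is enforced inside _scalar_weights; verify via the filter
        from thetapupil.beamformer import _regularized_inverse, _scalar_weights

        x = ep.data
        xc = x - x.mean(axis=-1, keepdims=True)
        cov = np.einsum("tcs,tds->cd", xc, xc) / (x.shape[0] * x.shape[2])
        w, ori = _scalar_weights(
            leadfield16.gain[[50]], cov, _regularized_inverse(cov, 0.05)
        )
        assert w[0] @ (ori[0] @ leadfield16.gain[50]) == pytest.approx(1.0, abs=1e-8)

    def test_empty_roi_raises(self, leadfield16, rng):
        ep = _epochs(rng.normal(size=(4, 16, 512)))
        with pytest.raises(ValueError, match="empty"):
            bf.lcmv_reconstruct(ep, leadfield16, np.array([], dtype=int))
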