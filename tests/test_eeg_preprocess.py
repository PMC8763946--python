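"""Filtering, epoching, artifact criteria, baseline and CSD transform."""

import numpy as np
import pandas as pd
import pytest

from thetapupil.eeg_preprocess import (
    EEGRecording,
    apply_filters,
    baseline_correct,
    csd_transform,
    epoch,
    reject_artifacts,
    rereference_average,
    resample,
)
from thetapupil.montage import equidistant_montage


def _rec(data, sfreq=256.0, n_ch=None):
    data = np.atleast_2d(np.asarray(data, float))
    n_ch = data.shape[0]
    names, pos = equidistant_montage(max(8, n_ch))
    return EEGRecording(
        data=data, sfreq=sfreq, ch_names=names[:n_ch], ch_pos=pos[:n_ch]
    )


def _sinusoid(f, sfreq=256.0, dur=8.0, amp=1.0):
    t = np.arange(int(dur * sfreq)) / sfreq
    return amp * np.sin(2 * np.pi * f * t)


class TestFilters:
    def test_passband_preserves_5hz(self):
        # long signal with generous margins: the 0.5 Hz high-pass has a
        # multi-second impulse response, so edge transients travel far
        x = _sinusoid(5.0, dur=24.0)
        out = apply_filters(_rec(x), extra_lp=None).data[0]
        mid = slice(int(8 * 256), -int(8 * 256))
        assert np.abs(out[mid] - x[mid]).max() < 0.01

    def test_notch_attenuates_50hz(self):
        x = _sinusoid(50.0)
        out = apply_filters(_rec(x), lp=90.0, extra_lp=None, notch=50.0).data[0]
        atten = 20 * np.log10(x[512:-512].std() / max(out[512:-512].std(), 1e-15))
        assert atten >= 20.0

    def test_extra_lowpass_attenuates_30hz(self):
        x = _sinusoid(30.0)
        out = apply_filters(_rec(x)).data[0]
        atten = 20 * np.log10(x[512:-512].std() / max(out[512:-512].std(), 1e-15))
        assert atten >= 20.0

    def test_dc_offset_removed(self):
        out = apply_filters(_rec(np.full(2048, 100.0))).data[0]
        assert np.abs(out.mean()) < 1e-6

    def test_linearity(self, rng):
        x = rng.normal(size=(1, 2048))
        y = rng.normal(size=(1, 2048))
        fa = apply_filters(_rec(2 * x + 3 * y)).data
        fb = 2 * apply_filters(_rec(x)).data + 3 * apply_filters(_rec(y)).data
        assert np.abs(fa - fb).max() < 1e-9

    def test_lowpass_above_nyquist_raises(self):
        with pytest.raises(ValueError):
            apply_filters(_rec(np.zeros(1024)), lp=200.0)

    def test_average_reference_zero_mean(self, rng):
        rec = _rec(rng.normal(size=(8, 512)) + 5.0)
        out = rereference_average(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12


class TestResample:
    def test_downsample_sinusoid_rms(self):
        sf = 500.0
        t = np.arange(int(8 * sf)) / sf
        rec = _rec(np.sin(2 * np.pi * 5 * t), sfreq=sf)
        out = resample(rec, 256.0)
        t2 = np.arange(out.n_samples) / out.sfreq
        ref = np.sin(2 * np.pi * 5 * t2)
        mid = slice(256, -256)
        err = np.sqrt(np.mean((out.data[0, mid] - ref[mid]) ** 2))
        assert err < 0.01
        assert out.sfreq == pytest.approx(256.0)

    def test_identity_when_target_equals_sfreq(self, rng):
        rec = _rec(rng.normal(size=(2, 512)))
        assert resample(rec, 256.0) is rec

    def test_event_onset_remap(self):
        sf = 500.0
        rec = _rec(np.zeros((1, int(4 * sf))), sfreq=sf)
        ev = pd.DataFrame(dict(onset_sample=[500]))
        _, ev2 = resample(rec, 256.0, events=ev)
        assert ev2["onset_sample"].iloc[0] == 256

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample(_rec(np.zeros(512)), 512.0)


def _events(onsets, sfreq=256.0, **kw):
    n = len(onsets)
    base = dict(
        onset_sample=[int(round(o * sfreq)) for o in onsets],
        session=[1] * n,
        trial_type=["go"] * n,
        angle=[30] * n,
        correct=[True] * n,
    )
    base.update(kw)
    return pd.DataFrame(base)


class TestEpoch:
    def test_window_arithmetic(self, rng):
        rec = _rec(rng.normal(size=(2, 256 * 20)))
        ep = epoch(rec, _events([10.0]))
        assert ep.data.shape == (1, 2, 1280)
        assert np.array_equal(ep.data[0], rec.data[:, 2048:3328])
        assert ep.times[0] == pytest.approx(-2.0)

    def test_incorrect_trials_excluded(self, rng):
        rec = _rec(rng.normal(size=(1, 256 * 30)))
        ev = _events([5.0, 10.0, 15.0], correct=[True, False, True])
        ep = epoch(rec, ev)
        assert ep.n_epochs == 2

    def test_out_of_bounds_dropped(self, rng):
        rec = _rec(rng.normal(size=(1, 256 * 12)))
        ep = epoch(rec, _events([1.0, 6.0, 11.0]))  # first and last out of range
        assert ep.n_epochs == 1


class TestArtifactRejection:
    def _flat_epochs(self, n=1, amp=0.0):
        sf = 256.0
        times = -2.0 + np.arange(int(5 * sf)) / sf
        data = np.full((n, 1, times.size), 0.0)
        rng = np.random.default_rng(0)
        data += rng.normal(0, 1.0, size=data.shape)  # healthy background
        return data, times

    def _make(self, data, times, sfreq=256.0):
        from thetapupil.eeg_preprocess import EpochSet

        names, pos = equidistant_montage(8)
        n_ch = data.shape[1]
        meta = pd.DataFrame(dict(session=[1] * data.shape[0]))
        return EpochSet(
            data=data, times=times, meta=meta, sfreq=sfreq,
            ch_names=names[:n_ch], ch_pos=pos[:n_ch],
        )

    def test_voltage_step_rejected(self):
        data, times = self._flat_epochs()
        i0 = np.argmin(np.abs(times))
        data[0, 0, i0] += 200.0  # 51.2 µV/ms at 256 Hz
        ep = reject_artifacts(self._make(data, times))
        assert ep.meta["bad_gradient"].iloc[0]
        assert not ep.meta["kept"].iloc[0]

    def test_flat_epoch_rejected_for_low_activity(self):
        sf = 256.0
        times = -2.0 + np.arange(int(5 * sf)) / sf
        data = 0.15 * np.sin(2 * np.pi * 1.0 * times)[None, None, :]  # 0.3 µV range
        ep = reject_artifacts(self._make(data, times))
        assert ep.meta["bad_low_activity"].iloc[0]

    def test_moderate_sinusoid_kept(self):
        sf = 256.0
        times = -2.0 + np.arange(int(5 * sf)) / sf
        data = 10.0 * np.sin(2 * np.pi * 5.0 * times)[None, None, :]
        ep = reject_artifacts(self._make(data, times))
        assert ep.meta["kept"].iloc[0]

    def test_amplitude_limit(self):
        data, times = self._flat_epochs()
        data[0, 0, np.argmin(np.abs(times))] = 160.0
        ep = reject_artifacts(self._make(data, times))
        assert ep.meta["bad_amplitude"].iloc[0]

    def test_ptp_criterion(self):
        sf = 256.0
        times = -2.0 + np.arange(int(5 * sf)) / sf
        # 10 Hz, 120 µV peak-to-peak: full swing inside any 200 ms interval,
        # gradient stays below 30 µV/ms and amplitude below ±150 µV
        data = 60.0 * np.sin(2 * np.pi * 10.0 * times)[None, None, :]
        ep = reject_artifacts(self._make(data, times))
        assert ep.meta["bad_ptp"].iloc[0]
        assert not ep.meta["bad_gradient"].iloc[0]

    def test_flags_invariant_to_channel_permutation(self, rng):
        sf = 256.0
        times = -2.0 + np.arange(int(5 * sf)) / sf
        data = rng.normal(0, 30.0, size=(6, 4, times.size))
        ep = reject_artifacts(self._make(data, times))
        perm = rng.permutation(4)
        ep_p = reject_artifacts(self._make(data[:, perm, :], times))
        assert np.array_equal(
            ep.meta["kept"].to_numpy(), ep_p.meta["kept"].to_numpy()
        )


class TestBaseline:
    def test_constant_epoch_zeroed_and_idempotent(self):
        sf = 256.0
        times = -2.0 + np.arange(int(5 * sf)) / sf
        from thetapupil.eeg_preprocess import EpochSet

        names, pos = equidistant_montage(8)
        ep = EpochSet(
            data=np.full((2, 1, times.size), 50.0),
            times=times,
            meta=pd.DataFrame(dict(session=[1, 1])),
            sfreq=sf,
            ch_names=names[:1],
            ch_pos=pos[:1],
        )
        out = baseline_correct(ep)
        assert np.abs(out.data).max() == 0.0
        sl = (out.times >= -0.2) & (out.times < 0.0)
        out2 = baseline_correct(out)
        assert np.abs(out2.data - out.data).max() == 0.0
        assert np.abs(out.data[:, :, sl].mean()) == 0.0


class TestCSD:
    def _epochs(self, data, sfreq=256.0):
        from thetapupil.eeg_preprocess import EpochSet

        names, pos = equidistant_montage(data.shape[1])
        times = np.arange(data.shape[2]) / sfreq
        return EpochSet(
            data=data, times=times, meta=pd.DataFrame(dict(session=[1] * data.shape[0])),
            sfreq=sfreq, ch_names=names, ch_pos=pos,
        )

    def test_uniform_potential_maps_to_zero(self):
        ep = self._epochs(np.full((1, 40, 64), 7.5))
        out = csd_transform(ep)
        assert np.abs(out.data).max() < 1e-6

    def test_output_sums_to_zero_on_full_sphere(self, rng):
        """Channel sums approximate the vanishing surface integral of the
        Laplacian — a quadrature property, so it requires sampling the whole
        sphere (on a partial cap the sum is not constrained)."""
        from thetapupil.eeg_preprocess import EpochSet

        n = 64
        k = np.arange(n)
        z = 1 - (k + 0.5) * 2 / n
        rho = np.sqrt(1 - z**2)
        phi = k * np.pi * (3 - np.sqrt(5))
        pos = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
        # smooth (band-limited) potential fields: mixtures of Gaussian bumps
        centers = rng.normal(size=(6, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        amps = rng.normal(size=(6, 16))
        topo = np.exp((pos @ centers.T - 1.0) / 0.3)  # (n, 6)
        data = np.tile((topo @ amps)[None, :, :], (2, 1, 1))
        ep = EpochSet(
            data=data,
            times=np.arange(16) / 256.0,
            meta=pd.DataFrame(dict(session=[1, 1])),
            sfreq=256.0,
            ch_names=[f"E{i}" for i in range(n)],
            ch_pos=pos,
        )
        out = csd_transform(ep)
        sums = out.data.sum(axis=1)
        assert np.abs(sums).max() < 0.1 * np.abs(out.data).max()

    def test_focal_pattern_peak_preserved(self):
        """The surface Laplacian of a focal bump peaks at the same channel."""
        names, pos = equidistant_montage(40)
        src = pos[12]
        topo = np.exp(-((1 - pos @ src) / 0.08))
        ep = self._epochs(np.tile(topo[None, :, None], (1, 1, 8)))
        out = csd_transform(ep)
        assert np.argmax(out.data[0, :, 4]) == 12

    def test_too_few_channels_raises(self, rng):
        ep = self._epochs(rng.normal(size=(1, 16, 32)))
        with pytest.raises(ValueError, match="32 channels"):
            csd_transform(ep)
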