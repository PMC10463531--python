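import math

import numpy as np
import pytest

from pactacs import features as ft
from pactacs import synth, task

PI = math.pi


# ---------------------------------------------------------------------------
# independent brute-force oracles

def itpc_bruteforce(epochs: ft.EpochSet, freqs, time_idx):
    """ITPC by direct (loop) correlation with the Morlet wavelet at
    selected time indices — independent of the FFT-convolution path."""
    fs, pad = epochs.fs, epochs.pad
    out = np.empty((len(freqs), len(time_idx)))
    for fi, f in enumerate(freqs):
        w = ft.morlet_wavelet(f, fs, float(ft.default_cycles(f)))
        half = len(w) // 2
        for ti, t in enumerate(time_idx):
            c = t + pad  # position within the padded epoch
            acc = 0j
            for trial in epochs.padded:
                lo, hi = c - half, c + half + 1
                a, b = max(lo, 0), min(hi, len(trial))
                v = np.sum(trial[a:b] * np.conj(w[a - lo : len(w) - (hi - b)]))
                acc += v / abs(v)
            out[fi, ti] = abs(acc) / len(epochs.padded)
    return out


def mi_bruteforce(phase, amp, n_bins=18):
    """Tort MI by explicit per-bin loops."""
    means = []
    for k in range(n_bins):
        lo = -PI + k * 2 * PI / n_bins
        hi = lo + 2 * PI / n_bins
        if k == n_bins - 1:
            sel = (phase >= lo) & (phase <= hi)
        else:
            sel = (phase >= lo) & (phase < hi)
        means.append(amp[sel].mean() if sel.any() else 0.0)
    p = np.array(means) / np.sum(means)
    h = -sum(pk * math.log(pk) for pk in p if pk > 0)
    return (math.log(n_bins) - h) / math.log(n_bins)


# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_dc_offset_removed(self, schedule):
        rec = synth.gen_eeg(synth.SyntheticSubjectSpec(seed=1), schedule)
        rec.eeg = np.full_like(rec.eeg, 50.0)
        out = ft.preprocess(rec)
        assert abs(out.eeg.mean()) < 1e-6

    def test_60hz_notched_and_10hz_preserved(self, schedule):
        fs = 2048.0
        rec = synth.gen_eeg(synth.SyntheticSubjectSpec(seed=1), schedule)
        t = np.arange(len(rec.eeg)) / fs
        for f0, check in ((60.0, "notch"), (10.0, "pass")):
            rec.eeg = np.sin(2 * PI * f0 * t)
            y = ft.preprocess(rec).eeg[int(fs) : -int(fs)]
            ratio = np.sqrt(np.mean(y**2) / 0.5)  # output/input RMS
            if check == "notch":
                assert 20 * np.log10(ratio) < -20
            else:
                assert ratio == pytest.approx(1.0, abs=0.05)

    def test_low_fs_rejected(self, schedule):
        spec = synth.SyntheticSubjectSpec(seed=1, fs=128.0)
        rec = synth.gen_eeg(spec, schedule)
        with pytest.raises(ValueError):
            ft.preprocess(rec)


class TestEpochAndReject:
    def test_window_length_is_fs(self, clean_recording):
        epochs = ft.epoch_and_reject(ft.preprocess(clean_recording))
        assert epochs.epochs.shape[1] == int(clean_recording.fs)

    def test_clean_fixture_keeps_all(self, clean_recording):
        epochs = ft.epoch_and_reject(ft.preprocess(clean_recording))
        assert epochs.rejected_trial_ids == []
        assert epochs.n_kept == 144

    def test_threshold_boundary_spike(self, clean_recording):
        rec = ft.preprocess(clean_recording)
        x = rec.eeg.copy()
        onset = int(rec.events["sample"].iloc[5])
        x[onset - 1024] = 100.1  # single sample just above threshold
        rec2 = synth.Recording(eeg=x, eog=rec.eog, events=rec.events, fs=rec.fs)
        epochs = ft.epoch_and_reject(rec2)
        assert 5 in epochs.rejected_trial_ids

    def test_event_too_close_to_start_is_invalid(self, clean_recording):
        rec = ft.preprocess(clean_recording)
        events = rec.events.copy()
        events.loc[0, "sample"] = 100  # < 1 s of history
        rec2 = synth.Recording(eeg=rec.eeg, eog=rec.eog, events=events, fs=rec.fs)
        epochs = ft.epoch_and_reject(rec2)
        assert 0 in epochs.invalid_trial_ids
        assert 0 not in epochs.rejected_trial_ids

    def test_rejection_idempotent(self, clean_recording):
        rec = ft.preprocess(clean_recording)
        first = ft.epoch_and_reject(rec)
        events = rec.events.iloc[first.kept_trial_ids].reset_index(drop=True)
        rec2 = synth.Recording(eeg=rec.eeg, eog=rec.eog, events=events, fs=rec.fs)
        second = ft.epoch_and_reject(rec2)
        assert second.rejected_trial_ids == []
        assert second.n_kept == first.n_kept


class TestITPC:
    fs = 256.0

    def _epochs(self, trials):
        return ft.EpochSet.from_array(np.asarray(trials), self.fs)

    def test_identical_trials_give_unit_itpc(self, rng):
        trial = rng.standard_normal(int(self.fs))
        epochs = self._epochs([trial] * 8)
        tfmap = ft.itpc(epochs, freqs=np.arange(2, 41, 2))
        assert np.allclose(tfmap.values, 1.0, atol=1e-9)

    def test_random_phase_mean_is_rayleigh(self, rng):
        # 100 trials of white noise: iid uniform phases at every (f, t)
        epochs = self._epochs(rng.standard_normal((100, int(self.fs))))
        tfmap = ft.itpc(epochs, freqs=np.arange(5, 96, 10))
        assert tfmap.values.mean() == pytest.approx(math.sqrt(PI) / 2 / 10, abs=0.02)

    def test_half_locked_half_random(self, rng):
        t = np.arange(int(self.fs)) / self.fs
        locked = [np.sin(2 * PI * 10 * t)] * 50
        rand = [np.sin(2 * PI * 10 * t + rng.uniform(0, 2 * PI)) for _ in range(50)]
        tfmap = ft.itpc(self._epochs(locked + rand), freqs=np.array([10.0]))
        centre = tfmap.values[0, int(self.fs) // 4 : -int(self.fs) // 4]
        assert centre.mean() == pytest.approx(0.5, abs=0.05)

    def test_amplitude_scaling_invariance(self, rng):
        trials = rng.standard_normal((10, int(self.fs)))
        scales = rng.uniform(0.1, 10, size=(10, 1))
        a = ft.itpc(self._epochs(trials), freqs=np.arange(4, 41, 4)).values
        b = ft.itpc(self._epochs(trials * scales), freqs=np.arange(4, 41, 4)).values
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_agrees_with_direct_convolution(self, rng):
        epochs = self._epochs(rng.standard_normal((5, int(self.fs))))
        freqs = np.array([5.0, 13.0, 40.0])
        tfmap = ft.itpc(epochs, freqs=freqs)
        time_idx = [40, 128, 200]
        brute = itpc_bruteforce(epochs, freqs, time_idx)
        np.testing.assert_allclose(tfmap.values[:, time_idx], brute, atol=1e-6)

    def test_requires_two_trials(self, rng):
        with pytest.raises(ValueError):
            ft.itpc(self._epochs(rng.standard_normal((1, int(self.fs)))))


class TestWindowMean:
    def _map(self, values, fs=2048.0):
        n = values.shape[1]
        return ft.TimeFreqMap(values=values, freqs=np.arange(1, values.shape[0] + 1),
                              times=np.arange(n) / fs - 1.0, n_trials=5)

    def test_constant_map(self):
        tfmap = self._map(np.full((100, 2048), 0.37))
        means = ft.window_mean(tfmap)
        assert len(means) == 6
        assert all(v == pytest.approx(0.37) for v in means.values())

    def test_checkerboard_matches_bruteforce(self, rng):
        values = rng.uniform(size=(100, 2048))
        tfmap = self._map(values)
        means = ft.window_mean(tfmap)
        for name, ((flo, fhi), (tlo, thi)) in ft.ITPC_WINDOWS.items():
            fm = (tfmap.freqs >= flo) & (tfmap.freqs <= fhi)
            tm = (tfmap.times >= tlo) & (tfmap.times < thi)
            expected = values[fm][:, tm].mean()
            assert means[name] == pytest.approx(expected, abs=1e-12)

    def test_out_of_grid_window_rejected(self):
        tfmap = self._map(np.zeros((20, 2048)))
        with pytest.raises(ValueError, match="outside"):
            ft.window_mean(tfmap, {"bad": ((50.0, 90.0), (-0.4, -0.2))})


class TestPowerSpectrum:
    def test_sinusoid_power_and_quadratic_scaling(self):
        fs = 2048.0
        t = np.arange(int(fs)) / fs
        for amp in (1.0, 2.0):
            epochs = ft.EpochSet.from_array([amp * np.sin(2 * PI * 10 * t)] * 3, fs)
            spec = ft.power_spectrum(epochs)
            assert spec.at(10.0) == pytest.approx(amp**2 / 2, rel=1e-6)
            assert spec.at(10.0) > 1e4 * spec.at(20.0)

    def test_white_noise_flat(self, rng):
        fs = 2048.0
        epochs = ft.EpochSet.from_array(rng.standard_normal((1000, int(fs))), fs)
        spec = ft.power_spectrum(epochs)
        band = spec.power[(spec.freqs >= 5) & (spec.freqs <= 95)]
        assert 10 * np.log10(band.max() / band.min()) < 3.0


class TestModulationIndex:
    def test_uniform_amplitude_zero_mi(self, rng):
        phase = rng.uniform(-PI, PI, size=int(60 * 500))
        mi = ft.modulation_index(phase, np.ones_like(phase))
        assert mi < 0.01

    def test_single_bin_concentration_unit_mi(self):
        phase = np.full(1000, 0.1)
        amp = np.ones(1000)
        assert ft.modulation_index(phase, amp) == pytest.approx(1.0)

    def test_scaling_and_rotation_invariance(self, rng):
        phase = rng.uniform(-PI, PI, size=20000)
        amp = 1 + 0.8 * np.cos(phase - 1.0)
        base = ft.modulation_index(phase, amp)
        assert ft.modulation_index(phase, 7.3 * amp) == pytest.approx(base, abs=1e-12)
        rot = (phase + 2 * PI / 18) % (2 * PI)
        rot = np.angle(np.exp(1j * rot))  # back to [-pi, pi)
        assert ft.modulation_index(rot, amp) == pytest.approx(base, rel=1e-6)

    def test_agrees_with_bruteforce_binning(self, rng):
        phase = rng.uniform(-PI, PI, size=5000)
        amp = (1 + 0.5 * np.cos(phase - 2.0)) * rng.uniform(0.5, 1.5, size=5000)
        assert ft.modulation_index(phase, amp) == pytest.approx(
            mi_bruteforce(phase, amp), abs=1e-6
        )

    def test_mvl_positive_under_coupling(self, rng):
        phase = rng.uniform(-PI, PI, size=20000)
        amp = 1 + 0.8 * np.cos(phase)
        assert ft.mean_vector_length(phase, amp) > 10 * ft.mean_vector_length(
            phase, np.ones_like(phase)
        )


class TestComodulogram:
    def test_grid_shape_17x15(self, rng):
        fs = 512.0
        epochs = ft.EpochSet.from_array(rng.standard_normal((4, int(fs))), fs)
        com = ft.pac_comodulogram(epochs)
        assert com.values.shape == (17, 15)
        assert np.all((com.values >= 0) & (com.values <= 1))

    def test_window_subgrid_is_7x5(self):
        (plo, phi), (alo, ahi) = ft.PAC_WINDOW
        n_phase = np.sum((ft.PHASE_FREQS >= plo) & (ft.PHASE_FREQS <= phi))
        n_amp = np.sum((ft.AMP_FREQS >= alo) & (ft.AMP_FREQS <= ahi))
        assert (n_phase, n_amp) == (7, 5)

    def test_window_mean_constant_and_zero(self):
        com = ft.Comodulogram(values=np.full((17, 15), 0.2),
                              phase_freqs=ft.PHASE_FREQS.astype(float),
                              amp_freqs=ft.AMP_FREQS.astype(float),
                              n_phase_bins=18, method="tort")
        assert ft.pac_window_mean(com) == pytest.approx(0.2)
        com.values = np.zeros((17, 15))
        assert ft.pac_window_mean(com) == 0.0


class TestSaccadeDetector:
    fs = 2048.0

    def test_flat_trace(self):
        assert ft.detect_saccades(np.zeros(int(10 * self.fs)), self.fs) == []

    def test_step_recall(self):
        n = int(30 * self.fs)
        eog = np.zeros(n)
        truth = [2.0 + 2.5 * k for k in range(10)]
        for t0 in truth:
            eog[int(t0 * self.fs):] += 100.0
        detected = ft.detect_saccades(eog, self.fs)
        hits = sum(any(abs(t - d) < 0.05 for d in detected) for t in truth)
        assert hits >= 9

    def test_slow_drift_specificity(self):
        t = np.arange(int(30 * self.fs)) / self.fs
        drift = 200.0 * np.sin(2 * PI * 0.2 * t)
        assert ft.detect_saccades(drift, self.fs) == []
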