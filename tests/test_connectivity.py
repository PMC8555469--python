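"""Complex Morlet kernel, phase extraction, and phase-locking values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

import plvnet as pv

from conftest import make_epochs


def phase_tensor(phase, names=None, sfreq=250.0, labels=None):
    phase = np.asarray(phase)
    if names is None:
        names = pv.CHANNELS_16[:phase.shape[1]]
    return pv.PhaseTensor(phase=phase, band=pv.ALPHA,
                          valid_mask=np.ones(phase.shape[2], bool),
                          channel_names=tuple(names), sfreq=sfreq,
                          labels=labels)


def full_window(pt):
    return pv.WindowDef("full", 0.0, pt.phase.shape[2] / pt.sfreq)


class TestKernel:
    def test_peak_value_closed_form(self):
        # |psi(0)| = (pi * fb)^(-1/2): 1.0301 for the alpha band
        k = pv.cmw_kernel(pv.ALPHA, 250.0)
        assert k.size % 2 == 1
        assert abs(k[k.size // 2]) == pytest.approx((np.pi * 0.3) ** -0.5,
                                                    rel=1e-12)
        assert abs(k[k.size // 2]) == pytest.approx(1.030, abs=5e-4)

    def test_envelope_symmetric(self):
        for band in (pv.ALPHA, pv.BETA):
            k = pv.cmw_kernel(band, 250.0)
            assert np.allclose(np.abs(k), np.abs(k[::-1]))

    def test_fft_peaks_at_center_frequency(self):
        for band in (pv.ALPHA, pv.BETA):
            k = pv.cmw_kernel(band, 250.0)
            n = 1 << 14
            freqs = np.fft.fftfreq(n, 1 / 250.0)
            peak = freqs[np.abs(np.fft.fft(k, n)).argmax()]
            assert abs(peak - band.fc) <= 250.0 / k.size  # within one bin

    def test_tail_below_threshold(self):
        k = pv.cmw_kernel(pv.ALPHA, 250.0)
        assert abs(k[0]) < 1e-6 * abs(k[k.size // 2])

    def test_tiny_bandwidth_error(self):
        with pytest.raises(ValueError, match="3 samples"):
            pv.cmw_kernel(pv.BandSpec("x", 10.0, 1e-9), 100.0)

    def test_undersampled_error(self):
        with pytest.raises(ValueError, match="twice the center"):
            pv.cmw_kernel(pv.ALPHA, 20.0)


class TestExtractPhase:
    def test_tone_phase_slope(self):
        t = np.arange(2000) / 250.0
        data = np.cos(2 * np.pi * 10.5 * t)[None, None, :].repeat(2, 1)
        ep = make_epochs(data, channel_names=("C3", "C4"))
        ph = pv.extract_phase(ep, pv.ALPHA)
        valid = np.where(ph.valid_mask)[0]
        unwrapped = np.unwrap(ph.phase[0, 0, valid])
        slope = np.polyfit(valid / 250.0, unwrapped, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10.5, rel=0.01)

    def test_constant_offset_preserved(self):
        t = np.arange(2000) / 250.0
        a = np.cos(2 * np.pi * 10.5 * t + np.pi / 2)
        b = np.cos(2 * np.pi * 10.5 * t)
        ep = make_epochs(np.stack([a, b])[None], channel_names=("C3", "C4"))
        ph = pv.extract_phase(ep, pv.ALPHA)
        diff = np.angle(np.exp(1j * (ph.phase[0, 0] - ph.phase[0, 1])))
        assert np.allclose(diff[ph.valid_mask], np.pi / 2, atol=1e-3)

    def test_phase_bounded(self, random_epochs):
        ph = pv.extract_phase(random_epochs, pv.BETA)
        assert np.all(np.abs(ph.phase) <= np.pi)

    def test_trial_shorter_than_kernel_error(self):
        ep = make_epochs(np.zeros((2, 2, 100)), channel_names=("C3", "C4"))
        with pytest.raises(ValueError, match="shorter than"):
            pv.extract_phase(ep, pv.ALPHA)

    def test_valid_mask_margins(self, random_epochs):
        ph = pv.extract_phase(random_epochs, pv.ALPHA)
        half = pv.cmw_kernel(pv.ALPHA, 250.0).size // 2
        assert not ph.valid_mask[:half].any()
        assert not ph.valid_mask[-half:].any()
        assert ph.valid_mask[half:2000 - half].all()


class TestPlvPair:
    def test_identical_phases_give_one(self, rng):
        ph = rng.uniform(-np.pi, np.pi, (5, 1, 40))
        pt = phase_tensor(np.concatenate([ph, ph], axis=1),
                          names=("C3", "C4"), sfreq=40.0)
        assert pv.plv_pair(pt, "C3", "C4", full_window(pt)) == pytest.approx(1.0)

    def test_cancelling_phases_give_zero(self):
        # phase differences alternate exactly {0, pi} across trials
        ph = np.zeros((4, 2, 10))
        ph[::2, 0, :] = np.pi
        pt = phase_tensor(ph, names=("C3", "C4"), sfreq=10.0)
        assert pv.plv_pair(pt, "C3", "C4", full_window(pt)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_phases_near_rayleigh_mean(self, rng):
        # E[PLV] for i.i.d. uniform differences, N = 100: sqrt(pi/400)
        n_rep = 200
        ph = rng.uniform(-np.pi, np.pi, (100, 2, n_rep))
        pt = phase_tensor(ph, names=("C3", "C4"), sfreq=float(n_rep))
        est = pv.plv_pair(pt, "C3", "C4", full_window(pt))  # averages over samples
        # SE of the window-averaged estimate is ~0.0033 for 200 samples
        assert est == pytest.approx(np.sqrt(np.pi / 400), abs=0.013)

    def test_self_pair_error(self, rng):
        pt = phase_tensor(rng.uniform(size=(3, 2, 5)), names=("C3", "C4"),
                          sfreq=5.0)
        with pytest.raises(ValueError, match="self-pair"):
            pv.plv_pair(pt, "C3", "C3", full_window(pt))

    def test_needs_two_trials(self, rng):
        pt = phase_tensor(rng.uniform(size=(1, 2, 5)), names=("C3", "C4"),
                          sfreq=5.0)
        with pytest.raises(ValueError, match="2 trials"):
            pv.plv_pair(pt, "C3", "C4", full_window(pt))

    def test_amplitude_invariance(self, rng):
        t = np.arange(2000) / 250.0
        base = np.cos(2 * np.pi * 10.5 * t
                      + rng.uniform(-np.pi, np.pi, (6, 2, 1)))
        ep1 = make_epochs(base, channel_names=("C3", "C4"))
        scaled = base * np.array([1.0, 37.5])[None, :, None]
        ep2 = make_epochs(scaled, channel_names=("C3", "C4"))
        w = pv.WindowDef("mid", 3.0, 5.0)
        v1 = pv.plv_pair(pv.extract_phase(ep1, pv.ALPHA), "C3", "C4", w)
        v2 = pv.plv_pair(pv.extract_phase(ep2, pv.ALPHA), "C3", "C4", w)
        assert v1 == pytest.approx(v2, abs=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hst.integers(0, 2 ** 31 - 1))
    def test_matches_bruteforce_loop(self, seed):
        """Production PLV equals a naive per-sample loop over trials."""
        rng = np.random.default_rng(seed)
        ph = rng.uniform(-np.pi, np.pi, (5, 3, 50))
        pt = phase_tensor(ph, names=("F3", "C3", "C4"), sfreq=50.0)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            acc = 0.0
            for t in range(50):
                s = 0.0 + 0.0j
                for n in range(5):
                    s += np.exp(1j * (ph[n, i, t] - ph[n, j, t]))
                acc += abs(s / 5)
            expected = acc / 50
            got = pv.plv_pair(pt, i, j, full_window(pt))
            assert abs(got - expected) < 1e-10


class TestPlvMatrixAndDelta:
    def test_matrix_has_120_rows(self, rng):
        pt = phase_tensor(rng.uniform(-np.pi, np.pi, (4, 16, 30)), sfreq=30.0)
        df = pv.plv_matrix(pt, full_window(pt))
        assert len(df) == 120
        assert (df.groupby(["channel_i", "channel_j"]).size() == 1).all()

    def test_matrix_agrees_with_plv_pair(self, rng):
        pt = phase_tensor(rng.uniform(-np.pi, np.pi, (4, 16, 30)), sfreq=30.0)
        df = pv.plv_matrix(pt, full_window(pt)).set_index(["channel_i", "channel_j"])
        for i, j in [("F3", "Fz"), ("C3", "C4"), ("CP6", "T8")]:
            assert df.loc[(i, j), "plv"] == pytest.approx(
                pv.plv_pair(pt, i, j, full_window(pt)), abs=1e-12)

    def test_globally_locked_input_all_ones(self):
        common = np.random.default_rng(3).uniform(-np.pi, np.pi, (5, 1, 20))
        pt = phase_tensor(np.repeat(common, 16, axis=1), sfreq=20.0)
        df = pv.plv_matrix(pt, full_window(pt))
        assert np.allclose(df["plv"], 1.0)

    def test_label_subset(self, rng):
        labels = np.array(["left", "right"] * 3)
        pt = phase_tensor(rng.uniform(-np.pi, np.pi, (6, 16, 20)),
                          sfreq=20.0, labels=labels)
        df = pv.plv_matrix(pt, full_window(pt), "left")
        assert (df["condition"] == "left").all()
        with pytest.raises(ValueError, match="no trials"):
            pv.plv_matrix(pt, full_window(pt), "rest")

    def test_delta_is_mi_minus_rest(self, rng):
        pt = phase_tensor(rng.uniform(-np.pi, np.pi, (6, 16, 20)),
                          sfreq=20.0,
                          labels=np.array(["left"] * 6))
        mi = pv.plv_matrix(pt, full_window(pt), "left")
        rest = mi.copy()
        rest["window"] = "rest"
        rest["plv"] = rest["plv"] / 2
        delta = pv.delta_plv(mi, rest)
        assert np.allclose(delta["plv"], mi["plv"] / 2)
        assert (delta["window"] == "delta").all()

    def test_delta_zero_when_equal(self, rng):
        pt = phase_tensor(rng.uniform(-np.pi, np.pi, (6, 16, 20)),
                          sfreq=20.0, labels=np.array(["left"] * 6))
        mi = pv.plv_matrix(pt, full_window(pt), "left")
        delta = pv.delta_plv(mi, mi.assign(window="rest"))
        assert np.allclose(delta["plv"], 0.0)

    def test_delta_key_mismatch_error(self, rng):
        pt = phase_tensor(rng.uniform(-np.pi, np.pi, (6, 16, 20)),
                          sfreq=20.0, labels=np.array(["left"] * 6))
        mi = pv.plv_matrix(pt, full_window(pt), "left")
        rest = mi.assign(window="rest").iloc[:-3]
        with pytest.raises(ValueError, match="mismatch"):
            pv.delta_plv(mi, rest)
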