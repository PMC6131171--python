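"""Filtering, epoching, baselines, windowed amplitudes and paired tests."""

import dataclasses

import numpy as np
import pytest

from conftest import make_epochs
from psicat import erp
from psicat.filters import design_highpass, design_lowpass20, zero_phase_fir
from psicat.montage import ROI_CHANNELS


SF = 512.0


class TestHighpass:
    def test_dc_removed_and_passband_flat(self):
        taps = design_highpass(SF)
        n = 8 * int(SF)
        t = np.arange(n) / SF
        dc = zero_phase_fir(np.full(n, 5.0), taps)
        assert np.abs(dc[n // 4: -n // 4]).max() < 0.05  # |gain| < 1%
        sine = np.sin(2 * np.pi * 10.0 * t)
        out = zero_phase_fir(sine, taps)
        mid = slice(n // 4, -n // 4)
        gain = out[mid].std() / sine[mid].std()
        assert abs(gain - 1.0) < 0.01

    def test_design_is_linear_phase(self):
        taps = design_highpass(SF)
        assert np.allclose(taps, taps[::-1])  # symmetric impulse response

    def test_short_recording_rejected(self, practice_session):
        _, _, session = practice_session
        short = dataclasses.replace(session, data=session.data[:, :100])
        with pytest.raises(ValueError):
            erp.highpass(short)


class TestLowpass20:
    def test_band_gains(self):
        taps = design_lowpass20(SF)
        n = 4 * int(SF)
        t = np.arange(n) / SF
        mid = slice(n // 4, -n // 4)
        hi = zero_phase_fir(np.sin(2 * np.pi * 30.0 * t), taps)
        lo = zero_phase_fir(np.sin(2 * np.pi * 5.0 * t), taps)
        assert hi[mid].std() / np.sqrt(0.5) < 0.5  # >= 50% attenuation at 30 Hz
        assert abs(lo[mid].std() / np.sqrt(0.5) - 1.0) < 0.05
        dc = zero_phase_fir(np.ones(n), taps)
        assert np.allclose(dc[mid], 1.0, atol=1e-3)

    def test_approximately_idempotent_on_passband_content(self):
        t = np.arange(384) / SF
        sig = np.sin(2 * np.pi * 5.0 * t) + 0.5 * np.sin(2 * np.pi * 12.0 * t)
        ep = make_epochs(np.tile(sig, (3, 2, 1)))
        once = erp.lowpass20(ep)
        twice = erp.lowpass20(once)
        resid = np.abs(twice.data - once.data).max()
        assert resid < 0.02 * np.abs(once.data).max()


class TestEpoching:
    def test_epoch_geometry_and_hit_filter(self, practice_session):
        _, resp, session = practice_session
        ep = erp.epoch(session, hits_only=True)
        assert ep.data.shape[2] == 384  # 0.75 s x 512 Hz
        assert ep.times_ms[0] == pytest.approx(-250.0)
        n_hits = int(resp.correct.sum())
        assert ep.n_epochs == n_hits
        all_ep = erp.epoch(session, hits_only=False)
        assert all_ep.n_epochs == len(resp)
        # target onset lands at sample round(0.25 * SR)
        onset_idx = int(np.argmin(np.abs(ep.times_ms)))
        assert onset_idx == round(0.25 * SF)

    def test_edge_events_dropped(self, practice_session):
        _, _, session = practice_session
        clipped = dataclasses.replace(
            session, data=session.data[:, : int(session.sfreq * 2.0)])
        ep = erp.epoch(clipped, hits_only=False)
        assert ep.n_epochs < len(session.responses)


class TestBaseline:
    @pytest.mark.parametrize("mode", ["trial", "target"])
    def test_constant_epoch_zeroed(self, mode):
        ep = make_epochs(np.full((2, 3, 384), 5.0))
        out = erp.baseline_correct(ep, mode)
        assert np.allclose(out.data, 0.0, atol=1e-12)
        assert out.baseline_mode == mode

    def test_baseline_window_zero_mean_after_correction(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal((4, 3, 384)).cumsum(axis=2))
        for mode, (lo, hi) in erp.BASELINE_WINDOWS.items():
            out = erp.baseline_correct(ep, mode)
            mask = out.time_mask(lo, hi)
            assert np.abs(out.data[:, :, mask].mean(axis=2)).max() < 1e-9

    def test_modes_differ_by_per_epoch_constant(self):
        rng = np.random.default_rng(2)
        ep = make_epochs(rng.standard_normal((4, 3, 384)).cumsum(axis=2))
        a = erp.baseline_correct(ep, "trial").data
        b = erp.baseline_correct(ep, "target").data
        diff = a - b
        spread = diff.max(axis=2) - diff.min(axis=2)
        assert np.abs(spread).max() < 1e-9

    def test_unknown_mode_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 384)))
        with pytest.raises(ValueError):
            erp.baseline_correct(ep, "global")


class TestWindowedAmplitude:
    def test_constant_signal_recovered(self):
        ep = make_epochs(np.full((5, 20, 384), 2.0))
        w = erp.COMPONENT_WINDOWS["p3a"]
        vals = erp.roi_window_amplitude(ep, "vertex", w)
        assert vals["con.SCI"] == pytest.approx(2.0)

    def test_injected_component_recovered_noiselessly(self):
        from psicat.montage import load_montage

        mont = load_montage("reduced")
        times = (np.arange(384) - 128) / SF * 1000.0
        bump = 3.0 * np.exp(-0.5 * ((times - 280.0) / 50.0) ** 2)
        data = np.zeros((4, mont.n_channels, 384))
        data[:, mont.roi("vertex"), :] = bump
        ep = make_epochs(data, labels=mont.labels)
        w = erp.ComponentWindow("p3a_peak", 280.0, 5.0)
        val = erp.roi_window_amplitude(ep, "vertex", w)["con.SCI"]
        assert val == pytest.approx(3.0, rel=0.01)

    def test_linearity_in_additive_constant(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((3, 20, 384))
        ep1 = make_epochs(base)
        ep2 = make_epochs(base + 1.5)
        w = erp.COMPONENT_WINDOWS["target_n1"]
        v1 = erp.roi_window_amplitude(ep1, "occipital", w)
        v2 = erp.roi_window_amplitude(ep2, "occipital", w)
        assert v2["con.SCI"] - v1["con.SCI"] == pytest.approx(1.5)

    def test_empty_cell_is_missing(self):
        ep = make_epochs(np.zeros((2, 20, 384)), conditions=["con.SCI", "con.SCI"])
        vals = erp.roi_window_amplitude(ep, "vertex", erp.COMPONENT_WINDOWS["p3a"])
        assert np.isnan(vals["inc.noSCI"])


class TestPairedT:
    def test_equal_samples_give_half(self):
        a = np.arange(5.0)
        t, df, p = erp.paired_t_one_tailed(a, a, "greater")
        assert t == 0.0 and df == 4 and p == 0.5

    def test_constant_positive_difference_tiny_noise(self):
        rng = np.random.default_rng(0)
        b = rng.standard_normal(10)
        a = b + 2.0 + rng.normal(0, 1e-3, 10)
        t, df, p = erp.paired_t_one_tailed(a, b, "greater")
        assert p < 1e-10 and df == 9

    def test_wrong_direction_exceeds_half(self):
        rng = np.random.default_rng(1)
        b = rng.standard_normal(10)
        a = b - 1.0 + rng.normal(0, 0.1, 10)
        _, _, p = erp.paired_t_one_tailed(a, b, "greater")
        assert p > 0.5

    def test_null_type_i_error_rate(self):
        rng = np.random.default_rng(99)
        reps, hits = 10_000, 0
        for _ in range(reps):
            a, b = rng.standard_normal(17), rng.standard_normal(17)
            _, _, p = erp.paired_t_one_tailed(a, b, "greater")
            hits += p <= 0.05
        assert 0.04 <= hits / reps <= 0.06


class TestEsFromT:
    @pytest.mark.parametrize("t,n,expected", [
        (6.68, 17, 2.29), (-3.06, 17, -1.05), (0.0, 17, 0.0),
    ])
    def test_cohens_d_conversion(self, t, n, expected):
        assert round(erp.es_from_t(t, n), 2) == expected

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            erp.es_from_t(1.0, 0)


def test_roi_definitions_resolve_in_both_montages():
    from psicat.montage import load_montage

    for name in ("full", "reduced"):
        mont = load_montage(name)
        for roi, chans in ROI_CHANNELS.items():
            idx = mont.roi(roi)
            assert len(idx) == len(chans)
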