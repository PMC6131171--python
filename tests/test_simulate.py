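"""Synthetic-session generator: calibration, determinism, signal injection."""

import dataclasses

import numpy as np
import pytest

from psicat import erp, simulate
from psicat.scheduler import build_practice, build_schedule
from psicat.simulate import (
    ERP_DELTA_TARGETS,
    BehaviorModel,
    ExGaussian,
    ThetaDynamics,
    default_behavior_model,
    simulate_recording,
    simulate_responses,
)


class TestBehaviourCalibration:
    def test_exgaussian_median_and_sd_match_table(self):
        model = default_behavior_model()
        expected = {"con.SCI": (396, 65), "con.noSCI": (453, 101),
                    "inc.SCI": (468, 78), "inc.noSCI": (489, 85)}
        for cond, (med, sd) in expected.items():
            exg = model.rt[cond]
            assert exg.median == pytest.approx(med, abs=1e-6)
            assert exg.sd == pytest.approx(sd, abs=1e-9)

    def test_large_sample_median_within_5ms(self):
        # single-stream draws (no participant-level effects), 50k trials
        model = default_behavior_model()
        rng = np.random.default_rng(17)
        rts = model.rt["con.SCI"].sample(50_000, rng)
        assert abs(np.median(rts) - 396.0) <= 5.0

    def test_error_rate_matches_printed_value(self):
        # inc.SCI trials for non-interference-prone participants: 2.0 +/- 0.2%
        model = dataclasses.replace(default_behavior_model(),
                                    interference_prone_prob=0.0)
        rng = np.random.default_rng(3)
        n, errs = 0, 0
        while n < 50_000:
            sched = build_schedule(seed=int(rng.integers(2**31)),
                                   make_stimuli=False)
            resp = simulate_responses(sched, model, rng)
            sub = resp[resp.condition == "inc.SCI"]
            n += len(sub)
            errs += (~sub.correct).sum()
        assert 100.0 * errs / n == pytest.approx(2.0, abs=0.2)


class TestResponses:
    def test_zero_variance_model_degenerates_to_mu(self):
        exg = ExGaussian(mu=500.0, sigma=1e-9, tau=1e-9)
        model = BehaviorModel(
            rt={c: exg for c in ("con.SCI", "con.noSCI", "inc.SCI", "inc.noSCI")},
            error_prob={c: 0.0 for c in ("con.SCI", "con.noSCI", "inc.SCI", "inc.noSCI")},
            participant_rt_sd_ms=0.0, rtv_scale_sd=0.0, interference_prone_prob=0.0,
        )
        sched = build_practice(seed=1, make_stimuli=False)
        resp = simulate_responses(sched, model, np.random.default_rng(0))
        assert np.allclose(resp.rt_ms, 500.0, atol=1e-6)
        assert resp.correct.all()

    def test_seed_reproducibility(self):
        model = default_behavior_model()
        sched = build_practice(seed=2, make_stimuli=False)
        r1 = simulate_responses(sched, model, np.random.default_rng(9))
        r2 = simulate_responses(sched, model, np.random.default_rng(9))
        assert r1.equals(r2)

    def test_buttons_follow_hand_map(self):
        model = default_behavior_model()
        sched = build_practice(seed=2, make_stimuli=False)
        resp = simulate_responses(sched, model, np.random.default_rng(4))
        hits = resp[resp.correct]
        for cls, hand in sched.response_hand_map.items():
            sub = hits[hits.target_class == cls]
            assert (sub.button == hand).all()


class TestCalibratedDeltas:
    def test_pipeline_measured_deltas_equal_targets(self, models):
        # the generator's definition: noiseless pipeline measurement of each
        # published contrast reproduces the published value
        _, neural = models
        from psicat.montage import load_montage
        from psicat.simulate import _noiseless_measure

        mont = load_montage("reduced")
        for key, spec in ERP_DELTA_TARGETS.items():
            measured = _noiseless_measure(list(neural.components), mont,
                                          neural, key)
            assert measured == pytest.approx(spec[-1], abs=1e-6), key

    def test_p3a_congruency_delta_parameter_sign_and_scale(self, models):
        _, neural = models
        p3a = {c.name: c for c in neural.components}["p3a"]
        con = (p3a.amplitudes["con.SCI"] + p3a.amplitudes["con.noSCI"]) / 2
        inc = (p3a.amplitudes["inc.SCI"] + p3a.amplitudes["inc.noSCI"]) / 2
        assert con - inc == pytest.approx(3.23, abs=0.15)


class TestRecording:
    def test_noiseless_component_recovery_at_roi(self, models):
        from psicat.scheduler import TimingConfig

        _, neural = models
        quiet = dataclasses.replace(
            neural, noise_rms=0.0, amplitude_subject_sd=0.0,
            theta=ThetaDynamics(evoked_amp_early=0.0, evoked_amp_late=0.0,
                                induced_rms_early=0.0, induced_rms_late=0.0))
        behav = dataclasses.replace(
            default_behavior_model(),
            error_prob={c: 0.0 for c in
                        ("con.SCI", "con.noSCI", "inc.SCI", "inc.noSCI")})
        # long ITIs isolate each trial from the high-pass kernel's ~1.5 s
        # ringing of its neighbours, exposing the pure injected waveform
        timing = TimingConfig(iti_base_ms=4000.0, iti_jitter_ms=100.0)
        sched = build_practice(timing=timing, seed=6, make_stimuli=False)
        rng = np.random.default_rng(6)
        resp = simulate_responses(sched, behav, rng)
        session = simulate_recording(sched, resp, quiet, rng)
        session = erp.highpass(session)
        amp = erp.participant_amplitudes(erp.epoch(session, hits_only=True))
        for row in amp.itertuples():
            target = ERP_DELTA_TARGETS[row.hypothesis][-1]
            assert row.mean1 - row.mean2 == pytest.approx(target, abs=0.02)

    def test_zero_theta_slopes_leave_early_late_balanced(self, models):
        _, neural = models
        flat = dataclasses.replace(
            neural, noise_rms=2.0,
            theta=ThetaDynamics(evoked_amp_early=1.0, evoked_amp_late=1.0,
                                induced_rms_early=2.0, induced_rms_late=2.0))
        behav = default_behavior_model()
        sched = build_schedule(seed=8, make_stimuli=False)
        rng = np.random.default_rng(8)
        resp = simulate_responses(sched, behav, rng)
        session = simulate_recording(sched, resp, flat, rng)
        from psicat import spectral

        ep = erp.epoch(session, hits_only=False)
        pair = spectral.subset_epochs(ep)
        res = spectral.psd(ep, pair, seed=5, n_perm=300, alpha=0.01)
        th = (res.freqs_hz >= 4) & (res.freqs_hz <= 8)
        # no systematic drift: few theta bins flagged in either direction
        assert res.significant[th].mean() <= 0.35
        ratio = res.late[th].mean() / res.early[th].mean()
        assert 0.8 < ratio < 1.25

    def test_marker_and_response_consistency(self, practice_session):
        sched, resp, session = practice_session
        tgt = session.target_samples()
        assert len(tgt) == sched.n_trials
        assert (np.diff(tgt["sample"]) > 0).all()
        assert set(session.responses.trial_index) == {
            t.trial_index for t in sched.trials}

    def test_mismatched_responses_rejected(self, models, practice_session):
        behav, neural = models
        sched, resp, _ = practice_session
        with pytest.raises(ValueError):
            simulate_recording(sched, resp.iloc[:-1], neural,
                               np.random.default_rng(0))

    def test_recording_seed_deterministic(self, models):
        behav, neural = models
        sched = build_practice(seed=3, make_stimuli=False)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(12)
            resp = simulate_responses(sched, behav, rng)
            out.append(simulate_recording(sched, resp, neural, rng))
        assert np.array_equal(out[0].data, out[1].data)
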