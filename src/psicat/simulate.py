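"""Synthetic behavioural responses and multichannel EEG for a scheduled session.

The generator's defaults emulate the published study conditions:

* response times are ex-Gaussian per primary condition, calibrated so the
  distribution median and SD equal the printed per-condition median RT and
  RTV (396/65, 453/101, 468/78, 489/85 ms), with error probabilities 0.7,
  0.7, 2.0 and 0.8 %;
* the EEG is a spatially weighted sum of Gaussian-windowed ERP component
  bumps (primer N1, target N1, P3a, P3b at their ROIs and latencies) whose
  per-condition amplitudes are solved so that the analysis pipeline's
  baseline-corrected windowed amplitudes recover the published
  condition-wise deltas; plus 1/f background noise; plus fronto-medial
  theta whose induced amplitude rises linearly over the session while the
  target-locked, phase-locked portion falls — yielding higher late-trial
  theta power with lower late-trial inter-trial coherence.

Everything is a pure function of (schedule, model, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .montage import ROI_CHANNELS, Montage, load_montage
from .scheduler import PRIMARY_CONDITIONS, Schedule, export_events

__all__ = [
    "ExGaussian",
    "BehaviorModel",
    "Component",
    "ThetaDynamics",
    "NeuralModel",
    "SessionData",
    "default_models",
    "default_behavior_model",
    "default_neural_model",
    "simulate_responses",
    "simulate_recording",
]

# printed per-condition behavioural triples: median RT ms, RTV ms, error %
_BEHAVIOUR_TABLE = {
    "con.SCI": (396.0, 65.0, 0.007),
    "con.noSCI": (453.0, 101.0, 0.007),
    "inc.SCI": (468.0, 78.0, 0.020),
    "inc.noSCI": (489.0, 85.0, 0.008),
}

# published condition-wise windowed-amplitude deltas (µV) the simulator is
# calibrated to: (component, measurement roi, window centre/half-width ms,
# baseline mode, contrast) -> delta
ERP_DELTA_TARGETS = {
    "H3P3a": ("p3a", "vertex", 280.0, 20.0, "trial", ("congruency", None), 3.23),
    "H3P3b": ("p3b", "parietal", 480.0, 20.0, "trial", ("congruency", None), -3.09),
    "H4pN1": ("primer_n1", "occipital", 0.0, 10.0, "trial", ("class", None), -1.30),
    "H4tN1.con": ("target_n1", "occipital", 165.0, 10.0, "target", ("class", "con"), 1.67),
    "H4tN1.inc": ("target_n1", "occipital", 165.0, 10.0, "target", ("class", "inc"), -1.59),
    "H4tP3a.con": ("p3a", "vertex", 280.0, 20.0, "target", ("class", "con"), 1.63),
    "H4tP3a.inc": ("p3a", "vertex", 280.0, 20.0, "target", ("class", "inc"), 1.00),
}

_BASELINE_WINDOWS = {"trial": (-250.0, -150.0), "target": (-100.0, 0.0)}


# ---------------------------------------------------------------------------
# behaviour

@dataclass(frozen=True)
class ExGaussian:
    """Ex-Gaussian RT law: Normal(mu, sigma) + Exponential(tau), in ms."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self):
        if min(self.mu, self.sigma, self.tau) <= 0:
            raise ValueError("ex-Gaussian parameters must be positive")

    @property
    def median(self) -> float:
        return float(stats.exponnorm.median(self.tau / self.sigma,
                                            loc=self.mu, scale=self.sigma))

    @property
    def sd(self) -> float:
        return float(np.hypot(self.sigma, self.tau))

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mu, self.sigma, size) + rng.exponential(self.tau, size)


def exgaussian_from_median_sd(median: float, sd: float) -> ExGaussian:
    """Calibrate (mu, sigma, tau) to a target median and SD.

    The SD is split sigma = 0.8 SD, tau = 0.6 SD (so sigma^2 + tau^2 = SD^2)
    and mu is solved from the exact exponnorm median.
    """
    sigma, tau = 0.8 * sd, 0.6 * sd
    m0 = float(stats.exponnorm.median(tau / sigma, loc=0.0, scale=sigma))
    return ExGaussian(mu=median - m0, sigma=sigma, tau=tau)


@dataclass(frozen=True)
class BehaviorModel:
    """Per-primary-condition RT laws and error probabilities."""

    rt: dict  # primary condition -> ExGaussian
    error_prob: dict  # primary condition -> probability
    lapse_prob: float = 0.0  # probability of an attentional lapse trial
    lapse_rt_ms: tuple = (1000.0, 2500.0)  # uniform RT range on lapses
    participant_rt_sd_ms: float = 5.0  # between-participant median-RT spread
    rtv_scale_sd: float = 0.22  # log-normal between-participant dispersion
    # scale: multiplies sigma and tau while mu is re-solved to keep the
    # condition median fixed, so participants differ in RT variability
    # without shifting the median-RT structure
    interference_prone_prob: float = 0.35  # fraction of participants markedly
    # susceptible to primer interference: their incongruent error probability
    # is multiplied by 2.5-4.5x (several participants reach ~5% errors on
    # incongruent-SCI trials while everyone else stays uniformly low)
    interference_factor_range: tuple = (2.5, 4.5)
    min_rt_ms: float = 120.0  # physiological floor

    def __post_init__(self):
        for p in self.error_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("error probabilities must lie in [0, 1]")
        if not 0.0 <= self.lapse_prob <= 1.0:
            raise ValueError("lapse probability must lie in [0, 1]")


def default_behavior_model() -> BehaviorModel:
    return BehaviorModel(
        rt={c: exgaussian_from_median_sd(m, s) for c, (m, s, _) in _BEHAVIOUR_TABLE.items()},
        error_prob={c: e for c, (_, _, e) in _BEHAVIOUR_TABLE.items()},
    )


def simulate_responses(schedule: Schedule, model: BehaviorModel,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Draw one response per scheduled trial.

    RT is an ex-Gaussian draw for the trial's primary condition plus a
    participant-level offset (drawn once per call); correctness is a
    Bernoulli draw; rare lapses replace the RT with a slow uniform draw.
    """
    offset = rng.normal(0.0, model.participant_rt_sd_ms) if model.participant_rt_sd_ms > 0 else 0.0
    scale = float(np.exp(rng.normal(0.0, model.rtv_scale_sd))) if model.rtv_scale_sd > 0 else 1.0
    if rng.random() < model.interference_prone_prob:
        err_factor = float(rng.uniform(*model.interference_factor_range))
    else:
        err_factor = 1.0
    laws = {}
    for cond, exg in model.rt.items():
        med = exg.median
        laws[cond] = ExGaussian(mu=med - (med - exg.mu) * scale,
                                sigma=exg.sigma * scale, tau=exg.tau * scale)
    hand = schedule.response_hand_map
    rows = []
    for tr in schedule.trials:
        cond = tr.condition.primary
        rt = float(laws[cond].sample((), rng)) + offset
        if model.lapse_prob > 0 and rng.random() < model.lapse_prob:
            rt = float(rng.uniform(*model.lapse_rt_ms))
        rt = max(rt, model.min_rt_ms)
        rt = min(rt, schedule.timing.target_timeout_ms)
        p_err = model.error_prob[cond]
        if cond.startswith("inc."):
            p_err = min(p_err * err_factor, 0.5)
        correct = bool(rng.random() >= p_err)
        perceived = tr.condition.target_class if correct else (
            "noSCI" if tr.condition.target_class == "SCI" else "SCI")
        rows.append(dict(trial_index=tr.trial_index, condition=cond,
                         congruency=tr.condition.congruency,
                         target_class=tr.condition.target_class,
                         n_vertices=tr.condition.n_vertices,
                         button=hand[perceived], rt_ms=rt, correct=correct))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# neural model

@dataclass(frozen=True)
class Component:
    """One ERP component template.

    ``amplitudes`` maps each primary condition to the signed peak-equivalent
    amplitude in µV; the Gaussian envelope has FWHM ``width_ms`` and is
    rescaled so its mean over the component's own test window is one, making
    the windowed-amplitude readout equal the tabulated amplitude.
    """

    name: str
    roi: str
    latency_ms: float
    width_ms: float  # FWHM of the Gaussian envelope
    amplitudes: dict  # primary condition -> µV
    window_halfwidth_ms: float

    @property
    def sigma_ms(self) -> float:
        return self.width_ms / 2.3548200450309493  # FWHM -> sd

    def kernel(self, t_ms: np.ndarray) -> np.ndarray:
        """Unit-calibrated envelope: mean over its test window equals 1."""
        g = np.exp(-0.5 * ((t_ms - self.latency_ms) / self.sigma_ms) ** 2)
        lo = self.latency_ms - self.window_halfwidth_ms
        hi = self.latency_ms + self.window_halfwidth_ms
        tw = np.linspace(lo, hi, 201)
        norm = np.mean(np.exp(-0.5 * ((tw - self.latency_ms) / self.sigma_ms) ** 2))
        return g / norm


@dataclass(frozen=True)
class ThetaDynamics:
    """Session-long fronto-medial theta trends.

    Induced (random-phase, band-limited) amplitude rises linearly from
    ``induced_rms_early`` to ``induced_rms_late`` across the session, while
    the target-locked fixed-phase burst falls from ``evoked_amp_early`` to
    ``evoked_amp_late`` — so late trials show more theta power but less
    stimulus phase-locking.
    """

    band_hz: tuple = (4.0, 8.0)
    evoked_freq_hz: float = 6.0
    evoked_amp_early: float = 2.5  # µV
    evoked_amp_late: float = 0.4
    evoked_duration_ms: float = 300.0
    induced_rms_early: float = 1.5  # µV
    induced_rms_late: float = 4.0
    roi: str = "fronto_medial"


@dataclass(frozen=True)
class NeuralModel:
    sampling_rate: float = 512.0
    montage: str = "reduced"
    components: tuple = ()
    noise_exponent: float = 1.0  # 1/f^a power exponent
    noise_rms: float = 4.0  # µV per channel (cleaned-data residual level)
    noise_common_frac: float = 0.3  # shared across channels
    amplitude_subject_sd: float = 0.3  # µV, between-participant component spread
    topo_lambda: float = 0.35  # spatial falloff scale, projected radians
    theta: ThetaDynamics = field(default_factory=ThetaDynamics)

    def validate(self) -> "NeuralModel":
        hi = max(self.theta.band_hz[1], self.theta.evoked_freq_hz)
        if self.sampling_rate <= 2 * hi:
            raise ValueError("sampling rate must exceed twice the highest "
                             "synthesized frequency")
        return self

    def topography(self, roi: str, montage: Montage) -> np.ndarray:
        """Unit weight on ROI channels, Gaussian falloff with 2-D distance."""
        roi_pos = montage.pos2d[montage.roi(roi)]
        d = np.min(
            np.linalg.norm(montage.pos2d[:, None, :] - roi_pos[None, :, :], axis=2),
            axis=1,
        )
        w = np.exp(-((d / self.topo_lambda) ** 2))
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite topography weights")
        return w


def _nominal_components() -> list:
    """Starting amplitude tables before pipeline calibration."""
    def by_class(base, delta):
        return {"con.SCI": base + delta / 2, "con.noSCI": base - delta / 2,
                "inc.SCI": base + delta / 2, "inc.noSCI": base - delta / 2}

    p3a_pool, p3a_con, p3a_inc = 3.23, 1.63, 1.00
    p3a = {
        "con.SCI": 6.0 + p3a_pool / 2 + p3a_con / 2,
        "con.noSCI": 6.0 + p3a_pool / 2 - p3a_con / 2,
        "inc.SCI": 6.0 - p3a_pool / 2 + p3a_inc / 2,
        "inc.noSCI": 6.0 - p3a_pool / 2 - p3a_inc / 2,
    }
    tn1 = {"con.SCI": -5.0 + 1.67 / 2, "con.noSCI": -5.0 - 1.67 / 2,
           "inc.SCI": -5.0 - 1.59 / 2, "inc.noSCI": -5.0 + 1.59 / 2}
    p3b = {"con.SCI": 5.0 - 3.09 / 2, "con.noSCI": 5.0 - 3.09 / 2,
           "inc.SCI": 5.0 + 3.09 / 2, "inc.noSCI": 5.0 + 3.09 / 2}
    return [
        Component("primer_n1", "occipital", 0.0, 40.0, by_class(-4.0, -1.30), 10.0),
        Component("target_n1", "occipital", 165.0, 40.0, tn1, 10.0),
        Component("p3a", "vertex", 280.0, 120.0, p3a, 20.0),
        Component("p3b", "parietal", 480.0, 120.0, p3b, 20.0),
    ]


def _noiseless_measure(components, montage, model, key):
    """Pipeline-equivalent windowed contrast on the noiseless templates.

    The condition templates pass through the same zero-phase high- and
    low-pass kernels the analysis applies, so the calibrated amplitudes
    absorb filter ringing as well as cross-component baseline leakage.
    """
    from .filters import design_highpass, design_lowpass20, zero_phase_fir

    comp_name, roi, centre, half, bmode, (axis, stratum), _ = ERP_DELTA_TARGETS[key]
    fs = model.sampling_rate
    # long template for the continuous high-pass, then the same 384-sample
    # epoch cut / baseline / 20 Hz low-pass sequence the pipeline applies
    n_pre = int(round(0.25 * fs))
    n_epoch = int(round(0.75 * fs))
    s0 = int(1.0 * fs)
    t_long = (np.arange(int(2.25 * fs)) - s0) / fs * 1000.0
    t_ep = (np.arange(n_epoch) - n_pre) / fs * 1000.0
    roi_idx = montage.roi(roi)
    topo_w = {
        c.name: float(np.mean(model.topography(c.roi, montage)[roi_idx]))
        for c in components
    }
    hp = design_highpass(fs)
    lp = design_lowpass20(fs)
    blo, bhi = _BASELINE_WINDOWS[bmode]
    bmask = (t_ep >= blo) & (t_ep <= bhi)
    wmask = (t_ep >= centre - half) & (t_ep <= centre + half)

    def cond_value(cond):
        wave = np.zeros_like(t_long)
        for c in components:
            wave += c.amplitudes[cond] * topo_w[c.name] * c.kernel(t_long)
        wave = zero_phase_fir(wave, hp)
        ep = wave[s0 - n_pre: s0 - n_pre + n_epoch]
        ep = ep - ep[bmask].mean()
        ep = zero_phase_fir(ep, lp)
        return ep[wmask].mean()

    if axis == "congruency":
        return (cond_value("con.SCI") + cond_value("con.noSCI")) / 2 - (
            cond_value("inc.SCI") + cond_value("inc.noSCI")) / 2
    if stratum is None:  # class contrast pooled over congruency
        return (cond_value("con.SCI") + cond_value("inc.SCI")) / 2 - (
            cond_value("con.noSCI") + cond_value("inc.noSCI")) / 2
    return cond_value(f"{stratum}.SCI") - cond_value(f"{stratum}.noSCI")


def _calibrate_components(components, montage, model, n_iter=6):
    """Adjust amplitude tables so pipeline-measured deltas hit the targets.

    The measurement is linear in the amplitudes, but cross-component leakage
    (notably the primer-N1 bump inside the −100…0 ms target-level baseline)
    biases a naive injection; a short fixed-point iteration on the seven
    contrast parameters removes it.
    """
    comps = {c.name: c for c in components}

    def adjust(name, updates):
        c = comps[name]
        amps = dict(c.amplitudes)
        for cond, delta in updates.items():
            amps[cond] += delta
        comps[name] = replace(c, amplitudes=amps)

    for _ in range(n_iter):
        cur = list(comps.values())
        resid = {k: spec[-1] - _noiseless_measure(cur, montage, model, k)
                 for k, spec in ERP_DELTA_TARGETS.items()}
        r = resid["H4pN1"]
        adjust("primer_n1", {"con.SCI": r / 2, "inc.SCI": r / 2,
                             "con.noSCI": -r / 2, "inc.noSCI": -r / 2})
        adjust("target_n1", {"con.SCI": resid["H4tN1.con"] / 2,
                             "con.noSCI": -resid["H4tN1.con"] / 2,
                             "inc.SCI": resid["H4tN1.inc"] / 2,
                             "inc.noSCI": -resid["H4tN1.inc"] / 2})
        rp = resid["H3P3a"]
        adjust("p3a", {"con.SCI": rp / 2 + resid["H4tP3a.con"] / 2,
                       "con.noSCI": rp / 2 - resid["H4tP3a.con"] / 2,
                       "inc.SCI": -rp / 2 + resid["H4tP3a.inc"] / 2,
                       "inc.noSCI": -rp / 2 - resid["H4tP3a.inc"] / 2})
        rb = resid["H3P3b"]
        adjust("p3b", {"con.SCI": rb / 2, "con.noSCI": rb / 2,
                       "inc.SCI": -rb / 2, "inc.noSCI": -rb / 2})
    final = list(comps.values())
    resid = {k: spec[-1] - _noiseless_measure(final, montage, model, k)
             for k, spec in ERP_DELTA_TARGETS.items()}
    worst = max(abs(v) for v in resid.values())
    if worst > 1e-6:
        raise RuntimeError(f"component calibration did not converge ({worst:.2e} µV)")
    return tuple(final)


def default_neural_model(montage: str = "reduced") -> NeuralModel:
    model = NeuralModel(montage=montage).validate()
    mont = load_montage(montage)
    comps = _calibrate_components(_nominal_components(), mont, model)
    return replace(model, components=comps)


def default_models(montage: str = "reduced"):
    """Default (behaviour, neural) generator pair, calibrated to the published study conditions."""
    return default_behavior_model(), default_neural_model(montage)


# ---------------------------------------------------------------------------
# recording synthesis

@dataclass
class SessionData:
    """One participant's continuous EEG plus markers and behaviour."""

    data: np.ndarray  # (n_channels, n_samples), µV
    sfreq: float
    labels: tuple
    events: pd.DataFrame  # scheduler events dialect with responses merged
    responses: pd.DataFrame
    participant_id: str
    montage_name: str
    seed: int = -1

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def target_samples(self, hits_only: bool = False) -> pd.DataFrame:
        """Target-onset markers as sample indices, with condition labels."""
        tgt = self.events[self.events.event_type == "target"].copy()
        tgt["sample"] = np.round(tgt["onset"].to_numpy() * self.sfreq).astype(int)
        if hits_only:
            rsp = self.events[self.events.event_type == "response"]
            ok = set(rsp.loc[rsp.correct.astype(bool), "trial_index"])
            tgt = tgt[tgt.trial_index.isin(ok)]
        return tgt.reset_index(drop=True)


def _powerlaw_noise(shape, exponent, rng, sfreq):
    """Gaussian noise with power spectral density ∝ 1/f^exponent, unit RMS."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),)))
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    return x / np.where(rms == 0, 1.0, rms)


def _bandlimited_noise(n, band, rng, sfreq):
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    spec = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def simulate_recording(schedule: Schedule, responses: pd.DataFrame,
                       model: NeuralModel, rng: np.random.Generator) -> SessionData:
    """Synthesize the continuous multichannel EEG for one session."""
    model.validate()
    n_trials = schedule.n_trials
    if responses is None or len(responses) != n_trials or (
            set(responses.trial_index) != {t.trial_index for t in schedule.trials}):
        raise ValueError("responses must cover every scheduled trial exactly once")

    events = export_events(schedule, responses)
    mont = load_montage(model.montage)
    sfreq = model.sampling_rate
    duration_s = float(events.onset.max()) + 2.0
    n_samp = int(np.ceil(duration_s * sfreq))
    n_ch = mont.n_channels
    data = np.zeros((n_ch, n_samp))

    tgt = events[events.event_type == "target"]
    tgt_samples = np.round(tgt.onset.to_numpy() * sfreq).astype(int)
    conds = (tgt.congruency + "." + tgt.target_class).to_numpy()
    frac = (np.arange(n_trials) / max(n_trials - 1, 1))

    # ERP component bumps, condition-amplitude-coded, spatially weighted;
    # a zero-mean per-participant offset per component x condition models
    # between-participant amplitude spread
    pad = int(0.6 * sfreq)
    t_rel = (np.arange(-pad, pad + 1)) / sfreq * 1000.0
    for comp in model.components:
        kern = comp.kernel(t_rel)
        offsets = {cond: rng.normal(0.0, model.amplitude_subject_sd)
                   for cond in sorted(comp.amplitudes)}
        track = np.zeros(n_samp)
        for s, cond in zip(tgt_samples, conds):
            lo, hi = s - pad, s + pad + 1
            if lo < 0 or hi > n_samp:
                continue
            track[lo:hi] += (comp.amplitudes[cond] + offsets[cond]) * kern
        data += model.topography(comp.roi, mont)[:, None] * track[None, :]

    # target-locked phase-locked theta burst, amplitude falling over trials
    th = model.theta
    fm_topo = model.topography(th.roi, mont)
    burst_n = int(round(th.evoked_duration_ms / 1000.0 * sfreq))
    tb = np.arange(burst_n) / sfreq
    envelope = np.hanning(burst_n)
    burst = np.cos(2 * np.pi * th.evoked_freq_hz * tb) * envelope
    track = np.zeros(n_samp)
    amps = th.evoked_amp_early + (th.evoked_amp_late - th.evoked_amp_early) * frac
    for s, a in zip(tgt_samples, amps):
        if s + burst_n <= n_samp:
            track[s:s + burst_n] += a * burst
    data += fm_topo[:, None] * track[None, :]

    # induced (random-phase) theta, amplitude rising across the session
    induced = _bandlimited_noise(n_samp, th.band_hz, rng, sfreq)
    ramp = np.linspace(th.induced_rms_early, th.induced_rms_late, n_samp)
    data += fm_topo[:, None] * (induced * ramp)[None, :]

    # 1/f background: a common field plus independent per-channel noise
    if model.noise_rms > 0:
        common = _powerlaw_noise((n_samp,), model.noise_exponent, rng, sfreq)
        indep = _powerlaw_noise((n_ch, n_samp), model.noise_exponent, rng, sfreq)
        c = model.noise_common_frac
        data += model.noise_rms * (np.sqrt(c) * common[None, :] + np.sqrt(1 - c) * indep)

    return SessionData(
        data=data, sfreq=sfreq, labels=mont.labels, events=events,
        responses=responses, participant_id=schedule.participant_id,
        montage_name=model.montage,
    )
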