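"""ERP pipeline: filtering, epoching, dual baselines, ROI window statistics.

Continuous EEG is high-passed at 0.5 Hz with a least-squares linear-phase
FIR (order 1.5 x sampling rate, applied forward-backward so the net filter
is zero-phase), cut into 750 ms target-locked epochs (-250...+500 ms, hit
trials only), baseline-corrected with one of two 100 ms windows — the
pre-trial segment (-250...-150 ms, for whole-trial congruency questions and
the primer N1) or the pre-target segment (-100...0 ms, for target-locked
gestalt questions) — low-passed at 20 Hz, and summarized as mean amplitude
over ROI channels within fixed component windows.  Condition contrasts use
one-tailed paired t tests with Cohen's d = t * sqrt(2/n).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from .filters import design_highpass, design_lowpass20, zero_phase_fir
from .montage import ROI_CHANNELS, Montage, load_montage
from .simulate import SessionData

__all__ = [
    "EpochSet",
    "ComponentWindow",
    "COMPONENT_WINDOWS",
    "BASELINE_WINDOWS",
    "highpass",
    "lowpass20",
    "epoch",
    "baseline_correct",
    "reject_epochs",
    "roi_window_amplitude",
    "paired_t_one_tailed",
    "es_from_t",
    "erp_battery",
    "ERP_HYPOTHESES",
]

EPOCH_TMIN_S = -0.25
EPOCH_TMAX_S = 0.50

#: baseline mode -> (start_ms, end_ms); 'trial' precedes the whole trial,
#: 'target' is the latter 100 ms of the primer, just before target onset
BASELINE_WINDOWS = {"trial": (-250.0, -150.0), "target": (-100.0, 0.0)}


@dataclass(frozen=True)
class ComponentWindow:
    name: str
    center_ms: float
    halfwidth_ms: float

    @property
    def bounds(self):
        return (self.center_ms - self.halfwidth_ms, self.center_ms + self.halfwidth_ms)


COMPONENT_WINDOWS = {
    "primer_n1": ComponentWindow("primer_n1", 0.0, 10.0),
    "target_n1": ComponentWindow("target_n1", 165.0, 10.0),
    "p3a": ComponentWindow("p3a", 280.0, 20.0),
    "p3b": ComponentWindow("p3b", 480.0, 20.0),
}


@dataclass
class EpochSet:
    """Target-locked epochs with labels, hit flags and a baseline mode."""

    data: np.ndarray  # (n_epochs, n_channels, n_samples), µV
    sfreq: float
    labels: tuple  # channel labels
    times_ms: np.ndarray  # (n_samples,)
    conditions: np.ndarray  # primary condition per epoch, e.g. 'con.SCI'
    hit: np.ndarray  # bool per epoch
    trial_index: np.ndarray
    baseline_mode: str = "none"
    participant_id: str = ""

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def pick_channels(self, labels) -> np.ndarray:
        idx = {l: i for i, l in enumerate(self.labels)}
        try:
            return np.array([idx[l] for l in labels], int)
        except KeyError as err:
            raise KeyError(f"channel {err.args[0]!r} not present in epochs")

    def time_mask(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        return (self.times_ms >= lo_ms) & (self.times_ms <= hi_ms)

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy())


# ---------------------------------------------------------------------------
# filters

def highpass(session: SessionData, cutoff_hz: float = 0.5) -> SessionData:
    """Zero-phase 0.5 Hz FIR high-pass of the continuous recording."""
    if cutoff_hz != 0.5:
        raise ValueError("the pipeline's high-pass is fixed at 0.5 Hz")
    taps = design_highpass(session.sfreq)
    if session.n_samples < 3 * len(taps):
        raise ValueError("recording too short for the 1.5 x SR filter order")
    out = zero_phase_fir(session.data, taps)
    return replace(session, data=out)


def lowpass20(epochs: EpochSet) -> EpochSet:
    """Zero-phase 20 Hz FIR low-pass for visualisation and testing."""
    taps = design_lowpass20(epochs.sfreq)
    shape = epochs.data.shape
    flat = epochs.data.reshape(-1, shape[-1])
    out = zero_phase_fir(flat, taps).reshape(shape)
    return replace(epochs, data=out)


# ---------------------------------------------------------------------------
# epoching and baselines

def epoch(session: SessionData, hits_only: bool = True) -> EpochSet:
    """Cut 750 ms target-locked epochs (-250...+500 ms).

    Error trials are excluded when ``hits_only``; events too close to the
    recording edge are dropped.  At 512 Hz each epoch spans 384 samples with
    target onset at sample round(0.25 x SR).
    """
    sf = session.sfreq
    n_pre = int(round(-EPOCH_TMIN_S * sf))
    n_tot = int(round((EPOCH_TMAX_S - EPOCH_TMIN_S) * sf))
    tgt = session.target_samples(hits_only=hits_only)
    resp = session.events[session.events.event_type == "response"]
    hit_by_trial = dict(zip(resp.trial_index, resp.correct.astype(bool)))
    rows, labels_cond, hits, trials = [], [], [], []
    n_dropped = 0
    for r in tgt.itertuples():
        s0 = r.sample - n_pre
        if s0 < 0 or s0 + n_tot > session.n_samples:
            n_dropped += 1
            continue
        rows.append(session.data[:, s0:s0 + n_tot])
        labels_cond.append(f"{r.congruency}.{r.target_class}")
        hits.append(hit_by_trial.get(r.trial_index, True))
        trials.append(r.trial_index)
    data = np.stack(rows) if rows else np.empty((0, session.data.shape[0], n_tot))
    times = (np.arange(n_tot) - n_pre) / sf * 1000.0
    return EpochSet(
        data=data, sfreq=sf, labels=session.labels, times_ms=times,
        conditions=np.asarray(labels_cond), hit=np.asarray(hits, bool),
        trial_index=np.asarray(trials, int), baseline_mode="none",
        participant_id=session.participant_id,
    )


def baseline_correct(epochs: EpochSet, mode: str) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the mode's window."""
    if mode not in BASELINE_WINDOWS:
        raise ValueError(f"unknown baseline mode {mode!r}; "
                         f"choose from {sorted(BASELINE_WINDOWS)}")
    lo, hi = BASELINE_WINDOWS[mode]
    mask = epochs.time_mask(lo, hi)
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base, baseline_mode=mode)


def reject_epochs(epochs: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Amplitude-threshold artifact hook: drop epochs with |x| > threshold."""
    keep = np.max(np.abs(epochs.data), axis=(1, 2)) <= threshold_uv
    return replace(
        epochs, data=epochs.data[keep], conditions=epochs.conditions[keep],
        hit=epochs.hit[keep], trial_index=epochs.trial_index[keep],
    )


# ---------------------------------------------------------------------------
# windowed amplitudes and tests

def roi_window_amplitude(epochs: EpochSet, roi: str, window: ComponentWindow,
                         grouping: str = "condition") -> pd.Series:
    """Mean µV over ROI channels and window samples, averaged per group.

    ``grouping='condition'`` yields one value per primary condition;
    ``'congruency'`` and ``'target_class'`` pool accordingly.  Empty cells
    come back missing for pairwise exclusion downstream.
    """
    ch = epochs.pick_channels(ROI_CHANNELS[roi])
    mask = epochs.time_mask(*window.bounds)
    if not mask.any():
        raise ValueError(f"window {window.name} lies outside the epoch")
    per_epoch = epochs.data[:, ch, :][:, :, mask].mean(axis=(1, 2))
    if grouping == "condition":
        keys = epochs.conditions
        levels = ("con.SCI", "con.noSCI", "inc.SCI", "inc.noSCI")
    elif grouping == "congruency":
        keys = np.array([c.split(".")[0] for c in epochs.conditions])
        levels = ("con", "inc")
    elif grouping == "target_class":
        keys = np.array([c.split(".")[1] for c in epochs.conditions])
        levels = ("SCI", "noSCI")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return pd.Series(
        {lv: (float(per_epoch[keys == lv].mean()) if np.any(keys == lv) else np.nan)
         for lv in levels}, name=window.name)


def paired_t_one_tailed(a, b, direction: str = "greater"):
    """Paired t of a vs b; one-sided p in the stated direction; df = n - 1."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = stats.t.sf(t, df) if direction == "greater" else stats.t.cdf(t, df)
    return float(t), int(df), float(p)


def es_from_t(t: float, n: int) -> float:
    """Cohen's d from a paired t with n participants: d = t * sqrt(2/n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return t * np.sqrt(2.0 / n)


#: hypothesis id -> (component window, roi, baseline mode, contrast axis,
#: congruency stratum or None, direction of the first-named group)
ERP_HYPOTHESES = {
    "H3P3a": ("p3a", "vertex", "trial", "congruency", None, "greater"),
    "H3P3b": ("p3b", "parietal", "trial", "congruency", None, "less"),
    "H4pN1": ("primer_n1", "occipital", "trial", "target_class", None, "less"),
    "H4tN1.con": ("target_n1", "occipital", "target", "target_class", "con", "less"),
    "H4tN1.inc": ("target_n1", "occipital", "target", "target_class", "inc", "less"),
    "H4tP3a.con": ("p3a", "vertex", "target", "target_class", "con", "greater"),
    "H4tP3a.inc": ("p3a", "vertex", "target", "target_class", "inc", "greater"),
}


def participant_amplitudes(raw_epochs: EpochSet, lowpass: bool = True) -> pd.DataFrame:
    """All per-hypothesis group means for one participant's epochs.

    The epochs must be uncorrected ('none'); each hypothesis applies its own
    baseline before the windowed mean.
    """
    if raw_epochs.baseline_mode != "none":
        raise ValueError("pass uncorrected epochs; baselines are per hypothesis")
    cache = {}
    rows = []
    for hyp, (wname, roi, bmode, axis, stratum, _) in ERP_HYPOTHESES.items():
        if bmode not in cache:
            e = baseline_correct(raw_epochs, bmode)
            cache[bmode] = lowpass20(e) if lowpass else e
        ep = cache[bmode]
        if stratum is not None:
            keep = np.char.startswith(ep.conditions.astype(str), stratum + ".")
            ep = replace(ep, data=ep.data[keep], conditions=ep.conditions[keep],
                         hit=ep.hit[keep], trial_index=ep.trial_index[keep])
        vals = roi_window_amplitude(ep, roi, COMPONENT_WINDOWS[wname], grouping=axis)
        g1, g2 = (("con", "inc") if axis == "congruency" else ("SCI", "noSCI"))
        rows.append(dict(participant=raw_epochs.participant_id, hypothesis=hyp,
                         group1=g1, group2=g2, mean1=vals[g1], mean2=vals[g2]))
    return pd.DataFrame(rows)


def erp_battery(amplitudes: pd.DataFrame, n_participants: int = None) -> pd.DataFrame:
    """Cohort-level paired one-tailed t tests with Holm adjustment.

    ``amplitudes`` stacks ``participant_amplitudes`` rows over participants.
    Returns one row per hypothesis with the mean amplitude difference, t,
    df, raw and adjusted p, and Cohen's d.
    """
    from .behavior import holm_bonferroni

    rows = []
    for hyp, (_, _, _, _, stratum, direction) in ERP_HYPOTHESES.items():
        sub = amplitudes[amplitudes.hypothesis == hyp]
        a, b = sub.mean1.to_numpy(), sub.mean2.to_numpy()
        t, df, p = paired_t_one_tailed(a, b, direction=direction)
        n = int(np.sum(~(np.isnan(a) | np.isnan(b))))
        rows.append(dict(hypothesis=hyp, stratum=stratum or "",
                         diff_uv=float(np.nanmean(a - b)), t=t, df=df,
                         p_raw=p, es=es_from_t(t, n), n=n))
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_bonferroni(out.p_raw.to_numpy())
    return out[["hypothesis", "stratum", "diff_uv", "t", "df", "p_raw", "p_adj", "es", "n"]]
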