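import numpy as np
import pytest

from psicat import simulate
from psicat.erp import EpochSet
from psicat.geometry import GeometryConfig
from psicat.scheduler import build_practice


@pytest.fixture(scope="session")
def gconf():
    return GeometryConfig().validate()


@pytest.fixture(scope="session")
def models():
    """Default calibrated (behaviour, neural) models, reduced montage."""
    return simulate.default_models("reduced")


@pytest.fixture(scope="session")
def practice_session(models):
    """A short (12-trial) simulated session for fast pipeline tests."""
    behav, neural = models
    sched = build_practice(seed=11, make_stimuli=False)
    rng = np.random.default_rng(5)
    resp = simulate.simulate_responses(sched, behav, rng)
    session = simulate.simulate_recording(sched, resp, neural, rng)
    return sched, resp, session


@pytest.fixture(scope="session")
def cohort():
    """The default 17-participant synthetic cohort, analysed end to end."""
    from psicat.study import run_synthetic_study

    return run_synthetic_study(n_participants=17, seed=1, make_stimuli=True,
                               n_perm=500)


def make_epochs(data, sfreq=512.0, labels=None, conditions=None, hit=None,
                trial_index=None, tmin_s=-0.25):
    """Hand-built EpochSet around a (n_epochs, n_channels, n_samples) array."""
    data = np.asarray(data, float)
    n_ep, n_ch, n_t = data.shape
    if labels is None:
        from psicat.montage import load_montage

        pool = load_montage("reduced").labels
        # C20 first so single-channel epochs still carry the ERSP/ITC channel
        labels = tuple(["C20"] + [l for l in pool if l != "C20"])[:n_ch]
    times = (np.arange(n_t) + tmin_s * sfreq) / sfreq * 1000.0
    return EpochSet(
        data=data, sfreq=sfreq, labels=tuple(labels), times_ms=times,
        conditions=np.asarray(conditions if conditions is not None
                              else ["con.SCI"] * n_ep),
        hit=np.asarray(hit if hit is not None else [True] * n_ep, bool),
        trial_index=np.asarray(trial_index if trial_index is not None
                               else np.arange(n_ep), int),
    )
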