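"""Trial scheduling for the primed Kanizsa continuous performance test.

A test session is five blocks of 110 trials (550 total) separated by
one-minute breaks; each trial's condition is an independent uniform draw
from the 2 x 2 x 2 cells (congruency x target class x vertex count).  Every
trial shows a 100 ms fixation cross, a 150 ms primer, then the target held
until response, followed by a uniform 500 +/- 100 ms inter-trial interval.
A practice set holds 12 trials, three per primary (congruency x class)
condition.  With a ~750 ms mean response time the expected trial duration
is 100 + 150 + 750 + 500 = 1500 ms, i.e. a ~22 minute session.

Schedules are pure functions of (configs, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import geometry as geom

__all__ = [
    "TimingConfig",
    "ConditionLabel",
    "TrialSpec",
    "Schedule",
    "CONDITIONS",
    "PRIMARY_CONDITIONS",
    "build_schedule",
    "build_practice",
    "assign_response_hands",
    "export_events",
    "schedule_from_events",
]

N_BLOCKS = 5
TRIALS_PER_BLOCK = 110
PRACTICE_TRIALS = 12


@dataclass(frozen=True)
class TimingConfig:
    fixation_ms: float = 100.0
    primer_ms: float = 150.0
    target_timeout_ms: float = 3000.0  # simulation safety net; targets are
    # nominally held until response
    iti_base_ms: float = 500.0
    iti_jitter_ms: float = 100.0  # uniform +/- around the base
    block_break_s: float = 60.0
    lead_in_s: float = 2.0  # quiet recording before the first trial

    def validate(self) -> "TimingConfig":
        for name in ("fixation_ms", "primer_ms", "target_timeout_ms",
                     "iti_base_ms", "block_break_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.iti_jitter_ms < self.iti_base_ms:
            raise ValueError("iti_jitter_ms must lie in [0, iti_base_ms)")
        return self


@dataclass(frozen=True, order=True)
class ConditionLabel:
    congruency: str  # "con" | "inc"
    target_class: str  # "SCI" | "noSCI"
    n_vertices: int  # 3 | 4

    @property
    def primary(self) -> str:
        """Primary 2x2 cell name, e.g. 'con.SCI' (vertex count is a control)."""
        return f"{self.congruency}.{self.target_class}"

    def __str__(self) -> str:
        return f"{self.congruency}.{self.target_class}.{self.n_vertices}v"


#: all eight 2 x 2 x 2 condition cells
CONDITIONS: tuple = tuple(
    ConditionLabel(c, t, n)
    for c, t, n in itertools.product(("con", "inc"), ("SCI", "noSCI"), (3, 4))
)
#: the four primary cells, congruency x target class
PRIMARY_CONDITIONS = ("con.SCI", "con.noSCI", "inc.SCI", "inc.noSCI")


@dataclass(frozen=True)
class TrialSpec:
    trial_index: int  # session-wide, 0-based
    block_index: int
    condition: ConditionLabel
    target_id: str
    primer_id: str
    iti_ms: float  # realized, uniform on base +/- jitter
    fixation_onset_ms: float  # from session start
    primer_onset_ms: float
    target_onset_ms: float


@dataclass(frozen=True)
class Schedule:
    participant_id: str
    response_hand_map: dict  # {"SCI": "left"|"right", "noSCI": ...}
    blocks: tuple  # tuple of tuples of TrialSpec
    is_practice: bool
    seed: int
    timing: TimingConfig
    stimuli: dict = field(default_factory=dict, repr=False)  # id -> stimulus

    @property
    def trials(self) -> tuple:
        return tuple(t for block in self.blocks for t in block)

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)


def assign_response_hands(participant_index: int) -> dict:
    """Counterbalance SCI-response hand by participant parity.

    Even indices respond SCI with the right hand, odd with the left.
    """
    sci = "right" if participant_index % 2 == 0 else "left"
    return {"SCI": sci, "noSCI": "left" if sci == "right" else "right"}


def _realize_trials(conditions, timing, geometry, rng, make_stimuli, mean_rt_ms=750.0):
    """Lay trials on the timeline; target duration placeholder = mean RT.

    Onsets beyond the target are provisional until responses are simulated
    or recorded; the events exporter re-derives them from responses.
    """
    trials, stimuli = [], {}
    t = timing.lead_in_s * 1000.0
    block_index = 0
    per_block = len(conditions) if len(conditions) <= PRACTICE_TRIALS else TRIALS_PER_BLOCK
    for i, cond in enumerate(conditions):
        if i > 0 and i % per_block == 0:
            block_index += 1
            t += timing.block_break_s * 1000.0
        iti = rng.uniform(timing.iti_base_ms - timing.iti_jitter_ms,
                          timing.iti_base_ms + timing.iti_jitter_ms)
        tgt_id, pri_id = f"t{i:04d}", f"p{i:04d}"
        if make_stimuli:
            target, primer = geom.make_stimulus_pair(
                cond.n_vertices, cond.target_class, cond.congruency,
                geometry, rng, stimulus_id=tgt_id,
            )
            primer = replace(primer, primer_id=pri_id)
            stimuli[tgt_id], stimuli[pri_id] = target, primer
        fix_on = t
        pri_on = fix_on + timing.fixation_ms
        tgt_on = pri_on + timing.primer_ms
        trials.append(
            TrialSpec(
                trial_index=i, block_index=block_index, condition=cond,
                target_id=tgt_id, primer_id=pri_id, iti_ms=float(iti),
                fixation_onset_ms=float(fix_on), primer_onset_ms=float(pri_on),
                target_onset_ms=float(tgt_on),
            )
        )
        t = tgt_on + mean_rt_ms + iti
    blocks, cur = [], []
    for tr in trials:
        if cur and tr.block_index != cur[-1].block_index:
            blocks.append(tuple(cur))
            cur = []
        cur.append(tr)
    blocks.append(tuple(cur))
    return tuple(blocks), stimuli


def build_schedule(
    timing: TimingConfig = None,
    geometry: geom.GeometryConfig = None,
    seed: int = 0,
    participant_index: int = 0,
    make_stimuli: bool = True,
) -> Schedule:
    """Build the full 5 x 110-trial test schedule for one participant.

    Conditions are i.i.d. uniform over the eight cells (550 is not divisible
    by 8, so exact balance is impossible); every trial references freshly
    generated stimuli when ``make_stimuli`` is set.
    """
    timing = (timing or TimingConfig()).validate()
    geometry = (geometry or geom.GeometryConfig()).validate()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(CONDITIONS), N_BLOCKS * TRIALS_PER_BLOCK)
    conditions = [CONDITIONS[i] for i in idx]
    blocks, stimuli = _realize_trials(conditions, timing, geometry, rng, make_stimuli)
    return Schedule(
        participant_id=f"sub-{participant_index:02d}",
        response_hand_map=assign_response_hands(participant_index),
        blocks=blocks, is_practice=False, seed=seed, timing=timing, stimuli=stimuli,
    )


def build_practice(
    timing: TimingConfig = None,
    geometry: geom.GeometryConfig = None,
    seed: int = 0,
    participant_index: int = 0,
    make_stimuli: bool = True,
) -> Schedule:
    """Build the 12-trial practice set: three per primary condition, shuffled.

    Vertex counts alternate 3/4/3 across each primary condition's three
    repetitions so both stimulus complexities are previewed.
    """
    timing = (timing or TimingConfig()).validate()
    geometry = (geometry or geom.GeometryConfig()).validate()
    rng = np.random.default_rng(seed)
    conditions = [
        ConditionLabel(c, t, n)
        for c, t in itertools.product(("con", "inc"), ("SCI", "noSCI"))
        for n in (3, 4, 3)
    ]
    order = rng.permutation(len(conditions))
    conditions = [conditions[i] for i in order]
    blocks, stimuli = _realize_trials(conditions, timing, geometry, rng, make_stimuli)
    return Schedule(
        participant_id=f"sub-{participant_index:02d}",
        response_hand_map=assign_response_hands(participant_index),
        blocks=blocks, is_practice=True, seed=seed, timing=timing, stimuli=stimuli,
    )


# ---------------------------------------------------------------------------
# events table

EVENT_COLUMNS = [
    "onset", "duration", "event_type", "trial_index", "block", "congruency",
    "target_class", "n_vertices", "stimulus_id", "response", "rt_ms", "correct",
]


def export_events(schedule: Schedule, responses: pd.DataFrame = None) -> pd.DataFrame:
    """One row per event (fixation/primer/target/response/break), onsets in s.

    Without ``responses`` the target/response timeline uses the schedule's
    provisional 750 ms placeholder; with responses (columns ``trial_index``,
    ``button``, ``rt_ms``, ``correct``) the realized timeline is emitted and
    the response rows carry behaviour.
    """
    timing = schedule.timing
    resp = None
    if responses is not None:
        resp = responses.set_index("trial_index")
    rows = []
    t = timing.lead_in_s * 1000.0
    prev_block = 0
    for tr in schedule.trials:
        if tr.block_index != prev_block:
            rows.append(dict(onset=t / 1000.0, duration=timing.block_break_s,
                             event_type="break", trial_index=-1, block=prev_block))
            t += timing.block_break_s * 1000.0
            prev_block = tr.block_index
        cond = tr.condition
        common = dict(trial_index=tr.trial_index, block=tr.block_index,
                      congruency=cond.congruency, target_class=cond.target_class,
                      n_vertices=cond.n_vertices)
        fix_on, pri_on, tgt_on = t, t + timing.fixation_ms, t + timing.fixation_ms + timing.primer_ms
        if resp is not None and tr.trial_index in resp.index:
            r = resp.loc[tr.trial_index]
            rt, button, correct = float(r["rt_ms"]), r["button"], bool(r["correct"])
        else:
            rt, button, correct = 750.0, "", True
        rows.append(dict(onset=fix_on / 1000.0, duration=timing.fixation_ms / 1000.0,
                         event_type="fixation", **common))
        rows.append(dict(onset=pri_on / 1000.0, duration=timing.primer_ms / 1000.0,
                         event_type="primer", stimulus_id=tr.primer_id, **common))
        rows.append(dict(onset=tgt_on / 1000.0, duration=rt / 1000.0,
                         event_type="target", stimulus_id=tr.target_id, **common))
        rows.append(dict(onset=(tgt_on + rt) / 1000.0, duration=0.0,
                         event_type="response", response=button, rt_ms=rt,
                         correct=correct, **common))
        t = tgt_on + rt + tr.iti_ms
    df = pd.DataFrame(rows)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[EVENT_COLUMNS]


def schedule_from_events(events: pd.DataFrame) -> pd.DataFrame:
    """Per-trial view (one row per target) recovered from an events table."""
    tgt = events[events.event_type == "target"].copy()
    rsp = events[events.event_type == "response"][["trial_index", "response", "rt_ms", "correct"]]
    out = tgt.drop(columns=["response", "rt_ms", "correct"]).merge(
        rsp, on="trial_index", how="left"
    )
    return out.reset_index(drop=True)
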