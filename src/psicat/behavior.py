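"""Behavioural summaries and the nonparametric hypothesis battery.

Per participant and primary condition the summary is the median RT and the
SD of RTs over hit trials only (error trials removed first) plus the error
percentage.  Condition contrasts are one-sided Mann-Whitney U tests with
effect size ES = |z| / sqrt(N) (N = total observations) and Holm-Bonferroni
family-wise adjustment.  A Wilcoxon signed-rank alternative is available
behind a flag for the paired reading of the design.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scheduler import PRIMARY_CONDITIONS

__all__ = [
    "BehavioralSummary",
    "RankTestResult",
    "summarize",
    "mann_whitney_one_sided",
    "wilcoxon_one_sided",
    "es_from_z",
    "holm_bonferroni",
    "assumption_screens",
    "behavioural_battery",
    "check_rt_transitivity",
]

#: the behavioural hypothesis family: id, column, grouping, direction a < b
HYPOTHESES = (
    ("H1rt.con", "median_rt_ms", ("con.SCI", "con.noSCI"), "less"),
    ("H1rt.mid", "median_rt_ms", ("con.noSCI", "inc.SCI"), "less"),
    ("H1rt.inc", "median_rt_ms", ("inc.SCI", "inc.noSCI"), "less"),
    ("H1rtv", "rtv_ms", ("SCI", "noSCI"), "less"),
    ("H2err", "error_pct", ("con", "inc"), "less"),
)


@dataclass(frozen=True)
class BehavioralSummary:
    """Per participant x condition medians/RTVs/error rates (long format)."""

    table: pd.DataFrame  # participant, condition, median_rt_ms, rtv_ms, error_pct, n_hits
    class_rtv: pd.DataFrame  # participant, target_class, rtv_ms (hits pooled over congruency)
    congruency_error: pd.DataFrame  # participant, congruency, error_pct


@dataclass(frozen=True)
class RankTestResult:
    hypothesis: str
    direction: str
    median_diff: float  # median(b) - median(a) for direction a < b
    u_stat: float
    z: float
    p_raw: float
    p_adj: float
    es: float
    n: int
    degenerate: bool = False


def summarize(responses: pd.DataFrame, participant: str = "") -> BehavioralSummary:
    """Summarize one participant's responses per primary condition.

    RT and RTV use hit (correct) trials only; conditions with no hits are
    emitted with missing values so downstream tests can exclude them
    pairwise.
    """
    req = {"condition", "rt_ms", "correct"}
    if not req <= set(responses.columns):
        raise ValueError(f"responses must carry columns {sorted(req)}")
    rows = []
    for cond in PRIMARY_CONDITIONS:
        sub = responses[responses.condition == cond]
        hits = sub[sub.correct.astype(bool)]
        rows.append(dict(
            participant=participant, condition=cond,
            median_rt_ms=float(hits.rt_ms.median()) if len(hits) else np.nan,
            rtv_ms=float(hits.rt_ms.std(ddof=1)) if len(hits) > 1 else
            (0.0 if len(hits) == 1 else np.nan),
            error_pct=100.0 * (1.0 - sub.correct.mean()) if len(sub) else np.nan,
            n_hits=len(hits), n_trials=len(sub),
        ))
    cls_rows = []
    for cls in ("SCI", "noSCI"):
        hits = responses[(responses.condition.str.endswith("." + cls))
                         & responses.correct.astype(bool)]
        cls_rows.append(dict(participant=participant, target_class=cls,
                             rtv_ms=float(hits.rt_ms.std(ddof=1)) if len(hits) > 1 else np.nan))
    con_rows = []
    for cg in ("con", "inc"):
        sub = responses[responses.condition.str.startswith(cg + ".")]
        con_rows.append(dict(participant=participant, congruency=cg,
                             error_pct=100.0 * (1.0 - sub.correct.mean()) if len(sub) else np.nan))
    return BehavioralSummary(
        table=pd.DataFrame(rows),
        class_rtv=pd.DataFrame(cls_rows),
        congruency_error=pd.DataFrame(con_rows),
    )


def concat_summaries(summaries) -> BehavioralSummary:
    return BehavioralSummary(
        table=pd.concat([s.table for s in summaries], ignore_index=True),
        class_rtv=pd.concat([s.class_rtv for s in summaries], ignore_index=True),
        congruency_error=pd.concat([s.congruency_error for s in summaries], ignore_index=True),
    )


# ---------------------------------------------------------------------------
# rank tests

def _u_and_z(a: np.ndarray, b: np.ndarray):
    """U of sample a (rank-sum form) and its tie-corrected normal z."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = 0.0 if var == 0 else (u1 - mu) / math.sqrt(var)
    return float(u1), float(z)


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float, direction: str) -> float:
    """Exact one-sided p by enumerating all label assignments (ties allowed)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u, _ = _u_and_z(pooled[list(idx)], np.delete(pooled, list(idx)))
        total += 1
        if direction == "less":
            count += u <= u_obs
        else:
            count += u >= u_obs
    return count / total


def mann_whitney_one_sided(a, b, direction: str = "less",
                           hypothesis: str = "", exact_max_n: int = 8) -> RankTestResult:
    """One-sided Mann-Whitney U test of ``a`` vs ``b``.

    ``direction='less'`` tests the alternative that ``a`` is stochastically
    smaller than ``b``.  For samples of at most ``exact_max_n`` each, the
    one-sided p is computed by exact enumeration of label assignments;
    otherwise a tie-corrected normal approximation is used (no continuity
    correction, so ES = |z|/sqrt(N) matches the z actually reported).
    """
    a = np.asarray([x for x in np.asarray(a, float).ravel() if not np.isnan(x)])
    b = np.asarray([x for x in np.asarray(b, float).ravel() if not np.isnan(x)])
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    n = len(a) + len(b)
    u, z = _u_and_z(a, b)
    degenerate = bool(np.all(np.concatenate([a, b]) == a[0]))
    if degenerate or z == 0.0:
        p = 0.5  # perfectly symmetric evidence either way
    elif len(a) <= exact_max_n and len(b) <= exact_max_n:
        p = _exact_p(a, b, u, direction)
    else:
        p = stats.norm.cdf(z) if direction == "less" else stats.norm.sf(z)
    return RankTestResult(
        hypothesis=hypothesis, direction=direction,
        median_diff=float(np.median(b) - np.median(a)),
        u_stat=u, z=z, p_raw=float(p), p_adj=float("nan"),
        es=es_from_z(z, n), n=n, degenerate=bool(degenerate),
    )


def wilcoxon_one_sided(a, b, direction: str = "less", hypothesis: str = "") -> RankTestResult:
    """Paired alternative: one-sided Wilcoxon signed-rank on b - a.

    Provided because the compared samples are participant-paired even though
    the documented test is the (unpaired) Mann-Whitney U.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    alt = "less" if direction == "less" else "greater"
    res = stats.wilcoxon(a, b, alternative=alt, method="approx")
    z = float(getattr(res, "zstatistic", stats.norm.ppf(res.pvalue)))
    return RankTestResult(
        hypothesis=hypothesis, direction=direction,
        median_diff=float(np.median(b) - np.median(a)),
        u_stat=float(res.statistic), z=z, p_raw=float(res.pvalue),
        p_adj=float("nan"), es=es_from_z(z, 2 * len(a)), n=2 * len(a),
    )


def es_from_z(z: float, n: int) -> float:
    """Rank-test effect size |z| / sqrt(N), N the total observation count."""
    if n <= 0:
        raise ValueError("N must be positive")
    return abs(z) / math.sqrt(n)


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    return multipletests(p, method="holm")[1]


def assumption_screens(a, b) -> dict:
    """Advisory Levene / Shapiro-Wilk screens; never blocks the rank test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    out = {"degenerate": bool(np.ptp(a) == 0 or np.ptp(b) == 0)}
    if out["degenerate"]:
        out.update(levene_p=np.nan, shapiro_p_a=np.nan, shapiro_p_b=np.nan)
        return out
    out["levene_p"] = float(stats.levene(a, b).pvalue)
    out["shapiro_p_a"] = float(stats.shapiro(a).pvalue) if len(a) >= 3 else np.nan
    out["shapiro_p_b"] = float(stats.shapiro(b).pvalue) if len(b) >= 3 else np.nan
    return out


# ---------------------------------------------------------------------------
# the full behavioural family

def _samples_for(summary: BehavioralSummary, hyp):
    _, column, (ga, gb), _ = hyp
    if column == "median_rt_ms":
        t = summary.table.pivot(index="participant", columns="condition",
                                values="median_rt_ms")
        return t[ga].to_numpy(), t[gb].to_numpy()
    if column == "rtv_ms":
        t = summary.class_rtv.pivot(index="participant", columns="target_class",
                                    values="rtv_ms")
        return t[ga].to_numpy(), t[gb].to_numpy()
    t = summary.congruency_error.pivot(index="participant", columns="congruency",
                                       values="error_pct")
    return t[ga].to_numpy(), t[gb].to_numpy()


def behavioural_battery(summary: BehavioralSummary, paired: bool = False) -> pd.DataFrame:
    """Run H1rt (three chain links), H1rtv and H2err with Holm adjustment."""
    results = []
    for hyp in HYPOTHESES:
        a, b = _samples_for(summary, hyp)
        test = wilcoxon_one_sided if paired else mann_whitney_one_sided
        results.append(test(a, b, direction=hyp[3], hypothesis=hyp[0]))
    adj = holm_bonferroni([r.p_raw for r in results])
    rows = [
        dict(hypothesis=r.hypothesis, direction=r.direction,
             median_diff=r.median_diff, u_stat=r.u_stat, z=r.z,
             p_raw=r.p_raw, p_adj=float(pa), es=r.es, n=r.n,
             degenerate=r.degenerate)
        for r, pa in zip(results, adj)
    ]
    return pd.DataFrame(rows)


def check_rt_transitivity(summary: BehavioralSummary, alpha: float = 0.05) -> dict:
    """Test the RT chain link-by-link; the chain is transitive if all hold."""
    battery = behavioural_battery(summary)
    chain = battery[battery.hypothesis.isin(["H1rt.con", "H1rt.mid", "H1rt.inc"])]
    links = {
        row.hypothesis: bool(row.median_diff > 0 and row.p_adj <= alpha)
        for row in chain.itertuples()
    }
    return {"links": links, "transitive": all(links.values())}
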