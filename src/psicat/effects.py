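"""Effect-size pooling and the headline congruency-vs-gestalt verdict.

Significant results are pooled by data family (behavioural, using
ES = z/sqrt(N); neural, using Cohen's d — never mixed) and by question
(congruency manipulation vs gestalt SCI/no-SCI class), their absolute
effect sizes reduced to a median, mapped to the extended rule-of-thumb
nominal labels, and compared: the headline claim holds when the congruency
median exceeds the gestalt median within every family.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "ESRecord",
    "HESVerdict",
    "pool_median_abs",
    "nominal_label",
    "hes_verdict",
    "records_from_batteries",
]

#: extended Cohen's-d rule-of-thumb thresholds, closed lower bounds
_NOMINAL_THRESHOLDS = (
    (2.0, "huge"),
    (1.2, "very large"),
    (0.8, "large"),
    (0.5, "medium"),
    (0.2, "small"),
    (0.01, "very small"),
)

#: question tags for the standard hypothesis battery; H1rt rows mix
#: congruency and gestalt orderings and are excluded from pooling
_QUESTION = {
    "H1rtv": "sci", "H2err": "congruency",
    "H3P3a": "congruency", "H3P3b": "congruency",
    "H4pN1": "sci", "H4tN1.con": "sci", "H4tN1.inc": "sci",
    "H4tP3a.con": "sci", "H4tP3a.inc": "sci",
}


@dataclass(frozen=True)
class ESRecord:
    hypothesis: str
    family: str  # 'behavioural' | 'neural'
    question: str  # 'congruency' | 'sci' | None (excluded from pooling)
    es: float
    estimator: str  # 'r_from_z' | 'd_from_t'
    significant: bool  # adjusted p <= 0.05

    def __post_init__(self):
        if self.family not in ("behavioural", "neural"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.question not in ("congruency", "sci", None):
            raise ValueError(f"unknown question {self.question!r}")


@dataclass(frozen=True)
class HESVerdict:
    per_family: pd.DataFrame  # family, question medians + labels, supported flag
    supported: bool  # congruency median > sci median in every computable family
    complete: bool  # every family had both cells populated


def _round2_half_away(x: float) -> float:
    d = Decimal(repr(abs(float(x)))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(d) * (1 if x >= 0 else -1)


def pool_median_abs(records, family: str, question: str) -> float:
    """Median |ES| over the cell's *significant* records, to 2 decimals.

    Raises if the cell mixes ES estimators; returns NaN for an empty cell.
    """
    cell = [r for r in records
            if r.family == family and r.question == question and r.significant]
    if not cell:
        return float("nan")
    if len({r.estimator for r in cell}) > 1:
        raise ValueError(f"cell ({family}, {question}) mixes ES estimators")
    return _round2_half_away(float(np.median([abs(r.es) for r in cell])))


def nominal_label(es_abs: float) -> str:
    """Extended rule-of-thumb label for an absolute effect size."""
    if not np.isfinite(es_abs) or es_abs < 0:
        raise ValueError("nominal_label expects a finite non-negative |ES|")
    for lo, label in _NOMINAL_THRESHOLDS:
        if es_abs >= lo:
            return label
    return "negligible"


def hes_verdict(records) -> HESVerdict:
    """Per-family congruency-vs-gestalt median comparison and overall verdict."""
    rows = []
    supported_flags, complete = [], True
    for family in ("behavioural", "neural"):
        if not any(r.family == family for r in records):
            continue
        m_con = pool_median_abs(records, family, "congruency")
        m_sci = pool_median_abs(records, family, "sci")
        ok = np.isfinite(m_con) and np.isfinite(m_sci)
        complete &= ok
        supported = bool(m_con > m_sci) if ok else False
        if ok:
            supported_flags.append(supported)
        rows.append(dict(
            family=family, median_es_congruency=m_con, median_es_sci=m_sci,
            label_congruency=nominal_label(m_con) if np.isfinite(m_con) else "",
            label_sci=nominal_label(m_sci) if np.isfinite(m_sci) else "",
            supported=supported,
        ))
    return HESVerdict(
        per_family=pd.DataFrame(rows),
        supported=bool(supported_flags) and all(bool(f) for f in supported_flags),
        complete=bool(complete),
    )


def records_from_batteries(behavioural: pd.DataFrame, erp: pd.DataFrame,
                           alpha: float = 0.05) -> list:
    """Build ESRecords from the behavioural and ERP test tables."""
    records = []
    for row in behavioural.itertuples():
        records.append(ESRecord(
            hypothesis=row.hypothesis, family="behavioural",
            question=_QUESTION.get(row.hypothesis),
            es=float(row.es), estimator="r_from_z",
            significant=bool(row.p_adj <= alpha),
        ))
    for row in erp.itertuples():
        records.append(ESRecord(
            hypothesis=row.hypothesis, family="neural",
            question=_QUESTION.get(row.hypothesis),
            es=float(row.es), estimator="d_from_t",
            significant=bool(row.p_adj <= alpha),
        ))
    return records
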