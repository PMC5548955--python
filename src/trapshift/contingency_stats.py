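"""Exact 2x2 contingency statistics and seizure-incidence summaries.

``fisher_exact`` is the Fisher engine used by every other module. The
two-sided p-value follows the probability-mass rule: conditioning on both
margins, sum the hypergeometric probabilities of all tables whose
probability does not exceed the observed one (with a small tolerance factor
to guard floating-point ties). Hypergeometric terms are computed with
log-gamma, so large tables cannot overflow.

Incidence summaries score audiogenic seizures by their maximal stage
(wild running < clonic < tonic); each animal contributes to exactly one
stage, so the stage counts partition the seizing animals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ValidationError

#: severity stages in increasing order; "none" means no seizure
STAGES = ("WR", "clonic", "tonic")

_TIE_TOLERANCE = 1.0 + 1e-7


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float
    #: set when a zero cell makes the odds ratio 0 or infinite
    degenerate_odds: bool


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValidationError("table cells must be non-negative integers")
    arr = arr.astype(np.int64)
    if arr.sum() == 0:
        raise ValidationError("all-zero table has no defined test")
    return arr


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test for a 2x2 table.

    Returns the sample odds ratio (a*d)/(b*c) — infinity or 0 when a zero
    cell makes it degenerate, with ``degenerate_odds`` flagged — and the
    probability-mass two-sided p-value.
    """
    arr = _as_table(table)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    if a * d > 0 and b * c > 0:
        odds, degenerate = (a * d) / (b * c), False
    elif b * c == 0 and a * d == 0:
        odds, degenerate = math.nan, True  # 0/0: undefined
    elif b * c == 0:
        odds, degenerate = math.inf, True
    else:
        odds, degenerate = 0.0, True

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    # log P(X = x) for hypergeometric with margins (r1, r2, c1)
    logp = (
        gammaln(r1 + 1) - gammaln(support + 1) - gammaln(r1 - support + 1)
        + gammaln(r2 + 1) - gammaln(c1 - support + 1) - gammaln(r2 - c1 + support + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    probs = np.exp(logp)
    observed = probs[a - lo]
    p = float(probs[probs <= observed * _TIE_TOLERANCE].sum())
    return FisherResult(odds_ratio=odds, p_value=min(p, 1.0), degenerate_odds=degenerate)


def incidence_percent(n_seizing: int, n_tested: int) -> int:
    """Percent incidence rounded to the nearest integer, half away from zero."""
    if n_tested <= 0:
        raise ValidationError("n_tested must be positive")
    if not 0 <= n_seizing <= n_tested:
        raise ValidationError("n_seizing must lie in [0, n_tested]")
    return int(math.floor(100.0 * n_seizing / n_tested + 0.5))


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"animal_id", "group", "max_stage"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"records missing columns: {sorted(missing)}")
    allowed = {"none", *STAGES}
    bad = set(records["max_stage"]) - allowed
    if bad:
        raise ValidationError(f"unknown seizure stage(s): {sorted(bad)}")
    if records["animal_id"].duplicated().any():
        dup = records.loc[records["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise ValidationError(f"animal {dup!r} recorded more than once")
    return records


def incidence(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group seizure incidence from maximal-stage records.

    ``records`` needs columns animal_id, group, max_stage in
    {none, WR, clonic, tonic}. Returns one row per group with n_tested,
    n_seizing and the rounded percent.
    """
    records = _validate_records(records)
    rows = []
    for group, sub in records.groupby("group", sort=True):
        tested = len(sub)
        seizing = int((sub["max_stage"] != "none").sum())
        rows.append(
            {
                "group": group,
                "n_tested": tested,
                "n_seizing": seizing,
                "percent": incidence_percent(seizing, tested),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def severity_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-stage counts and percents under the maximal-stage rule.

    An animal recorded at a stage contributes only to that stage, so the
    stage counts sum to the number of seizing animals in the group.
    """
    records = _validate_records(records)
    rows = []
    for group, sub in records.groupby("group", sort=True):
        tested = len(sub)
        for stage in STAGES:
            count = int((sub["max_stage"] == stage).sum())
            rows.append(
                {
                    "group": group,
                    "stage": stage,
                    "count": count,
                    "n_tested": tested,
                    "percent": incidence_percent(count, tested),
                }
            )
    out = pd.DataFrame(rows)
    # consistency: stage counts partition the seizing animals
    seizing = incidence(records)["n_seizing"]
    per_group = out.groupby("group")["count"].sum()
    for group in per_group.index:
        if per_group[group] != seizing[group]:
            raise ValidationError(
                f"stage counts for group {group!r} do not sum to seizing animals"
            )
    return out.set_index(["group", "stage"])
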