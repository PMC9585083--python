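"""Clinical stratification: NOTCH-activation score, CIITA dichotomization,
Kaplan-Meier / log-rank comparisons, and Fisher-exact mutation enrichment.

The NOTCH-activation score of a patient is the arithmetic mean of the
normalized expression of HES1, HES2, HEY1 and HEY2; together with CIITA
expression it defines four patient groups (NOTCH high/low x CIITA high/low).
"High" means strictly above the threshold; the threshold is either the
cohort median or a frozen value carried over from a reference cohort, so the
same cut can be re-applied to an independent dataset.  The survival
machinery (product-limit estimator, k-group log-rank, Fisher's exact test)
is implemented from first principles; time-to-treatment and overall survival
share the same right-censored code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, InputFormatError

SCORE_GENES = ("hes1", "hes2", "hey1", "hey2")

__all__ = [
    "SCORE_GENES",
    "StratifiedCohort",
    "SurvivalComparison",
    "EnrichmentResult",
    "notch_score",
    "dichotomize",
    "stratify_four_groups",
    "kaplan_meier",
    "logrank_test",
    "fisher_enrichment",
]


def notch_score(cohort: pd.DataFrame) -> pd.Series:
    """Mean of HES1/2 and HEY1/2 expression per patient."""
    missing_cols = [g for g in SCORE_GENES if g not in cohort.columns]
    if missing_cols:
        raise InputFormatError(f"cohort table missing score genes: {missing_cols}")
    block = cohort[list(SCORE_GENES)]
    if block.isna().any().any():
        r, c = np.argwhere(block.isna().to_numpy())[0]
        patient = cohort["patient"].iloc[r] if "patient" in cohort.columns else cohort.index[r]
        raise InputFormatError(f"patient {patient} has missing {SCORE_GENES[c]} expression")
    score = block.mean(axis=1)
    score.name = "notch_score"
    return score


def dichotomize(values, threshold="median") -> tuple[pd.Series, float]:
    """Label values high/low around a threshold (strictly above = high).

    ``threshold`` may be a number or ``"median"``; values exactly equal to
    the threshold are labeled low.  Returns (labels, resolved threshold).
    """
    v = pd.Series(values, dtype=float)
    if len(v) < 2:
        raise ComputationError("dichotomize needs at least two values")
    thr = float(v.median()) if isinstance(threshold, str) and threshold == "median" else float(threshold)
    labels = pd.Series(np.where(v.to_numpy() > thr, "high", "low"), index=v.index)
    return labels, thr


@dataclass
class StratifiedCohort:
    """Four-group stratification with the thresholds that produced it."""

    table: pd.DataFrame  # patient, notch_score, notch_group, ciita_group, four_group
    notch_threshold: float
    ciita_threshold: float

    def group_sizes(self) -> pd.Series:
        return self.table["four_group"].value_counts().sort_index()


def stratify_four_groups(
    cohort: pd.DataFrame,
    notch_threshold="median",
    ciita_threshold="median",
) -> StratifiedCohort:
    """Cross NOTCH-score and CIITA dichotomizations into four groups.

    Thresholds resolved here (e.g. cohort medians) are recorded in the
    result so they can be frozen and re-applied verbatim to a second cohort.
    """
    score = notch_score(cohort)
    if "ciita" not in cohort.columns:
        raise InputFormatError("cohort table lacks a 'ciita' column")
    notch_group, notch_thr = dichotomize(score, notch_threshold)
    ciita_group, ciita_thr = dichotomize(cohort["ciita"], ciita_threshold)
    table = pd.DataFrame(
        {
            "patient": cohort["patient"] if "patient" in cohort.columns else cohort.index,
            "notch_score": score,
            "notch_group": notch_group,
            "ciita_group": ciita_group,
        }
    )
    table["four_group"] = "notch_" + table["notch_group"] + "_ciita_" + table["ciita_group"]
    return StratifiedCohort(table=table, notch_threshold=notch_thr, ciita_threshold=ciita_thr)


# ---------------------------------------------------------------------------
# survival machinery
# ---------------------------------------------------------------------------

def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time with the number at risk, number
    of events, and the running estimate S(t) = prod (1 - d_i/n_i).  Subjects
    censored at t are counted at risk at t.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size != e.size or t.size == 0:
        raise InputFormatError("times and events must be non-empty and aligned")
    if (t < 0).any():
        raise InputFormatError("negative survival time")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    rows = []
    surv = 1.0
    event_times = np.unique(t[e == 1])
    for et in event_times:
        n_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        surv *= 1.0 - d / n_risk
        rows.append((float(et), n_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_event", "survival"])


@dataclass
class SurvivalComparison:
    """Log-rank comparison of two or more groups with their KM curves."""

    km_curves: dict  # group label -> kaplan_meier frame
    statistic: float
    df: int
    p_value: float


def logrank_test(times, events, groups) -> SurvivalComparison:
    """Unweighted k-group log-rank test from observed-minus-expected counts.

    At every pooled event time the observed events per group are compared
    with their hypergeometric expectation; the chi-square statistic with
    k - 1 degrees of freedom uses the full covariance of the O - E vector.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if not (t.size == e.size == g.size) or t.size == 0:
        raise InputFormatError("times, events and groups must be non-empty and aligned")
    if (t < 0).any():
        raise InputFormatError("negative survival time")
    if e.sum() == 0:
        raise ComputationError("log-rank test requires at least one event")
    labels = np.unique(g)
    k = labels.size
    if k < 2:
        raise InputFormatError("log-rank test needs at least two groups")

    event_times = np.unique(t[e == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n = int(at_risk.sum())
        d = int(((t == et) & (e == 1)).sum())
        if n < 1:
            continue
        n_g = np.array([int((at_risk & (g == lab)).sum()) for lab in labels], dtype=float)
        d_g = np.array([int(((t == et) & (e == 1) & (g == lab)).sum()) for lab in labels],
                       dtype=float)
        O += d_g
        E += n_g * d / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            V += factor * (np.diag(n_g * n) - np.outer(n_g, n_g)) / n ** 2

    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    if np.allclose(diff, 0.0):
        statistic = 0.0
    else:
        statistic = float(diff @ np.linalg.pinv(Vsub) @ diff)
    statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, k - 1)) if statistic > 0 else 1.0
    km = {
        str(lab): kaplan_meier(t[g == lab], e[g == lab]) for lab in labels
    }
    return SurvivalComparison(km_curves=km, statistic=statistic, df=k - 1, p_value=p)


@dataclass
class EnrichmentResult:
    """Two-by-two enrichment: counts, odds ratio and Fisher exact p."""

    table: tuple  # (a, b, c, d)
    odds_ratio: float
    p_value: float


def fisher_enrichment(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Two-sided p sums the hypergeometric probabilities of every table with
    the same margins whose probability does not exceed the observed table's
    (probability-ordering rule).  The odds ratio is ad/bc, infinite when
    bc = 0 and ad > 0.
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise InputFormatError("cell counts must be non-negative integers")
    a, b, c, d = (int(x) for x in counts)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise InputFormatError("degenerate 2x2 table: a zero margin")
    n = r1 + r2
    dist = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    p = min(1.0, p)
    if b * c == 0:
        odds = math.inf if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(table=(a, b, c, d), odds_ratio=float(odds), p_value=p)
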