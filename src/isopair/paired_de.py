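"""Paired fold-change consistency differential-expression calling.

The core statistic is deliberately simple: for each patient an isogenic pair
(construct-transduced over control) yields one log2 fold change per feature,
and a feature is called when those per-pair fold changes agree.  Three
criteria are provided:

* standard — |log2FC| > threshold in at least half of the pairs;
* stringent — additionally the fold change has the same sign in every pair;
* protein — mean |log2FC| > threshold and the same sign in every pair
  (no per-pair threshold count), the rule used for small TMT cohorts.

Normalization helpers (quantile normalization, trimmed-mean-of-M-values
scaling, median scaling of peptide intensities) and the genotype-effect and
top-variable-gene comparisons round out the module.  No p-values are
attached to consistency calls: the criteria are threshold rules, not tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, InputFormatError

__all__ = [
    "ConsistencyCriterion",
    "ConsistencyCallResult",
    "GenotypeComparison",
    "STANDARD_CRITERION",
    "STRINGENT_CRITERION",
    "PROTEIN_CRITERION",
    "quantile_normalize",
    "trimmed_mean_scale",
    "normalize_counts",
    "pairwise_log2fc",
    "call_consistency",
    "call_protein_consistency",
    "median_scale_peptides",
    "sum_peptides_to_proteins",
    "benjamini_hochberg",
    "compare_genotype_effects",
    "top_variable_correlation",
]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the common reference distribution.

    The reference is the vector of row-wise means of the column-sorted
    matrix; ties within a column receive the mean of the reference values at
    their tied ranks, so identical inputs map to identical outputs.
    """
    if m.shape[1] < 2:
        raise ComputationError("quantile normalization needs at least two samples")
    X = m.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise InputFormatError("matrix contains non-finite values")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average the assigned reference values over tied groups
        _, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def trimmed_mean_scale(
    m: pd.DataFrame,
    trim_logratio: float = 0.3,
    trim_abundance: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, one positive factor per sample.

    The reference sample is the column whose 75th-percentile count fraction
    is closest to the mean of all columns' 75th percentiles.  For each
    sample, per-feature log ratios (M) and average abundances (A) against the
    reference are doubly trimmed (``trim_logratio`` on each M tail,
    ``trim_abundance`` on each A tail) and the factor is two to the
    precision-weighted mean of the surviving M values.  Factors are anchored
    so their geometric mean is 1; they are *residual* factors on top of
    library size, so a pure depth difference yields factors of 1.
    """
    X = m.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        raise ComputationError("trimmed-mean scaling: a sample has zero total counts")
    frac = X / lib
    q75 = np.quantile(frac, 0.75, axis=0)
    ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    fr = frac[:, ref_j]

    factors = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref_j:
            continue
        fj = frac[:, j]
        keep = (X[:, j] > 0) & (X[:, ref_j] > 0)
        if keep.sum() < 2:
            continue
        M = np.log2(fj[keep] / fr[keep])
        A = 0.5 * np.log2(fj[keep] * fr[keep])
        w = (lib[j] - X[keep, j]) / (lib[j] * X[keep, j]) + (
            lib[ref_j] - X[keep, ref_j]
        ) / (lib[ref_j] * X[keep, ref_j])
        n = M.size
        rM = stats.rankdata(M)
        rA = stats.rankdata(A)
        loM, hiM = np.floor(n * trim_logratio) + 1, n - np.floor(n * trim_logratio)
        loA, hiA = np.floor(n * trim_abundance) + 1, n - np.floor(n * trim_abundance)
        sel = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if sel.any() and w[sel].sum() > 0:
            factors[j] = 2.0 ** (np.sum(w[sel] * M[sel]) / np.sum(w[sel]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.columns, name="tmm_factor")


def normalize_counts(m: pd.DataFrame, quantile: bool = True, tmm: bool = True) -> pd.DataFrame:
    """Quantile normalization followed by trimmed-mean scaling.

    After scaling, every sample is divided by its effective library size
    (library size times its factor) and re-centered on the geometric mean of
    effective sizes, so magnitudes stay on the counts scale.
    """
    out = quantile_normalize(m) if quantile else m.astype(float)
    if tmm:
        factors = trimmed_mean_scale(out)
        eff = out.sum(axis=0) * factors
        out = out / eff * np.exp(np.mean(np.log(eff)))
    return out


# ---------------------------------------------------------------------------
# per-pair fold changes and consistency calls
# ---------------------------------------------------------------------------

def pairwise_log2fc(
    m: pd.DataFrame, sheet: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-patient log2((treated + pseudocount) / (control + pseudocount)).

    Returns a feature-by-patient table with one column per isogenic pair.
    """
    if pseudocount < 0:
        raise InputFormatError("pseudocount must be >= 0")
    cols = {}
    for patient, grp in sheet.groupby("patient", sort=True):
        by_cond = grp.set_index("condition")["sample"]
        if "treated" not in by_cond.index or "control" not in by_cond.index:
            raise InputFormatError(f"patient {patient} is missing a control or treated sample")
        treated = m[by_cond["treated"]].to_numpy(dtype=float)
        control = m[by_cond["control"]].to_numpy(dtype=float)
        cols[patient] = np.log2((treated + pseudocount) / (control + pseudocount))
    out = pd.DataFrame(cols, index=m.index)
    out.index.name = "feature_id"
    out.columns.name = "pair"
    return out


@dataclass(frozen=True)
class ConsistencyCriterion:
    """Parameters of a per-pair fold-change consistency rule.

    ``require_pair_threshold`` demands |log2FC| > ``fc_threshold`` in at
    least ``ceil(min_fraction * n_pairs)`` pairs; ``require_all_same_sign``
    demands a common sign in every pair; ``require_mean_threshold`` demands
    |mean log2FC| > ``fc_threshold``.  At least one of the pair-threshold and
    mean requirements must be active.
    """

    fc_threshold: float = 0.5
    min_fraction: float = 0.5
    require_all_same_sign: bool = False
    require_mean_threshold: bool = False
    require_pair_threshold: bool = True

    def __post_init__(self):
        if self.fc_threshold <= 0:
            raise InputFormatError("fc_threshold must be > 0")
        if not 0 < self.min_fraction <= 1:
            raise InputFormatError("min_fraction must be in (0, 1]")
        if not (self.require_pair_threshold or self.require_mean_threshold):
            raise InputFormatError("criterion must use a pair or mean threshold")


STANDARD_CRITERION = ConsistencyCriterion()
STRINGENT_CRITERION = ConsistencyCriterion(require_all_same_sign=True)
PROTEIN_CRITERION = ConsistencyCriterion(
    min_fraction=1.0,
    require_all_same_sign=True,
    require_mean_threshold=True,
    require_pair_threshold=False,
)


@dataclass
class ConsistencyCallResult:
    """Per-feature direction calls plus supporting summaries."""

    table: pd.DataFrame  # columns: direction, n_pairs_passing, mean_log2fc
    conflicts: list = field(default_factory=list)  # features passing both rules
    criterion: ConsistencyCriterion = STANDARD_CRITERION

    @property
    def up_features(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "up"]

    @property
    def down_features(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "down"]

    @property
    def called_features(self) -> pd.Index:
        return self.table.index[self.table["direction"] != "not_called"]


def call_consistency(
    t: pd.DataFrame, criterion: ConsistencyCriterion = STANDARD_CRITERION
) -> ConsistencyCallResult:
    """Apply a consistency criterion to a feature-by-pair log2FC table.

    A feature satisfying both the up and down conditions (possible with
    mixed large effects and a permissive ``min_fraction``) is reported as
    ``not_called`` and listed in ``conflicts``.
    """
    if t.shape[1] < 1 or t.shape[0] < 1:
        raise ComputationError("empty fold-change table")
    X = t.to_numpy(dtype=float)
    n_pairs = X.shape[1]
    need = int(math.ceil(criterion.min_fraction * n_pairs - 1e-9))
    thr = criterion.fc_threshold

    up_n = (X > thr).sum(axis=1)
    dn_n = (X < -thr).sum(axis=1)
    mean = X.mean(axis=1)

    up_ok = np.ones(X.shape[0], dtype=bool)
    dn_ok = np.ones(X.shape[0], dtype=bool)
    if criterion.require_pair_threshold:
        up_ok &= up_n >= need
        dn_ok &= dn_n >= need
    if criterion.require_all_same_sign:
        up_ok &= (X > 0).all(axis=1)
        dn_ok &= (X < 0).all(axis=1)
    if criterion.require_mean_threshold:
        up_ok &= mean > thr
        dn_ok &= mean < -thr

    conflict = up_ok & dn_ok
    direction = np.where(up_ok & ~conflict, "up",
                         np.where(dn_ok & ~conflict, "down", "not_called"))
    n_passing = np.where(direction == "up", up_n,
                         np.where(direction == "down", dn_n, np.maximum(up_n, dn_n)))
    table = pd.DataFrame(
        {"direction": direction, "n_pairs_passing": n_passing, "mean_log2fc": mean},
        index=t.index,
    )
    return ConsistencyCallResult(
        table=table, conflicts=list(t.index[conflict]), criterion=criterion
    )


def call_protein_consistency(t: pd.DataFrame) -> ConsistencyCallResult:
    """Protein-level rule: mean |log2FC| above threshold, same sign in all pairs."""
    return call_consistency(t, PROTEIN_CRITERION)


# ---------------------------------------------------------------------------
# proteomics normalization and aggregation
# ---------------------------------------------------------------------------

def median_scale_peptides(m: pd.DataFrame) -> pd.DataFrame:
    """Median scaling of peptide intensities; zeros are treated as missing.

    Each sample is multiplied by (median of per-sample medians) / (its own
    median of observed intensities) so that all per-sample medians of
    observed peptides agree afterward.
    """
    X = m.to_numpy(dtype=float).copy()
    X[X == 0] = np.nan
    observed = np.isfinite(X)
    if (~observed.any(axis=0)).any():
        bad = m.columns[~observed.any(axis=0)].tolist()
        raise ComputationError(f"samples with no observed peptides: {bad}")
    medians = np.nanmedian(X, axis=0)
    target = np.median(medians)
    factors = target / medians
    out = m.to_numpy(dtype=float) * factors
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def sum_peptides_to_proteins(m: pd.DataFrame, mapping) -> pd.DataFrame:
    """Sum normalized peptide intensities into protein-level quantities.

    ``mapping`` maps peptide id to protein id (dict, Series, or a two-column
    DataFrame).  Peptides mapped to more than one protein raise an error —
    shared peptides must be resolved upstream.  Proteins with no observed
    peptide anywhere are absent from the output.
    """
    if isinstance(mapping, pd.DataFrame):
        pairs = mapping.iloc[:, :2].drop_duplicates()
        dup = pairs.iloc[:, 0].duplicated()
        if dup.any():
            raise InputFormatError(
                f"peptides mapped to multiple proteins: {pairs.iloc[:, 0][dup].tolist()}"
            )
        mapping = dict(zip(pairs.iloc[:, 0], pairs.iloc[:, 1]))
    elif isinstance(mapping, pd.Series):
        mapping = mapping.to_dict()
    unmapped = [p for p in m.index if p not in mapping]
    if unmapped:
        raise InputFormatError(f"peptides without a protein mapping: {unmapped[:5]}")
    protein = pd.Index([mapping[p] for p in m.index], name="protein_id")
    observed = m.notna() & (m != 0)
    filled = m.where(observed, 0.0)
    sums = filled.groupby(protein).sum()
    seen = observed.groupby(protein).any().any(axis=1)
    return sums.loc[seen[seen].index]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up false-discovery-rate adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InputFormatError("p-values must be a non-empty 1-d array")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise InputFormatError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# cross-group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GenotypeComparison:
    """Mean per-pair fold changes of two genotype groups over their DE genes."""

    scatter: pd.DataFrame  # feature: mean_a, mean_b, called_in {A, B, both}
    common_features: list  # called in both groups with the same direction
    pearson_r: float
    pearson_p: float
    slope_a: tuple  # (slope, ci_low, ci_high) of mean_b on mean_a, group A genes
    slope_b: tuple


def _slope_ci(x: np.ndarray, y: np.ndarray) -> tuple:
    res = stats.linregress(x, y)
    if len(x) > 2 and np.isfinite(res.stderr):
        tcrit = stats.t.ppf(0.975, len(x) - 2)
        return (res.slope, res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return (res.slope, float("nan"), float("nan"))


def compare_genotype_effects(
    table_a: pd.DataFrame,
    calls_a: ConsistencyCallResult,
    table_b: pd.DataFrame,
    calls_b: ConsistencyCallResult,
) -> GenotypeComparison:
    """Compare the effect amplitudes two genotype groups assign to their DE genes.

    For every gene called in either group the per-pair mean log2FC is
    computed in both groups; the Pearson correlation is taken over the union
    and a least-squares slope (group B mean on group A mean) is fitted within
    each group's own called set.  ``common_features`` are genes called in
    both groups with the same direction.
    """
    shared = table_a.index.intersection(table_b.index)
    set_a = [f for f in calls_a.called_features if f in shared]
    set_b = [f for f in calls_b.called_features if f in shared]
    if len(set_a) < 3 or len(set_b) < 3:
        raise ComputationError("each group needs at least 3 called features")
    union = pd.Index(sorted(set(set_a) | set(set_b)))
    mean_a = table_a.loc[union].mean(axis=1)
    mean_b = table_b.loc[union].mean(axis=1)
    called_in = pd.Series(
        ["both" if (f in set(set_a) and f in set(set_b)) else ("A" if f in set(set_a) else "B")
         for f in union],
        index=union,
    )
    scatter = pd.DataFrame({"mean_a": mean_a, "mean_b": mean_b, "called_in": called_in})

    r, p = stats.pearsonr(mean_a.to_numpy(), mean_b.to_numpy())
    slope_a = _slope_ci(mean_a.loc[set_a].to_numpy(), mean_b.loc[set_a].to_numpy())
    slope_b = _slope_ci(mean_a.loc[set_b].to_numpy(), mean_b.loc[set_b].to_numpy())

    dir_a = calls_a.table.loc[set_a, "direction"]
    dir_b = calls_b.table["direction"]
    common = [f for f in set_a if f in set(set_b) and dir_a[f] == dir_b[f]]
    return GenotypeComparison(
        scatter=scatter,
        common_features=common,
        pearson_r=float(r),
        pearson_p=float(p),
        slope_a=slope_a,
        slope_b=slope_b,
    )


def top_variable_correlation(
    m: pd.DataFrame, sheet: pd.DataFrame, n_top: int = 500, return_selected: bool = False
):
    """Per-patient correlation of the two constructs over top-variable genes.

    Genes are ranked by their standard deviation across *all* samples (ties
    at the boundary broken by feature id) and the top ``n_top`` retained; for
    every patient the Pearson correlation between that patient's two
    non-control samples over those genes is returned.
    """
    if n_top > m.shape[0]:
        raise ComputationError(f"n_top={n_top} exceeds the {m.shape[0]} available features")
    sd = m.std(axis=1, ddof=1).to_numpy()
    order = np.lexsort((m.index.astype(str), -sd))
    top = m.index[order[:n_top]]

    treated = sheet[sheet["condition"] != "control"]
    out = {}
    for patient, grp in treated.groupby("patient", sort=True):
        if len(grp) != 2:
            raise InputFormatError(
                f"patient {patient} must have exactly two construct samples, found {len(grp)}"
            )
        a, b = grp["sample"].tolist()
        r, _ = stats.pearsonr(m.loc[top, a].to_numpy(), m.loc[top, b].to_numpy())
        out[patient] = float(r)
    result = pd.Series(out, name="pearson_r")
    return (result, top) if return_selected else result
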