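"""H3K27ac peak-signature cascade.

Per-sample peak calls are merged into consensus peaks, peaks present in too
few samples are dropped, counts over the survivors are variance-stabilized,
and a PCA over samples is inspected for the component that separates the
two members of each isogenic pair.  Peaks whose cross-sample profile
correlates with that component's sample scores (two-sided t test on the
Pearson r, p below alpha) form the signature, which is then intersected with
active chromatin states and annotated to genes whose span is extended 1.5 kb
upstream to cover the promoter.  A paired subtracted-signal track (mean of
treated minus control per base pair) supports browser-style inspection.

All coordinates are 0-based half-open.  Interval containers are plain
pandas DataFrames with ``chrom``/``start``/``end`` columns; consensus peaks
additionally carry ``support`` and are indexed by a ``chrom:start-end`` id.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, InputFormatError

logger = logging.getLogger("isopair.chromatin")

__all__ = [
    "PCAResult",
    "merge_intervals",
    "build_consensus",
    "filter_by_support",
    "vst_transform",
    "pca_over_samples",
    "condition_component_scan",
    "select_pc_correlated_peaks",
    "filter_by_chromatin_state",
    "annotate_to_genes",
    "paired_subtracted_signal",
    "peak_ids_to_intervals",
]

_PEAK_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def _validate_intervals(df: pd.DataFrame, context: str = "intervals") -> None:
    if not len(df):
        return
    bad = df[(df["start"] < 0) | (df["end"] <= df["start"])]
    if len(bad):
        row = bad.iloc[0]
        raise InputFormatError(
            f"{context}: malformed interval {row['chrom']}:{row['start']}-{row['end']}"
        )


def merge_intervals(df: pd.DataFrame, book_ended: bool = True) -> pd.DataFrame:
    """Merge overlapping (and, by default, book-ended) intervals per chromosome."""
    _validate_intervals(df)
    if not len(df):
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            joined = s <= cur_e if book_ended else s < cur_e
            if joined:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _overlaps_any(merged: pd.DataFrame, query: pd.DataFrame) -> np.ndarray:
    """For each query interval, whether it overlaps >= 1 bp of the merged set.

    ``merged`` must be sorted and non-overlapping within each chromosome.
    """
    hit = np.zeros(len(query), dtype=bool)
    by_chrom = {c: g for c, g in merged.groupby("chrom", sort=False)}
    for chrom, grp in query.groupby("chrom", sort=False):
        ref = by_chrom.get(chrom)
        if ref is None or not len(ref):
            continue
        starts = ref["start"].to_numpy()
        ends = ref["end"].to_numpy()
        qs = grp["start"].to_numpy()
        qe = grp["end"].to_numpy()
        # first reference interval whose end is beyond the query start
        idx = np.searchsorted(ends, qs, side="right")
        ok = idx < len(starts)
        ok[ok] = starts[idx[ok]] < qe[ok]
        hit[query.index.get_indexer(grp.index)] = ok
    return hit


def build_consensus(per_sample_peaks: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-sample peak calls into consensus peaks with support counts.

    Support is the number of distinct samples contributing at least 1 bp of
    overlap to a consensus peak.  The result is sorted, non-overlapping, and
    indexed by a ``chrom:start-end`` peak id.
    """
    if not per_sample_peaks:
        raise InputFormatError("no per-sample peak sets provided")
    merged_per_sample = {}
    for sample, df in per_sample_peaks.items():
        _validate_intervals(df, context=f"sample {sample}")
        merged_per_sample[sample] = merge_intervals(df)
    union = merge_intervals(pd.concat(merged_per_sample.values(), ignore_index=True))
    union = union.reset_index(drop=True)
    support = np.zeros(len(union), dtype=int)
    for sample, merged in merged_per_sample.items():
        support += _overlaps_any(merged, union).astype(int)
    union["support"] = support
    union.index = pd.Index(
        [f"{c}:{s}-{e}" for c, s, e in union[["chrom", "start", "end"]].itertuples(index=False)],
        name="peak_id",
    )
    return union


def filter_by_support(consensus: pd.DataFrame, min_samples: int = 2) -> pd.DataFrame:
    """Keep consensus peaks present in at least ``min_samples`` samples."""
    if "support" not in consensus.columns:
        raise InputFormatError("consensus peaks lack a 'support' column")
    return consensus[consensus["support"] >= min_samples].copy()


def peak_ids_to_intervals(ids: Sequence[str]) -> pd.DataFrame:
    """Parse ``chrom:start-end`` peak ids back into an interval frame."""
    rows = []
    for pid in ids:
        match = _PEAK_ID_RE.match(str(pid))
        if match is None:
            raise InputFormatError(f"peak id {pid!r} is not of the form chrom:start-end")
        rows.append((match["chrom"], int(match["start"]), int(match["end"])))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"], index=pd.Index(ids, name="peak_id"))
    return out


# ---------------------------------------------------------------------------
# variance stabilization and PCA
# ---------------------------------------------------------------------------

def vst_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing transform: median-of-ratios size factors, then
    log2(count / size_factor + 1).

    The size factor of a sample is the median across all-positive peaks of
    the ratio of its count to the geometric-mean reference; a pure depth
    replicate therefore maps onto a near-identical column.  When no peak has
    all-positive counts the transform falls back to library-size factors and
    logs a warning.
    """
    if counts.shape[1] < 2:
        raise ComputationError("vst_transform needs at least two samples")
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise InputFormatError("counts must be non-negative")
    all_pos = (X > 0).all(axis=1)
    if all_pos.any():
        logX = np.log(X[all_pos])
        log_ref = logX.mean(axis=1)
        sf = np.exp(np.median(logX - log_ref[:, None], axis=0))
    else:
        logger.warning("vst_transform: no peak with all-positive counts; "
                       "falling back to library-size factors")
        lib = X.sum(axis=0)
        if (lib <= 0).any():
            raise ComputationError("a sample has zero total counts")
        sf = lib / np.exp(np.mean(np.log(lib)))
    vst = np.log2(X / sf + 1.0)
    return pd.DataFrame(vst, index=counts.index, columns=counts.columns)


@dataclass
class PCAResult:
    """Principal components of a peak matrix, samples as observations."""

    sample_scores: pd.DataFrame  # samples x components
    peak_loadings: pd.DataFrame  # peaks x components
    explained_fraction: pd.Series  # per component

    @property
    def n_components(self) -> int:
        return self.sample_scores.shape[1]


def pca_over_samples(m: pd.DataFrame) -> PCAResult:
    """PCA with samples as observations and peaks as variables.

    Peaks are centered, not scaled.  Components are ordered by decreasing
    explained fraction and the sign convention makes the largest-magnitude
    loading of each component positive.
    """
    if m.shape[1] < 3:
        raise ComputationError("pca_over_samples needs at least 3 samples")
    X = m.to_numpy(dtype=float).T  # samples x peaks
    Xc = X - X.mean(axis=0)
    total = float((Xc ** 2).sum())
    if total <= 0:
        raise ComputationError("constant matrix: zero total variance")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(S.size):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * S
    names = [f"PC{k + 1}" for k in range(S.size)]
    return PCAResult(
        sample_scores=pd.DataFrame(scores, index=m.columns, columns=names),
        peak_loadings=pd.DataFrame(Vt.T, index=m.index, columns=names),
        explained_fraction=pd.Series(S ** 2 / (S ** 2).sum(), index=names,
                                     name="explained_fraction"),
    )


def condition_component_scan(pca: PCAResult, condition: Sequence) -> pd.Series:
    """Correlation of each component's sample scores with a condition indicator.

    A plumbing helper to guide the (explicit, user-made) choice of component:
    returns per-component Pearson r against a binary condition vector aligned
    with the score rows.
    """
    labels = np.asarray(condition)
    if labels.dtype.kind in "OUS":
        uniq = np.unique(labels)
        if uniq.size != 2:
            raise InputFormatError("condition indicator must be binary")
        labels = (labels == uniq[1]).astype(float)
    labels = labels.astype(float)
    out = {}
    for name in pca.sample_scores.columns:
        scores = pca.sample_scores[name].to_numpy()
        if np.std(scores) == 0 or np.std(labels) == 0:
            out[name] = 0.0
        else:
            out[name] = float(np.corrcoef(scores, labels)[0, 1])
    return pd.Series(out, name="condition_correlation")


def select_pc_correlated_peaks(
    m: pd.DataFrame,
    pca: PCAResult | None = None,
    component: int | None = None,
    alpha: float = 0.05,
    peaks: pd.DataFrame | None = None,
    scores: Sequence | None = None,
) -> pd.DataFrame:
    """Peaks whose cross-sample profile correlates with a component's scores.

    For every peak the Pearson r against the chosen component's sample
    scores (1-based ``component``) is converted to a two-sided p-value via
    ``t = r * sqrt((n-2)/(1-r^2))`` with n-2 degrees of freedom; peaks with
    p < ``alpha`` are retained, both signs.  Zero-variance peaks are
    excluded (their count is logged).  ``scores`` may be given directly in
    place of ``pca``/``component``.  Returns the retained peaks' intervals
    (from ``peaks`` or parsed from the matrix index) with ``pearson_r`` and
    ``p_value`` columns.
    """
    if scores is None:
        if pca is None or component is None:
            raise InputFormatError("provide either pca+component or explicit scores")
        if not 1 <= component <= pca.n_components:
            raise InputFormatError(f"component {component} out of range 1..{pca.n_components}")
        scores = pca.sample_scores.iloc[:, component - 1].to_numpy()
    sc = np.asarray(scores, dtype=float)
    n = m.shape[1]
    if sc.size != n:
        raise InputFormatError("score vector length does not match the sample count")
    if n < 4:
        raise ComputationError("need at least 4 samples for a correlation p-value")

    X = m.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    scc = sc - sc.mean()
    peak_norm = np.sqrt((Xc ** 2).sum(axis=1))
    score_norm = float(np.sqrt((scc ** 2).sum()))
    if score_norm == 0:
        raise ComputationError("component scores are constant")
    defined = peak_norm > 0
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("select_pc_correlated_peaks: excluded %d zero-variance peaks", n_dropped)
    r = np.zeros(X.shape[0])
    r[defined] = (Xc[defined] @ scc) / (peak_norm[defined] * score_norm)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    keep = defined & (p < alpha)

    if peaks is None:
        peaks = peak_ids_to_intervals(m.index)
    out = peaks.loc[m.index[keep], ["chrom", "start", "end"]].copy()
    out["pearson_r"] = r[keep]
    out["p_value"] = p[keep]
    return out


# ---------------------------------------------------------------------------
# chromatin-state and gene filters
# ---------------------------------------------------------------------------

def filter_by_chromatin_state(
    signature: pd.DataFrame,
    states: pd.DataFrame,
    active_map: Mapping[str, bool],
) -> pd.DataFrame:
    """Remove signature peaks that do not touch an active chromatin state.

    ``states`` carries ``chrom``/``start``/``end``/``state``; ``active_map``
    must cover every label present (unknown labels raise).  Chromosomes with
    no state coverage are treated as inactive and logged.
    """
    _validate_intervals(states, context="chromatin states")
    unknown = sorted(set(states["state"]) - set(active_map))
    if unknown:
        raise InputFormatError(f"chromatin states without an activity flag: {unknown}")
    active = states[states["state"].map(active_map)]
    merged = merge_intervals(active[["chrom", "start", "end"]])
    uncovered = sorted(set(signature["chrom"]) - set(states["chrom"]))
    if uncovered:
        logger.info("filter_by_chromatin_state: chromosomes without state coverage "
                    "treated as inactive: %s", uncovered)
    sig = signature.reset_index()
    keep = _overlaps_any(merged, sig)
    return signature[keep].copy()


def annotate_to_genes(
    signature: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_extension: int = 1500,
) -> pd.DataFrame:
    """Annotate peaks to promoter-extended genes; drop peaks hitting none.

    Each gene interval is extended on its 5' side (start - extension for
    ``+`` strand, end + extension for ``-``, clamped at zero).  A peak
    overlapping several extended genes is annotated to the one with the
    largest overlap, ties broken by gene id.
    """
    _validate_intervals(genes, context="gene models")
    if not set(genes["strand"]) <= {"+", "-"}:
        raise InputFormatError("gene strand must be '+' or '-'")
    ext = genes.copy()
    plus = ext["strand"] == "+"
    ext.loc[plus, "start"] = (ext.loc[plus, "start"] - promoter_extension).clip(lower=0)
    ext.loc[~plus, "end"] = ext.loc[~plus, "end"] + promoter_extension

    annotated = []
    genes_by_chrom = {c: g for c, g in ext.groupby("chrom", sort=False)}
    for pid, row in signature.iterrows():
        grp = genes_by_chrom.get(row["chrom"])
        if grp is None:
            continue
        ov = np.minimum(grp["end"].to_numpy(), row["end"]) - np.maximum(
            grp["start"].to_numpy(), row["start"]
        )
        hit = ov > 0
        if not hit.any():
            continue
        cand = pd.DataFrame(
            {"gene_id": grp["gene_id"].to_numpy()[hit], "overlap": ov[hit]}
        ).sort_values(["overlap", "gene_id"], ascending=[False, True])
        annotated.append((pid, cand.iloc[0]["gene_id"]))
    keep_ids = [pid for pid, _ in annotated]
    out = signature.loc[keep_ids].copy()
    out["annotated_gene"] = [g for _, g in annotated]
    return out


# ---------------------------------------------------------------------------
# paired subtracted signal
# ---------------------------------------------------------------------------

def _track_by_chrom(track: pd.DataFrame, context: str) -> dict:
    _validate_intervals(track, context=context)
    out = {}
    for chrom, grp in track.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise InputFormatError(f"{context}: overlapping runs on {chrom}")
        out[chrom] = (starts, ends, grp["value"].to_numpy(dtype=float))
    return out


def _segment_values(chrom_track, bounds: np.ndarray) -> np.ndarray:
    """Value of a run-length track on each segment between consecutive bounds."""
    seg_starts = bounds[:-1]
    if chrom_track is None:
        return np.zeros(seg_starts.size)
    starts, ends, values = chrom_track
    idx = np.searchsorted(starts, seg_starts, side="right") - 1
    vals = np.zeros(seg_starts.size)
    inside = idx >= 0
    inside[inside] &= ends[idx[inside]] > seg_starts[inside]
    vals[inside] = values[idx[inside]]
    return vals


def paired_subtracted_signal(
    pairs: Sequence[tuple[pd.DataFrame, pd.DataFrame]],
    chroms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean per-base-pair (treated - control) signal across pairs.

    Tracks are bedGraph frames; bases not covered by a run read as zero.
    The result is exact at 1-bp resolution, run-length merged, with all-zero
    runs suppressed.  When ``chroms`` is given, any track naming a
    chromosome outside it raises an error listing the offenders.
    """
    if not pairs:
        raise InputFormatError("no sample pairs provided")
    parsed = []
    seen = set()
    for i, (treated, control) in enumerate(pairs):
        t = _track_by_chrom(treated, context=f"pair {i} treated")
        c = _track_by_chrom(control, context=f"pair {i} control")
        parsed.append((t, c))
        seen |= set(t) | set(c)
    if chroms is not None:
        extra = sorted(seen - set(chroms))
        if extra:
            raise InputFormatError(f"tracks name chromosomes outside the universe: {extra}")
        universe = [c for c in chroms if c in seen]
    else:
        universe = sorted(seen)

    rows = []
    n_pairs = len(parsed)
    for chrom in universe:
        bounds = np.unique(
            np.concatenate(
                [np.concatenate([trk[chrom][0], trk[chrom][1]])
                 for t, c in parsed for trk in (t, c) if chrom in trk]
            )
        )
        if bounds.size < 2:
            continue
        total = np.zeros(bounds.size - 1)
        for t, c in parsed:
            total += _segment_values(t.get(chrom), bounds)
            total -= _segment_values(c.get(chrom), bounds)
        mean = total / n_pairs
        # run-length merge adjacent equal values, suppress zeros
        cur_s, cur_v = bounds[0], mean[0]
        for k in range(1, mean.size):
            if mean[k] != cur_v:
                if cur_v != 0.0:
                    rows.append((chrom, int(cur_s), int(bounds[k]), float(cur_v)))
                cur_s, cur_v = bounds[k], mean[k]
        if cur_v != 0.0:
            rows.append((chrom, int(cur_s), int(bounds[-1]), float(cur_v)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
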