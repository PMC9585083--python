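"""Synthetic data generators for paired isogenic tumor B-cell experiments.

Every generator emulates the statistical structure the downstream analyses
assume rather than any sequence-level detail:

* ``simulate_paired_counts`` — negative-binomial count matrices for a paired
  design (one control and one construct-transduced sample per patient) with a
  log2-additive mean model: feature baseline + per-patient/per-feature offset
  + condition effect.  The patient offsets are drawn independently per
  feature, so the two samples of a patient share a feature profile and the
  leading principal components of the resulting matrix are patient-specific,
  while a small consistent condition effect surfaces in a minor component.
* ``simulate_peak_experiment`` — the same count model laid out on genomic
  intervals, plus per-sample peak-presence calls and per-sample signal
  tracks, so the consensus/support/VST/PCA cascade is exercisable end to end.
* ``simulate_cohort`` — a right-censored survival cohort with exponential
  event times in which the (high NOTCH-score, low CIITA) group carries an
  elevated hazard and mutations are enriched among CIITA-low patients at a
  configurable odds ratio.

All randomness in one call flows from a single ``numpy`` generator seeded
from the config; identical configs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "SurvivalSimConfig",
    "SyntheticTruth",
    "PeakExperiment",
    "simulate_paired_counts",
    "simulate_peak_experiment",
    "simulate_annotation",
    "simulate_cohort",
    "default_rnaseq_config",
    "default_chip_config",
]

_CHROMS = ("chr1", "chr2", "chr3", "chr4")
_PEAK_WIDTH = 600
_PEAK_SPACING = 2000


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the paired negative-binomial count generator.

    Parameters are on the log2 scale where noted.  ``dispersion`` is the
    negative-binomial shape (size) parameter: variance = mu + mu^2/size, so
    larger values approach Poisson noise.  Library sizes are drawn
    log-uniformly within ``lib_size_range`` so normalization stages are
    exercised non-trivially.
    """

    n_patients: int = 6
    n_features: int = 2000
    frac_affected: float = 0.05
    effect_log2fc_mean: float = 1.0
    effect_log2fc_sd: float = 0.0
    patient_effect_sd: float = 0.0  # log2 units, per patient and feature
    dispersion: float = 10.0
    lib_size_range: tuple[float, float] = (5e5, 2e6)
    baseline_log2_mean: float = -12.0
    baseline_log2_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if int(self.n_patients) != self.n_patients or self.n_patients < 2:
            raise ConfigurationError("n_patients must be an integer >= 2")
        if int(self.n_features) != self.n_features or self.n_features < 1:
            raise ConfigurationError("n_features must be a positive integer")
        if not 0.0 <= self.frac_affected <= 1.0:
            raise ConfigurationError("frac_affected must be in [0, 1]")
        if self.effect_log2fc_sd < 0 or self.patient_effect_sd < 0:
            raise ConfigurationError("effect and patient sds must be >= 0")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("lib_size_range must be positive and ordered")
        if self.baseline_log2_sd < 0:
            raise ConfigurationError("baseline_log2_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth of a simulated paired experiment."""

    affected_features: frozenset
    true_log2fc: pd.Series  # indexed by feature id; 0 for unaffected
    patient_offsets: pd.DataFrame  # patients x features, log2 units

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "true_log2fc": self.true_log2fc,
                "affected": [f in self.affected_features for f in self.true_log2fc.index],
            }
        ).rename_axis("feature_id")


class PeakExperiment(NamedTuple):
    """Outputs of ``simulate_peak_experiment``."""

    peaks: dict  # sample id -> BED DataFrame (chrom, start, end)
    signals: dict  # sample id -> bedGraph DataFrame (chrom, start, end, value)
    counts: pd.DataFrame  # peak id x sample
    samples: pd.DataFrame  # sample sheet
    truth: SyntheticTruth
    intervals: pd.DataFrame  # peak id -> (chrom, start, end)


def default_rnaseq_config(seed: int = 0) -> SimulationConfig:
    """Paired transcriptome conditions: 6 patients, 2000 genes, 5% of genes
    shifted by one log2 unit, moderate counting noise (size 10)."""
    return SimulationConfig(seed=seed)


def default_chip_config(seed: int = 0) -> SimulationConfig:
    """Paired acetylation-peak conditions: 5 patients (10 samples), 2000
    peaks, patient-dominant variance (per-patient peak profiles with sd 0.4
    log2) over low counting noise, and a consistent |log2FC| = 1.5 shift on
    the planted fraction.  Chosen so that, as in real paired chromatin data,
    the leading principal components are patient-specific and the condition
    surfaces in a minor component carrying a few percent of the variance."""
    return SimulationConfig(
        n_patients=5,
        n_features=2000,
        frac_affected=0.02,
        effect_log2fc_mean=1.5,
        effect_log2fc_sd=0.0,
        patient_effect_sd=0.4,
        dispersion=100.0,
        seed=seed,
    )


def _patient_ids(n: int) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(n)]


def _genotypes(n: int) -> list[str]:
    # mirrors the roughly even tri12/del13q split of the emulated design
    n_tri = math.ceil(n / 2)
    return ["tri12"] * n_tri + ["del13q"] * (n - n_tri)


def _sample_sheet(patients: list[str]) -> pd.DataFrame:
    genos = _genotypes(len(patients))
    rows = []
    for pat, gt in zip(patients, genos):
        rows.append((f"{pat}_control", pat, "control", gt))
        rows.append((f"{pat}_treated", pat, "treated", gt))
    return pd.DataFrame(rows, columns=["sample", "patient", "condition", "genotype"])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # gamma-Poisson mixture; robust for very large shape (Poisson limit)
    if dispersion >= 1e9:
        return rng.poisson(mean)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def _simulate_counts(
    config: SimulationConfig,
    rng: np.random.Generator,
    feature_ids: list[str],
    signed_effects: bool,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    n_feat = int(config.n_features)
    n_pat = int(config.n_patients)
    patients = _patient_ids(n_pat)
    sheet = _sample_sheet(patients)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_feat)
    n_affected = int(round(config.frac_affected * n_feat))
    affected_idx = np.sort(rng.choice(n_feat, size=n_affected, replace=False))
    effects = np.zeros(n_feat)
    if n_affected:
        magnitude = rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd, n_affected)
        if signed_effects:
            magnitude = magnitude * rng.choice([-1.0, 1.0], size=n_affected)
        effects[affected_idx] = magnitude

    offsets = rng.normal(0.0, config.patient_effect_sd, size=(n_pat, n_feat))
    lo, hi = config.lib_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=2 * n_pat))

    counts = np.empty((n_feat, 2 * n_pat), dtype=np.int64)
    for j, (_, row) in enumerate(sheet.iterrows()):
        p = patients.index(row["patient"])
        cond = 1.0 if row["condition"] == "treated" else 0.0
        mu = lib[j] * np.exp2(baseline + offsets[p] + cond * effects)
        counts[:, j] = _nb_draw(rng, mu, config.dispersion)

    counts_df = pd.DataFrame(counts, index=feature_ids, columns=list(sheet["sample"]))
    counts_df.index.name = "feature_id"
    truth = SyntheticTruth(
        affected_features=frozenset(feature_ids[i] for i in affected_idx),
        true_log2fc=pd.Series(effects, index=feature_ids, name="true_log2fc"),
        patient_offsets=pd.DataFrame(offsets, index=patients, columns=feature_ids),
    )
    return counts_df, sheet, truth


def simulate_paired_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a paired feature-by-sample count matrix.

    Returns ``(counts, sample_sheet, truth)``.  Counts are negative binomial
    with mean ``lib_size * 2**(baseline + patient_offset + condition *
    true_log2fc)``; every patient contributes exactly one control and one
    treated sample.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_features)))
    ids = [f"gene{i + 1:0{width}d}" for i in range(int(config.n_features))]
    return _simulate_counts(config, rng, ids, signed_effects=False)


def _peak_intervals(n_features: int) -> pd.DataFrame:
    per_chrom = math.ceil(n_features / len(_CHROMS))
    rows = []
    for i in range(n_features):
        chrom = _CHROMS[i // per_chrom]
        rank = i % per_chrom
        start = 1000 + rank * _PEAK_SPACING
        rows.append((chrom, start, start + _PEAK_WIDTH))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df.index = [f"{c}:{s}-{e}" for c, s, e in df.itertuples(index=False)]
    df.index.name = "peak_id"
    return df


def simulate_peak_experiment(
    config: SimulationConfig, pc_effect_frac: float = 0.02
) -> PeakExperiment:
    """Simulate a paired peak experiment (counts, presence calls, signal).

    ``pc_effect_frac`` is the fraction of peaks carrying the planted
    condition effect; it replaces ``config.frac_affected`` for this call.
    Planted peaks shift by the same signed log2 amount in every pair, while
    per-patient peak profiles (``patient_effect_sd`` > 0 required) dominate
    the overall variance.  Peak presence per sample is Bernoulli with
    probability increasing in that sample's count, so planted and most
    background peaks are present in at least two samples.  Signal tracks are
    per-bp constant over each peak at count/width, consistent with counts.
    """
    config.validate()
    if not 0.0 <= pc_effect_frac < 1.0:
        raise ConfigurationError("pc_effect_frac must be in [0, 1)")
    if config.patient_effect_sd <= 0:
        raise ConfigurationError(
            "simulate_peak_experiment requires patient_effect_sd > 0 "
            "(patient variance must dominate the condition effect)"
        )
    cfg = replace(config, frac_affected=pc_effect_frac)
    rng = np.random.default_rng(cfg.seed)
    intervals = _peak_intervals(int(cfg.n_features))
    counts, sheet, truth = _simulate_counts(cfg, rng, list(intervals.index), signed_effects=True)

    # presence probability saturates with abundance
    values = counts.values
    positive = values[values > 0]
    k0 = 0.05 * max(1.0, float(np.median(positive)) if positive.size else 1.0)
    p_present = values / (values + k0)
    present = rng.random(values.shape) < p_present

    peaks: dict[str, pd.DataFrame] = {}
    signals: dict[str, pd.DataFrame] = {}
    widths = (intervals["end"] - intervals["start"]).to_numpy()
    for j, sample in enumerate(counts.columns):
        mask = present[:, j]
        peaks[sample] = intervals.loc[mask, ["chrom", "start", "end"]].reset_index(drop=True)
        nz = values[:, j] > 0
        sig = intervals.loc[nz, ["chrom", "start", "end"]].copy()
        sig["value"] = values[nz, j] / widths[nz]
        signals[sample] = sig.reset_index(drop=True)

    return PeakExperiment(peaks, signals, counts, sheet, truth, intervals)


def simulate_annotation(
    intervals: pd.DataFrame,
    seed: int = 0,
    frac_peaks_active: float = 0.8,
    frac_peaks_genic: float = 0.75,
) -> tuple[pd.DataFrame, Mapping[str, bool], pd.DataFrame]:
    """Generate a chromatin-state track and gene models around peak intervals.

    Each peak is covered by one state interval (active regulatory state with
    probability ``frac_peaks_active``, inactive otherwise); a subset of peaks
    receives a gene, half overlapping the peak body directly and half
    reachable only through the 1.5 kb upstream promoter extension.  Purely a
    demonstration scaffold so the full signature cascade can run on
    synthetic data.
    """
    rng = np.random.default_rng(seed)
    states = intervals[["chrom", "start", "end"]].copy().reset_index(drop=True)
    states["start"] = (states["start"] - 200).clip(lower=0)
    states["end"] = states["end"] + 200
    active = rng.random(len(states)) < frac_peaks_active
    states["state"] = np.where(active, "active_enhancer", "heterochromatin")
    active_map = {"active_enhancer": True, "heterochromatin": False}

    genic = rng.random(len(intervals)) < frac_peaks_genic
    rows = []
    for i, (pid, row) in enumerate(intervals.iterrows()):
        if not genic[i]:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        # extents stay inside the peak's own neighborhood so one gene cannot
        # annotate the adjacent peak even after the promoter extension
        if rng.random() < 0.5:  # gene body overlaps the peak
            gs = int(row["start"]) + 100
            ge = int(row["end"]) + 800
        elif strand == "+":  # reachable only via the upstream extension
            gs = int(row["end"]) + 800
            ge = gs + 550
        else:
            ge = int(row["start"]) - 800
            gs = max(0, ge - 550)
        rows.append((row["chrom"], gs, ge, f"gene{i + 1:04d}", strand))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])
    return states, active_map, genes


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Knobs of the survival-cohort generator.

    Times are exponential; the risk group (NOTCH score above the cohort
    median and CIITA at or below it) has its hazard multiplied by
    ``hazard_ratio_risk_group``.  CIITA is drawn on a log2-like scale around
    14.9 so the documented fixed threshold is meaningful.
    """

    n_patients: int = 337
    baseline_hazard: float = 0.15  # events per unit time
    hazard_ratio_risk_group: float = 3.0
    censoring_rate: float = 0.08
    mutation_odds_ratio_low_ciita: float = 2.0
    mutation_rate_high_ciita: float = 0.15
    ciita_mean: float = 14.9
    ciita_sd: float = 1.5
    notch_gene_mean: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if int(self.n_patients) != self.n_patients or self.n_patients < 4:
            raise ConfigurationError("n_patients must be an integer >= 4")
        for name in (
            "baseline_hazard",
            "hazard_ratio_risk_group",
            "censoring_rate",
            "mutation_odds_ratio_low_ciita",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0 < self.mutation_rate_high_ciita < 1:
            raise ConfigurationError("mutation_rate_high_ciita must be in (0, 1)")


def simulate_cohort(config: SurvivalSimConfig) -> pd.DataFrame:
    """Simulate a right-censored cohort table.

    Columns: patient, hes1, hes2, hey1, hey2, ciita, notch1_mutated, time,
    event.  Event times are exponential with the risk-group hazard
    multiplier; censoring is an independent exponential; mutation flags are
    drawn so the mutation odds in CIITA-low vs CIITA-high patients equal
    ``mutation_odds_ratio_low_ciita`` in expectation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_patients)
    patients = [f"C{i + 1:04d}" for i in range(n)]

    activation = rng.normal(0.0, 0.8, n)
    genes = {
        g: config.notch_gene_mean + activation + rng.normal(0.0, 0.6, n)
        for g in ("hes1", "hes2", "hey1", "hey2")
    }
    score = np.mean([genes[g] for g in ("hes1", "hes2", "hey1", "hey2")], axis=0)
    ciita = rng.normal(config.ciita_mean, config.ciita_sd, n)

    notch_high = score > np.median(score)
    ciita_high = ciita > np.median(ciita)
    risk = notch_high & ~ciita_high
    hazard = np.where(risk, config.baseline_hazard * config.hazard_ratio_risk_group,
                      config.baseline_hazard)

    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.exponential(1.0 / config.censoring_rate, n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    p_hi = config.mutation_rate_high_ciita
    odds_lo = config.mutation_odds_ratio_low_ciita * p_hi / (1.0 - p_hi)
    p_lo = odds_lo / (1.0 + odds_lo)
    mutated = (rng.random(n) < np.where(ciita_high, p_hi, p_lo)).astype(int)

    return pd.DataFrame(
        {
            "patient": patients,
            "hes1": genes["hes1"],
            "hes2": genes["hes2"],
            "hey1": genes["hey1"],
            "hey2": genes["hey2"],
            "ciita": ciita,
            "notch1_mutated": mutated,
            "time": time,
            "event": event,
        }
    )
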