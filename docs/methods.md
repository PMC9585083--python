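# Methods

## The design being modeled

Each patient contributes an isogenic pair: the same primary tumor B cells
transduced with an empty-vector control or with a constitutively active
construct. Inter-patient differences dominate every molecular readout, so
all inference is within-pair: per-patient fold changes for expression and
protein abundance, and a principal-component decomposition for chromatin,
where patient identity is expected to own the leading components and the
construct effect to surface in a minor one.

## Synthetic generators

### Paired counts (`simulate_paired_counts`)

Counts are negative binomial with mean

```
mu[f, s] = lib_size[s] * 2^( baseline[f] + patient_offset[p(s), f] + cond(s) * log2fc[f] )
```

drawn as a gamma–Poisson mixture (shape = `dispersion`; the Poisson limit is
used above 1e9). Parameters, log2 units unless noted:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 6 | pairs (2 samples each) |
| `n_features` | 2000 | genes or peaks |
| `frac_affected` | 0.05 | fraction with a planted condition effect |
| `effect_log2fc_mean` / `_sd` | 1.0 / 0.0 | planted effect size distribution |
| `patient_effect_sd` | 0.0 | per-(patient, feature) offset sd |
| `dispersion` | 10 | NB shape; larger = closer to Poisson |
| `lib_size_range` | 5e5–2e6 | library sizes, log-uniform |
| `baseline_log2_mean` / `_sd` | −12 / 1.5 | feature abundance spectrum |

Two modeling choices matter. First, **patient offsets are drawn per
(patient, feature)**, not one scalar per patient: a per-patient scalar is a
pure depth effect that any normalization removes, whereas a per-feature
profile shared by the two samples of a patient is what makes the leading
principal components patient-specific. The full offset matrix is recorded in
the planted truth. Second, all randomness in a call flows from one
`numpy.random.Generator` seeded from the config, so identical configs are
bit-identical.

### Peak experiments (`simulate_peak_experiment`)

The same count model laid on non-overlapping intervals (600 bp peaks every
2 kb over four chromosomes). `pc_effect_frac` is the fraction of peaks
carrying the planted effect (it substitutes `frac_affected` for this call);
planted effects have a random sign per peak but the same signed shift in
every pair. Peak *presence* per sample — which the consensus/support filter
consumes — is Bernoulli with probability `count / (count + k)` where `k` is
5% of the median positive count, so abundant peaks are near-certain to be
called and most peaks appear in ≥ 2 of the samples. Signal tracks are
piecewise constant at count/width over each peak, so track arithmetic is
consistent with the count matrix.

The chip defaults (`default_chip_config`: 5 patients, `patient_effect_sd`
0.4, `dispersion` 100, |log2FC| 1.5 on 2% of 2000 peaks) were fixed by a
power analysis of the downstream correlation filter: with 10 samples the
p < 0.05 cut corresponds to |r| > 0.632, so the condition contrast
(amplitude 0.75 across samples) must dominate the per-peak residual sd;
patient variance then deflates the correlation of *background* peaks with
the condition component (their variance is large but orthogonal to it),
which is what gives the filter its precision. Under these conditions the
condition-associated component carries a few percent of total variance —
the minor-component structure the generator is meant to emulate.

### Survival cohorts (`simulate_cohort`)

Four score genes are drawn around a shared per-patient activation factor;
CIITA is Gaussian on a log2-like scale centered at 14.9 (so the documented
fixed threshold is usable). Event times are exponential; patients with
NOTCH score above the cohort median *and* CIITA at or below it have their
hazard multiplied by `hazard_ratio_risk_group` (default 3). Censoring is an
independent exponential. Mutation flags are Bernoulli with the odds in the
CIITA-low group equal to `mutation_odds_ratio_low_ciita` (default 2) times
the CIITA-high odds.

## Analysis stages

### Normalization

*Quantile normalization* maps every sample onto the vector of row means of
the column-sorted matrix; a tied group within a column receives the mean of
the reference values at its tied ranks. This makes the map deterministic and
symmetric but means exact distribution equality holds only for tie-free
columns. *Trimmed-mean scaling* produces residual per-sample factors on top
of library size: the reference is the sample whose 75th-percentile count
fraction is closest to the mean; M (log ratio) and A (average abundance)
values over doubly positive features are trimmed (30% per M tail, 5% per A
tail, rank-based) and the factor is 2 to the precision-weighted mean of the
surviving M values, with the weights the standard binomial variance
approximation. Factors are anchored to geometric mean 1. A pure depth
difference yields unit factors by construction. The DE pipeline applies
quantile normalization first and scaling second; both are switchable.

*Median peptide scaling* treats zeros as missing and equalizes per-sample
medians of observed intensities at the median of medians. Shared peptides
are an error, not fractionally allocated — the aggregation rule is plain
summation and anything else would silently change totals; the
peptide-to-protein map must be resolved upstream.

### Consistency calling

`pairwise_log2fc` computes `log2((treated + c)/(control + c))` per patient
with pseudocount `c = 1` on normalized counts (configurable; the choice only
matters near zero). The criterion engine supports three requirements —
per-pair threshold count, all-pairs sign, mean threshold — combined as:

* standard: `> 0.5` in at least `ceil(n/2)` pairs ("at least half" with an
  odd pair count rounds up, the strictest reading);
* stringent: standard plus a common sign in every pair;
* protein: mean `> 0.5` plus a common sign in every pair (no per-pair
  threshold count — the rule used for three-patient TMT designs).

A feature satisfying both the up and the down conditions (possible with
≥ 4 pairs and mixed large effects) is reported `not_called` and listed in a
conflict set rather than silently dropped. No p-values are attached: these
are threshold rules, and the null behavior is a property of the noise level
(see Limitations).

### Peak signature

Consensus peaks are the base-pair union of per-sample peak calls
(book-ended intervals merge; coordinates are 0-based half-open throughout);
support counts distinct samples contributing ≥ 1 bp. The variance
stabilization is median-of-ratios size factors followed by
`log2(x/sf + 1)` — deliberately not a fitted mean–dispersion transform,
since downstream use is purely relative (PCA and correlations); a
depth-scaled replicate maps onto an identical column, which is the property
the cascade needs. If no peak has all-positive counts the transform falls
back to library-size factors with a logged warning.

PCA treats samples as observations and peaks as variables, centered, not
scaled; components are ordered by explained fraction and signed so the
largest-magnitude loading is positive. The component carrying the construct
effect is chosen explicitly by the user (as in practice it is chosen by
inspection); `condition_component_scan` reports each component's correlation
with the condition indicator as guidance, and the CLI's `component: auto`
takes the argmax. Peak selection computes Pearson r between each peak's
cross-sample profile and the chosen component's sample scores, with a
two-sided p from `t = r sqrt((n-2)/(1-r^2))` on n − 2 df; peaks with
p < alpha are kept, both signs, without multiplicity adjustment (a
Benjamini–Hochberg helper exists but the selection rule is the raw
threshold). Zero-variance peaks are excluded and counted in the log.

State filtering keeps peaks overlapping ≥ 1 bp of an active state; unknown
state labels raise, chromosomes without state coverage are treated inactive
and logged. Gene annotation extends each gene 1.5 kb on its 5′ side
(strand-aware, clamped at zero), keeps peaks overlapping any extended gene,
and annotates to the gene with the largest overlap, ties broken by gene id.

The subtracted-signal operation is exact at 1-bp resolution: per
chromosome, all run boundaries are pooled, each pair contributes
treated − control per segment (absent runs read as zero), the mean over
pairs is run-length merged and zero runs are suppressed.

### Survival

The NOTCH score is the arithmetic mean of HES1, HES2, HEY1, HEY2.
Dichotomization is strictly-greater-than the threshold — values equal to
the threshold (including a cohort median with even n) are *low*; thresholds
resolved from one cohort are recorded so they can be frozen and re-applied
to another. Kaplan–Meier is the product-limit estimator with
censored-at-t subjects still at risk at t. The log-rank test is the
unweighted k-group statistic: observed minus expected event counts at
pooled event times with the full hypergeometric covariance, chi-square on
k − 1 df (singular covariances use a pseudo-inverse; time points with one
subject at risk contribute zero variance). Fisher's exact test sums
hypergeometric probabilities of all tables with the observed margins that
are no more probable than the observed one (with a 1e-7 relative tolerance
against floating-point ties); the odds ratio is ad/bc, infinite when
bc = 0. Time-to-treatment and overall survival share this machinery; the
endpoint is a column, not separate code.

## Numerical and interface conventions

* Single seed per call; no global random state. CLI stages write a manifest
  (version, resolved config, SHA-256 input digests, per-stage record counts,
  timestamps) on success and failure; unknown config keys are rejected
  before any computation. Exit codes: 2 config, 3 input, 4 computation.
* `ceil(min_fraction * n)` is computed with a 1e-9 guard against binary
  representation of fractions like 0.5.
* SD ranking ties at the top-n boundary break by feature id; annotation
  ties break by gene id; both deterministic.
* bedGraph values are written at full precision; reruns with the same
  config and seed are byte-identical.

## What the tests show — and what they cannot

The suite checks the implementations against independent oracles (literal
per-feature re-evaluation for the callers; dense per-base-pair arrays for
the interval engine; eigendecomposition for the PCA; lifelines and
exhaustive enumeration for the survival machinery), calibration under the
null (the correlation filter passes ~5% of peaks at alpha = 0.05 with iid
noise; log-rank p-values are uniform for identical groups), and recovery of
planted effects at the default study conditions. Problem sizes are modest
by design — 2000 features, 5–6 patients, 15–25 replicate seeds, cohorts of
a few hundred — enough for the medians being asserted while keeping the
whole suite under a minute of compute.

Null calibration of the correlation filter is asserted with
`patient_effect_sd = 0` and a fixed contrast vector: with patient-correlated
rows, the t reference distribution for a sample correlation does not apply
(the paired duplication inflates row variance), so the alpha-level statement
is only meaningful for the iid case. With patient structure present the
filter is *conservative* for background peaks — that conservatism is what
the recovery test measures as precision.

The generators emulate the statistical skeleton of real paired experiments —
patient-dominant variance, consistent within-pair shifts, library-size
spread, negative-binomial counting noise, presence/absence peak calls,
right-censored exponential survival — and none of the rest: no sequence
content, no read-level or fragment-level structure, no correlated gene
modules or enhancer–gene topology, no competing risks, and Gaussian
expression for the survival genes. Passing tests therefore demonstrate that
the procedures are implemented correctly and behave as designed under their
assumed generative structure, not that the thresholds are optimal for any
particular real dataset.

## Known limitations

* The standard consistency rule has no dispersion model, so its false-call
  rate is set entirely by the noise level: at negative-binomial size 10 the
  per-pair log2FC noise sd is ≈ 0.65 (the `1/size` term dominates regardless
  of sequencing depth), about 22% of null pairs exceed the 0.5 threshold,
  and the "at least half of pairs" rule then passes roughly a quarter of
  null features (the acceptance script computes this as
  `de_false_call_rate`). With quieter data (size ≳ 60) the rate drops below
  5%. Users wanting a controlled error rate at high dispersion should raise
  the threshold, require sign consistency, or use a moderated test upstream
  of this package.
* The variance-stabilizing transform is an approximation (size factors +
  shifted log); it preserves relative structure but is not a calibrated
  variance model at very low counts.
* Correlation p-values in the peak filter are unadjusted by design; the
  cascade's specificity comes from the downstream chromatin-state and gene
  filters plus the patient-variance deflation described above.
* KM curves carry no confidence bands, and there is no Cox or multivariable
  adjustment; stratified comparisons are crude by construction.
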