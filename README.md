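# isopair

Analysis pipeline for **paired isogenic tumor B-cell experiments**: primary
leukemia/lymphoma cells from each patient are split and transduced with an
empty-vector control or a constitutively active construct (e.g. a
PEST-truncated NOTCH intracellular domain), giving one isogenic pair per
patient. Because inter-patient variability dwarfs the construct effect, all
statistics here are built around the *pair*:

* **Per-pair fold-change consistency DE calling** — for each feature the
  per-patient log2 fold change (treated over control) is computed on
  quantile- and trimmed-mean-normalized counts; a gene is called *up* when
  log2FC > 0.5 in at least half of the pairs (standard rule), with a
  stringent variant additionally requiring the same sign in every pair, and
  a proteomics variant (mean log2FC > 0.5, all pairs positive) with median
  scaling of peptide intensities, peptide-to-protein summation and
  Benjamini–Hochberg adjustment. Genotype groups (trisomy 12 vs del13q) are
  compared by correlating their mean per-pair fold changes.
* **H3K27ac peak-signature cascade** — per-sample peak calls are merged into
  consensus peaks, peaks present in ≥ 2 samples are kept, counts are
  variance-stabilized (median-of-ratios size factors, log2(x/sf + 1)), and a
  PCA over samples is scanned for the component separating control from
  construct samples. Peaks whose cross-sample profile correlates with that
  component's sample scores (Pearson r, two-sided t test, p < 0.05) form the
  signature, which is filtered to active chromatin states and annotated to
  genes extended 1.5 kb upstream of their 5′ end. A mean per-bp
  treated-minus-control subtracted signal track is emitted alongside.
* **Survival stratification** — a NOTCH-activation score (mean expression of
  HES1/2 and HEY1/2) and CIITA expression are each dichotomized (cohort
  median or a frozen threshold such as the documented CIITA cut of 14.9),
  defining four patient groups compared by Kaplan–Meier curves and a
  k-group log-rank test, with Fisher's exact test for mutation enrichment in
  the CIITA-low group. KM, log-rank and Fisher are implemented from first
  principles.
* **Synthetic data generators** — negative-binomial paired count matrices
  with patient-dominant variance and planted condition effects, peak/signal
  experiments, and right-censored survival cohorts with a planted hazard
  ratio, so every stage runs with known ground truth and no access to
  patient-level data.

## Worked example

The repository ships a pinned demonstration configuration. One command runs
the whole pipeline on synthetic data:

```bash
isopair run --config configs/demo.yaml --out demo_out
```

The manifest (`demo_out/manifest.json`) records per-stage counts. With the
pinned seed it reads:

```text
de_call:         2000 genes -> 288 up, 307 down, 8 conflicting
chip_signature:  2000 consensus peaks -> 1999 in >=2 samples
                 condition component: PC5
                 42 component-correlated -> 33 in active chromatin
                 -> 27 annotated to a gene
stratify:        240 patients, 4 groups, 176 events, log-rank p < 0.05
```

Reading this: the DE stage calls features whose planted or chance fold
changes satisfy the consistency rule; the chromatin stage finds that the
leading principal components are patient-specific while a minor component
(here the fifth, a few percent of total variance) separates control from
construct samples, and the planted 40-peak signature funnels down the
correlation → chromatin-state → gene-annotation cascade; the survival stage
detects the elevated hazard planted in the NOTCH-high/CIITA-low group.

Each stage is also available separately (`isopair simulate rnaseq|chip|cohort`,
`isopair de-call`, `isopair chip-signature`, `isopair stratify`); see
`--help` on any subcommand.

## Layout

```
src/isopair/synthetic.py   generators (counts, peaks/signal, cohorts)
src/isopair/paired_de.py   normalization + consistency calling + comparisons
src/isopair/chromatin.py   consensus/VST/PCA/signature cascade, signal math
src/isopair/survival.py    scoring, stratification, KM / log-rank / Fisher
src/isopair/cli.py         click CLI, config validation, run manifests
docs/methods.md            models, assumptions, numerical choices, limits
```
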