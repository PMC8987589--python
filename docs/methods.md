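# Methods

## Model and procedure

`cfdyn` analyses paired somatic call sets from cell-free DNA: one serum
draw at baseline, one at documented acquired resistance, per patient.
The method makes three assumptions throughout:

* **Matched-normal subtraction upstream.** Call sets are assumed somatic
  (germline and clonal-hematopoiesis variants removed against matched
  white-cell DNA by the caller). Residual germline contamination is
  handled by the population-frequency filter, not modelled explicitly.
* **Copy-neutral heterozygous VAFs.** The expected variant allele
  fraction of a somatic variant is `tf · CCF / 2`, where `tf` is the
  tumor fraction of cfDNA and CCF the cancer-cell fraction. Interaction
  between copy number and VAF is out of scope.
* **A 1 % detection floor.** Below 1 % VAF, calls are not reliably
  distinguishable from sequencing error at ~140x exome coverage; the
  floor appears twice, as a filter stage and as the presence/absence
  threshold in dynamics classification.

### Filter cascade

Stages run in a fixed order — quality ≥ 30, depth ≥ 20, alt reads ≥ 3,
VAF ≥ 1 %, region ∈ {exonic, splicing}, population AF ≤ 1 %, synonymous
removed unless COSMIC-annotated, then an optional site blacklist (the
programmatic stand-in for manual read-level review). The passing set is
the conjunction of all predicates and therefore order-invariant; only
the audit's attribution of removals depends on the order, which is fixed
so audits are reproducible. The cascade is idempotent and monotone in
every threshold. Unannotated calls carry region `other` and fail the
region stage rather than being dropped at I/O: readers are lossless,
filtering is the filter's job.

### Dynamics classification

Per variant: `RES_ONLY` / `BASE_ONLY` when one time point is below the
detection floor (an absent variant has VAF 0), otherwise `VAF_UP` /
`VAF_DOWN` when |Δ VAF| exceeds 0.05, else `STABLE`. The 5-point change
threshold is an absolute VAF difference, the convention in serial ctDNA
monitoring; raw VAFs are compared (a tumor-fraction-normalised Δ is
available as a report-only column). Swapping the time points maps the
classes onto their mirror images and fixes `STABLE` — a property test.
Gene-level labels pick the variant with max |Δ|, ties broken by class
precedence `RES_ONLY > VAF_UP > BASE_ONLY > VAF_DOWN > STABLE`, then
genomic order; the aggregation rule is a package design choice since
one cell per gene-patient is required and no rule is canonical.

### Recurrence selection

A gene is selected when its direction-relevant patient count reaches
`min_patients` (default 2, i.e. "two or more"; configurable — cohort
reports show candidate genes with exactly two carriers, so the inclusive
reading is the default). `STABLE` never counts. Identical-site
recurrence (same protein change in several patients) is reported as a
supplementary hotspot table but not used for selection. The oncoprint
matrix orders columns by treatment group then patient id and rows by
descending resistance-carrier count — a deterministic substitute for
presentational clustering, chosen so byte-identical outputs can be
asserted.

### Signature refitting

Spectra use the 96 trinucleotide categories (six pyrimidine-strand
substitution classes × 16 flanking-base pairs); purine-reference SNVs
are reverse-complemented before binning, indels are tallied but not
binned. Refitting is greedy forward selection: start from no signatures,
repeatedly add the signature whose inclusion (all selected weights refit
by non-negative least squares on the count-normalised spectrum) most
reduces the squared error, stop when the relative improvement falls
below `tol = 1e-3`; zero weights below `weight_cutoff = 0.06` and
rescale the survivors to the pre-cutoff mass. This mirrors the published
behaviour of the standard refitting tools; both knobs are exposed since
no canonical values exist. If the raw NNLS weights sum above 1 they are
normalised to 1, keeping exposures interpretable as fractions.
Correctness is checked against two independent oracles: an exhaustive
grid search on the 3-signature simplex at 0.01 resolution, and a
projected-gradient NNLS solver.

### Copy number and ctDNA accounting

Segment tables (FACETS-style `tcn.em`) are consumed, not produced;
on-disk 1-based inclusive coordinates are normalised to 0-based
half-open on read. A segment is a **gain** when `tcn > 8`, strictly —
`tcn = 8.0` is not a gain. Gain calls are annotated with overlapping
cancer-gene intervals (user-supplied BED; external gene panels are
versioned resources, so none is bundled) and are invariant under segment
splitting. Per-gene mean tcn across overlapping segments is reported
alongside the per-segment calls. ctDNA amount is
`tumor fraction × total cfDNA` (ng).

### Statistics

Pearson r with the exact t-transform p (n−2 df), listwise deletion of
missing pairs; r > 0.5 is the reported "strong correlation" convention.
Survival uses the Kaplan–Meier product-limit estimator and the
unweighted (Mantel–Haenszel) log-rank test — no weighting scheme is
specified by convention, so the unweighted form is used. "Altered" for a
gene means any non-`STABLE` dynamics class (configurable to
resistance-direction only). ctDNA median splits send ties to "low". No
multiple-testing correction is applied by default; Benjamini–Hochberg is
available (`bh_adjust`, cross-checked against statsmodels).

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with defaults
set to the study conditions of a paired cfDNA exome cohort:

| parameter | default | rationale |
|---|---|---|
| patients | 20 | desk-scale cohort; 40 samples |
| mean coverage | 138x (per-site negative binomial, size 30) | cfDNA exome depth; per-site spread exercises the depth filter |
| tumor fraction | Uniform(0.15, 0.71) | envelope of reported lung/colorectal ctDNA fractions |
| passengers / sample | Poisson(50) | between reported lung (~44) and colorectal (~60) per-sample counts |
| passenger CCF | 0.02 + 0.98·Beta(0.7, 1.5) | subclonal-heavy, as in real tumors; makes detection fraction-dependent |
| error rate | 0.001 (per alt base: /3) | exercises the 1 % floor and 3-read rule |
| germline spikes | 5 / sample at pop AF 0.05 | all must die at the population stage |
| synonymous spikes | 3 / sample, 1 with COSMIC id | exercises the COSMIC exception |
| survival | exponential, hazard 0.03 / month, HR 3 for driver carriers, censor 60 months | gives the log-rank tests real signal |

Planted drivers share one genomic site and protein change across
carriers (hotspot structure); reads are Binomial(depth, tf·CCF/2 +
error/3). All randomness flows from one seed through per-patient
`default_rng([seed, 1, i])` streams, so adding patients never perturbs
earlier patients' draws and outputs are byte-identical across runs.

What the generator does **not** emulate: alignment artifacts and
repetitive-region false positives (the blacklist stage exists but ships
empty), clonal hematopoiesis, multi-allelic somatic sites, copy-number–
VAF interaction, caller-specific quality score distributions, and
between-timepoint coverage pairing. Passing tests therefore demonstrate
the pipeline's correctness on binomially-sampled, annotation-complete
call sets — not robustness to upstream calling artifacts.

## Numerical choices

* Tie-breaks: gene-label precedence as above; median-split ties → low;
  equal-|Δ| ties → class precedence, then genomic order.
* Degenerate inputs: empty spectra, zero-variance vectors, single-group
  survival data and out-of-range fractions raise `ValueError`; malformed
  files raise `FormatError` naming the offending line/record.
* The greedy refit compares SSE improvements relatively (`ΔSSE/SSE`), so
  `tol` is scale-free in the spectrum's total count.
* Variants at the same position with different alt alleles are distinct
  records end to end.

## Problem sizes

The test suite simulates 20-patient cohorts (10 seeds for recovery),
100-replicate signature refits at 5,000 mutations, 200 null and 100
alternative survival simulations, and 10,000-relabeling permutation
checks; the full suite runs in well under a minute on one core. These
sizes give the stochastic assertions comfortable margins (e.g. driver
recovery is near-certain per carrier at depth ~138 and VAF ≥ 6 %, so 10
seeds bound the failure probability far below the test's tolerance).

## Known limitations

* Two time points only; no trajectory modelling or CCF clustering.
* Recurrence selection is a count threshold, not an enrichment test.
* Gain calling thresholds per segment; no cytoband-level averaging
  (per-gene mean tcn is reported for inspection).
* Signature exposures are descriptive; no group-difference test is
  attached, and aetiology labels are user metadata.
* The simulator writes one VAF per variant per sample; harmonisation of
  VAFs across multiple callers is upstream of this package.
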