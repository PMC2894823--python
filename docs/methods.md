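# Methods

This note records the statistical model, the algorithmic conventions, and
the design choices behind `cnvgwas`, at the level of detail a maintainer or
a reviewer of results produced with it would want.

## 1. Detection model

A CNV call is a closed 1-based interval `[start, end]` on one chromosome
for one subject, with a state on a signed-dose scale:

| copy number | 0 | 1 | 3 | 4 | bare loss | bare gain |
|---|---|---|---|---|---|---|
| signed dose | −2 | −1 | +1 | +2 | −1 | +1 |

Copy number 2 is diploid and is rejected on input (with a warning), since a
"CNV" call of CN 2 carries no information. A single numeric scale was
chosen so that one column serves the additive regression model; no factor
coding is offered.

### Sweep-line semantics

Within a chromosome, each call contributes `+1` at `start` and `−1` at
`end`. All events at one physical position are applied before any segment
is evaluated; consequently a call covers the half-open span `[start, end)`
at segment granularity, and a reported sub-CNVR `[a, b]` means "the
carrier fraction strictly exceeded the threshold on every base between
bracketing SNPs a and b". Boundaries are therefore approximations at SNP
resolution — inherent to array data, not an implementation artifact.

Two further conventions matter:

* **Subjects, not calls.** Frequency is the fraction of *subjects* with a
  CNV inside the boundaries. A preprocessing pass merges each subject's
  overlapping same-chromosome calls into maximal covering intervals for
  counting (states are kept separately for state assignment). Merging
  changes counts only, never segment boundaries: every raw call border
  remains an event position.
* **Strict inequalities everywhere.** A segment qualifies iff
  `carriers / n_subjects > f`; a call survives the probe filter iff
  `n_snps ≥ min_snps` (fewer are discarded); a state qualifies iff
  `overlap / region_length > state threshold`. Frequencies are exact
  rationals (integer carrier counts over the cohort size); the comparison
  uses the IEEE value of the user's threshold, so a frequency printed equal
  to the threshold is *not* reported.

The basic detector emits one sub-CNVR per above-threshold inter-event
segment — with dense, interlaced call sets these are typically two SNPs
long, which motivates the extended algorithm. `merge_sub_cnvrs` fuses runs
of sub-CNVRs that share a bracketing position (equivalently: no
below-threshold segment separates them) into one region; the merged
carrier set is recomputed as the union over members (members keep their own
frequencies). Splitting a merged region at member boundaries recovers the
basic output exactly; this identity is tested.

### State assignment in merged regions

A subject's state in a region is no longer unique after merging, so the
longest-overlap rule decides: among the subject's calls overlapping the
region, take the one with maximal overlap (ties: larger |dose|, then
leftmost start — the rule must be deterministic); its dose becomes the
state iff `overlap / region_length > t` with `t = 0.5` by default, else 0.
Overlap and region length are closed-interval bp counts. The threshold is
interpreted as a *fraction* of the region length because an absolute length
would not scale across regions; an absolute-bp alternative
(`absolute_len_threshold`) is exposed for users who want the other reading.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `freq_threshold` | required (CLI: 0.05) | minimum carrier fraction, strict |
| `min_snps` | 1 | discard calls spanning fewer probes |
| `merge` | off | run the extended algorithm |
| `state_len_threshold` | 0.5 | overlap fraction for state assignment |
| `pool_states` | on | count gains and losses together |

Gains and losses are pooled by default (a region is copy-number *variable*
regardless of direction); `pool_states=False` detects the two sets
separately for users studying deletions and duplications apart.

## 2. Association model

Per region, complete-case OLS of the phenotype on
`[intercept, state, covariates…]`. Coefficients and standard errors come
from the normal equations `(XᵀX)β = Xᵀy`, inverted by Gauss–Jordan
elimination with partial pivoting. A pivot below `1e−10 ×` the largest
entry of `XᵀX` raises a collinearity error naming the offending column;
regions whose state column is constant in the analysed subjects are skipped
as *monomorphic* and listed with that reason. The solver is deliberately
written in-package (it is the analysis engine under test); the test suite
cross-checks it against statsmodels/numpy reference solvers to 1e−8
relative error on randomized problems.

The state coefficient's p-value is two-sided Student-t with
`df = n − k` (k includes the intercept; the alternative n − k − 1 df
convention would differ only when covariates are miscounted, and the choice
is fixed and documented here). Genome-wide significance: `p < α/M`, M = the
number of regions *actually tested* in the run — skipped regions do not
inflate M. Changing α re-flags results without refitting.

Missing data policy is complete-case per analysis: a subject contributes to
a region's regression iff response, state and every covariate are observed.
Missing phenotype cells are NaN, never zero. Subject filters drop subjects
missing the filtered column.

The combined SNP + CNVR analysis fits, for every mapped SNP inside a
region's span, `y ~ intercept + dose + state + covariates`, and judges the
cumulative SNP/CNV effect by a joint 2-df F-test against the
covariate-only model (per-term t-tests are also reported). "Cumulative
effect" admits several formalizations (joint model, sum score, sequential
conditioning); the joint model was chosen because it is the standard
nesting with a well-defined F-test, and this choice is flagged here
prominently. When the state is constant within a region the model reduces
to SNP-only with a warning, and the F-test drops to 1 df. Bonferroni M for
this analysis is the number of (region, SNP) models fitted.

## 3. Synthetic cohorts

`simdata` emulates what the pipeline actually consumes, not raw
intensities:

* marker map with exponential inter-marker gaps (mean 5 kb over two 1-Mb
  chromosomes by default, ~200 markers each);
* one planted loss region (200 kb, carrier frequency 0.2, effect β = 0.5
  per unit signed dose) whose carrier boundaries are jittered by up to two
  markers to mimic caller noise — this is what makes region fragmentation,
  and hence the merge step, actually occur in fixtures;
* background CNVs at 0.5 per subject per chromosome, 2–14 markers long,
  mostly single-dose — sparse enough that background per-segment coverage
  (~2%) stays below the detection thresholds a user would choose, matching
  the sparsity of real cohorts relative to recurrent CNVRs;
* phenotype `y = 25 + Σ β·state + 0.05·age − 0.8·sex + N(0,1)`; genotype
  doses per marker under Hardy–Weinberg with uniform random allele
  frequency and 1% missingness.

Two sizing rules were applied once and not revisited. First, the planted
span (~40 markers) is deliberately long relative to the ≤2-marker jitter,
so that end-to-end recovery measures the association machinery rather than
the detector's boundary approximation, which at array resolution cannot be
beaten. Second, the recovery analyses use a detection threshold of 0.10 —
half the planted carrier frequency — the standard analyst's choice of a
threshold comfortably below the frequency of the signal of interest while
above background.

What the generator does **not** model: LD structure among SNPs, intensity
noise, genotype–CNV correlation, family structure, X/Y dosage. Passing
tests therefore demonstrate the correctness and calibration of the
*statistics* under clean sampling assumptions, not robustness to the
artifacts of a particular calling pipeline.

The null-calibration helper (`simulate_null_gwas_inputs`) draws independent
Bernoulli(0.1) carrier sets per region and a standard-normal phenotype;
under this null the per-region t-statistics are exactly t-distributed, so
the raw p < α fraction should sit at α and Bonferroni should clear the
whole genome in ≈ (1 − α/M)^M of replicates (95.1% for M = 200 at
α = 0.05).

## 4. Numerical and formatting choices

* Coordinates: 1-based closed everywhere internally;
  `region_length = end − start + 1`; BED export converts to 0-based
  half-open; BED catalog import converts back.
* Results CSV serializes floats via `repr`, so read-back is bit-exact and
  p-values like 1e−300 survive; covariate coefficients travel in a JSON
  column for lossless round-trips.
* Manhattan plots clip −log10(p) at 320 (the double-precision underflow
  ceiling); the sidecar records when clipping occurred. The Bonferroni
  line height and M are asserted from the sidecar, not from pixels.
* Delimiter detection is limited to comma/tab/semicolon and reads the
  header line only; encodings are UTF-8.
* The phenotype reader parses numbers with Python `float`, which is
  round-trip exact; `pandas.to_numeric`'s default parser is not.

## 5. File dialects

The generic CNV CSV (`subject_id,chromosome,start,end,state,n_snps`) is
the canonical interchange format. The state column accepts unsigned copy
numbers (0, 1, 3, 4) *or* explicitly signed doses (−2…+2); the writer
always emits signed doses, making write→read the identity. `start`/`end`
accept marker ids when a SNP map is supplied.

The segment-summary reader is a tolerant adapter for per-segment
genotyping-console exports. Vendors do not publish a stable layout, so the
accepted header synonyms (see `SEGMENT_SUMMARY_SYNONYMS`) are a
reconstruction and are flagged as such; a missing marker-count column is
imputed as missing with a warning, and such calls are exempt from the
min-SNP filter (fail-open on metadata, fail-closed on coordinates).

Known-association catalogs are consumed as local file snapshots
(BED or 1-based CSV), never fetched live; the overlap rule for
highlighting is ≥1 bp on the same chromosome.

## 6. Known limitations

* Quantitative phenotypes only; no logistic model for case/control traits.
* No population-structure or relatedness correction; no mixed models.
* Bonferroni is the only multiple-testing procedure offered.
* Region boundaries are SNP-bracketing approximations; sub-SNP precision
  is out of reach of the input data.
* The merged-region frequency is recomputed over the merged span (union of
  member carriers); an alternative convention inherits member frequencies,
  which remain available on the members themselves.
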