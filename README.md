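# cnvgwas

Genome-wide association testing for **copy-number variation** (CNV) in
population cohorts. Upstream callers (array- or HMM-based) emit per-subject
CNV segments; the open statistical question downstream is *where* the genome
is recurrently copy-number variable across subjects, and *whether* a
subject's copy-number state at those places predicts a quantitative
phenotype. `cnvgwas` packages that downstream analysis as a library plus a
small CLI: region detection, covariate-adjusted association, genome-wide
significance bookkeeping, and plots.

## The method

**Region detection (sweep line).** For each chromosome, every CNV call
contributes a `+1` event at its start SNP and a `−1` event at its end SNP.
Scanning events in position order (all events at one position applied
together, with per-subject deduplication so the counter counts *subjects*,
not calls) yields a piecewise-constant carrier count. Every inter-SNP
segment whose carrier fraction strictly exceeds a user threshold *f* is a
**sub-CNVR**, bounded by its bracketing SNPs. Because interlaced calls
fragment the genome into many two-SNP regions, an **extended algorithm**
merges consecutive above-threshold sub-CNVRs into one region; a subject's
state in a merged region is taken from its longest-overlapping CNV iff that
overlap strictly exceeds a second threshold (default 50% of the region
length), else 0. States live on a signed-dose scale (CN 0,1,3,4 → −2, −1,
+1, +2).

**Association.** For each region, ordinary least squares of

```
phenotype ~ intercept + state + covariates
```

under an additive genetic model, solved via the normal equations by
Gaussian elimination with partial pivoting. The state coefficient β gets a
two-sided Student-*t* p-value with df = n − k, and a region is genome-wide
significant when `p < α / M` (Bonferroni, M = regions actually tested).
Subject filters (`sex==1`, `age>=40`, …) restrict any analysis to a
subgroup; a joint SNP-dose + region-state model with a 2-df F-test covers
the combined SNP/CNV analysis.

**Everything is testable offline**: the `simdata` module generates SNP
maps, CNV calls with planted effect regions and boundary jitter,
phenotypes and genotypes from a single seed.

## Worked example

```bash
cnvgwas simulate --out demo --seed 7 --n-subjects 500
cnvgwas detect --cnv demo/cnv_calls.csv --subjects 500 \
               --freq-threshold 0.10 --merge --out demo/regions.csv
cnvgwas assoc  --regions demo/regions.csv --cnv demo/cnv_calls.csv \
               --pheno demo/phenotypes.csv --dependent bmi \
               --covariates age,sex --out demo/results.csv
cnvgwas plot manhattan --results demo/results.csv --out demo/manhattan.png
```

The `assoc` step prints:

```
CNV region association results
==============================
regions tested     : 1
regions skipped    : 0
subjects (filtered): 350
alpha              : 0.05
Bonferroni cut-off : 5.000e-02
significant regions: 1

region                     freq     n      beta       se       t          p sig
1:409276-599023           0.276   350    0.4537   0.1123    4.04  6.560e-05 *
```

The simulation planted a 200-kb loss region on chromosome 1 carried by
~20% of subjects with a true effect of β = 0.5 on the phenotype (per unit
of signed dose). The detector localizes it (`1:409276-599023`, frequency
0.276 of the cohort of 500), and the regression recovers β̂ = 0.45 ± 0.11 —
the 95% CI covers the truth — with p = 6.6 × 10⁻⁵, below the Bonferroni
cut-off for the single region tested. `demo/manhattan.png.json` is a
machine-readable sidecar carrying the Bonferroni line position, the number
of tests M, and per-point metadata.

Library users get the same thing as objects: build a `CnvrGwas` model from
a `CnvrStateMatrix` and a `PhenotypeTable`, call `.fit()`, and read the
returned `CnvrGwasResults` (`.results`, `.summary()`, `.manhattan(spec)`).

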