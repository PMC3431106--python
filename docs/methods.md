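# Methods

## Problem and approach

Exon arrays measure expression in probe selection regions (PSRs), short
genomic windows tiled across annotated exonic sequence. Most PSRs hybridize
to sequence shared by several transcripts of a gene, so their signal cannot
be attributed to any single isoform. This package implements an analysis
that restricts attention to *transcript-specific* PSRs (TS-PSRs) — PSRs that
intersect the exons of exactly one annotated transcript — and uses them to
call differential expression at the level of individual transcripts across a
three-group prostate-cancer progression design (normal adjacent → primary
tumor → metastasis; 29/131/19 arrays in the GSE21034 cohort the design
mirrors), to place transcripts on the progression continuum, and to
stratify primary tumors by recurrence risk with a nearest-prototype
classifier.

## TS-PSR detection

All intervals are 0-based half-open internally; conversion to/from GTF's
1-based inclusive convention happens only at the file boundary. Overlap
means an intersection of at least one base **on the same strand**, for both
the exon-level and gene-hull tests; partial overlap counts (containment is
not required). The exclusion cascade, applied in a fixed order:

1. `EXCLUDED_UNRELIABLE` — one or more probes of the set do not align
   uniquely to the genome (consumed as a metadata flag);
2. `EXCLUDED_CROSSHYB` — not in the class-1 (non-cross-hybridizing) class;
3. `EXCLUDED_NOT_EXONIC` / `EXCLUDED_MULTI_TRANSCRIPT` — no same-strand
   exon overlap, or exons of two or more distinct transcripts;
4. `EXCLUDED_MULTI_GENE_OVERLAP` — the PSR intersects the exon hulls
   (min-to-max exon span, introns included) of two or more same-strand
   genes, e.g. a PSR inside another gene's intron; opposite-strand nesting
   never excludes;
5. `EXCLUDED_SINGLE_TRANSCRIPT_GENE` — the owning gene has one annotated
   transcript, so the measurement is gene-level anyway;
6. `EXCLUDED_ONE_TESTABLE_GENE` — the gene has several transcripts but only
   one of them retains any candidate PSR after steps 1–4, so no within-gene
   contrast is possible.

The probe-level filters run before the structural ones because they are
properties of the probes, not of the annotation; and testability in steps
5–6 is counted **after** steps 1–4 — a transcript whose only unique PSR is
unreliable cannot actually be tested. A gene is *fully tested* when every
one of its transcripts has at least one candidate PSR surviving steps 1–4;
reporting of fully-tested results is restricted to genes with two or more
transcripts. The three-value gene category map bins multi-transcript genes
with zero testable transcripts together with the one-testable ones.

The production classifier answers overlap queries from strand-keyed
interval trees; an independent quadratic all-pairs scan (used by the
generator to derive ground truth) serves as its oracle in the tests.

## Differential expression

Three pairwise contrasts span the design: normal vs primary (`NvsP`),
primary vs metastasis (`PvsM`), normal vs metastasis (`NvsM`); the fold is
always later stage over earlier. Before any contrast, PSRs whose median
log2 expression is below the background level in **all three** groups are
removed once. The background level is a single scalar supplied with the
study (the generator emits its true censoring threshold); how an array's
control probes would yield it is outside this package's scope.

Per PSR and contrast:

* two-sample pooled-variance t-test (two-sided, `nA+nB−2` df); rows with
  zero pooled variance get `t=0, p=1` with a warning;
* Benjamini–Hochberg adjusted q-values;
* median fold difference `MFD = 2^(median_B − median_A)` on the log2 data,
  i.e. the linear-scale ratio of group medians. This definition makes the
  stagewise folds compose multiplicatively, `MFD(N→P)·MFD(P→M) = MFD(N→M)`
  exactly — an identity the test suite asserts to machine precision and
  that also holds, up to 2-decimal rounding propagation, across the printed
  reference fold table in `published.py`;
* a PSR is DE when `q < 0.05` and `MFD ≥ 1.2` **or** `MFD ≤ 1/1.2` (the
  down-regulation bound is the reciprocal; the reference table reports
  values like 0.42 as significant, which fixes the symmetric reading).

Per transcript and contrast, the significant TS-PSR with the lowest p
represents the transcript; if none is significant the overall lowest-p PSR
is reported with `de=False`. Ties break by larger `|log2 MFD|`, then
lexicographic PSR id. Representatives are chosen independently per
contrast. Each DE-anywhere transcript is assigned one of the seven Venn
cells over the three contrasts; the *continuum* set is the union of the
all-three cell and the `NvsP∧PvsM` cell (transcripts flanking the primary
stage but silent in the net contrast). Direction concordance inspects genes
with at least two DE transcripts and flags sibling pairs that move in
opposite directions within the same contrast.

Gene-level comparison: the consensus-gene matrix is the per-sample median
over a gene's analyzed PSRs (a deliberately simple stand-in for a
probe-weighted summarization), pushed through the identical t/FDR/MFD
machinery, to demonstrate the information loss relative to transcript-level
calls on fully tested genes.

## Risk stratification

Features are the DE PSRs of the `NvsM` contrast ranked by ascending p
(ties: larger `|t|`, then id), truncated to the top 100 (fewer, with a
warning, when fewer exist). A k=1 Euclidean nearest-prototype classifier is
trained on the normal-adjacent + metastatic samples (never also queried)
and applied to the primaries; exact distance ties go to the
lexicographically smallest reference id. Evaluation on the biochemical
recurrence (BCR) endpoint: Kaplan–Meier product-limit curves per predicted
class, the two-group log-rank test, and a multivariable logistic model of
the BCR event on the predicted class and the dichotomized nomogram
probability (> 0.5), with Wald 95% CIs on the OR scale (chosen over profile
likelihood for determinism; convergence tolerance 1e−8, 50 Newton
iterations, gradient-method fallback with a `separation` flag when the
Hessian degenerates or coefficients diverge).

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions. It emulates:

* **Annotation** — ~60 random non-overlapping loci (1–5 transcripts per
  gene, shared plus transcript-unique exon slots) plus planted pathological
  loci: a single-transcript gene, a gene with one testable transcript, a
  gene nested in another's intron on the same and on the opposite strand,
  and a fully tested gene. Ground-truth dispositions come from the
  quadratic scan at generation time.
* **Expression** — per-PSR affinity `N(7, 1.5)` on the log2 scale,
  additive noise `N(0, 0.5)` (typical exon-array residual spread),
  background level 5.0 with 10% of PSRs generated ~1.5 log2 units below it
  in every group. Planted transcripts receive stagewise fold shifts on all
  their PSRs; default patterns cover the continuum Venn cells, weighted
  toward the late transition (metastasis-dominant deregulation, matching a
  cohort in which most DE arises in the `NvsM` contrast). A `nvsm_only`
  pattern (1.19 per stage) sits deliberately just under the fold threshold
  per stage while its product clears it.
* **Clinical** — exponential BCR times; a latent 20% high-risk subset of
  primaries carries hazard ratio 3 (baseline hazard 0.012/month) and a
  metastasis-level expression profile on the planted features; independent
  exponential censoring calibrated to censor ~40% at the baseline hazard;
  nomogram probability from a logistic model of true risk with noise.

A single seed fans out to per-stage child streams (annotation, expression,
clinical), so a fixed seed reproduces each stage byte-identically.

What the generator does **not** model: probe-level hybridization physics,
batch effects, correlated noise between PSRs of one transcript, annotation
incompleteness, or non-exponential hazards. Passing tests therefore show
that the pipeline's logic and statistics behave as specified under the
assumed model — not that the thresholds are optimal for real arrays.

## Calibration experiments and problem sizes

`tspsr.experiments` re-runs the machinery under seeded replicates at desk
scale — tens of genes and a few hundred PSRs per replicate, with the full
29/131/19 group design wherever power is at stake:

* classifier-vs-oracle agreement over 100 random toy genomes;
* null false-call rate: 20 replicates with nothing planted; the fraction of
  transcripts called DE in `NvsM` stays at or below the FDR target;
* planted power: fold 1.6 split evenly over the two stages, 20 replicates;
  recovery of planted transcripts in `NvsM` (a pilot run put per-PSR power
  near 98% at these group sizes, so the ≥90% requirement carries margin);
* log-rank power: 100 clinical-only cohorts of 131 primaries with hazard
  ratio 3 between the risk classes.

The headline genome-wide counts of the reference study (hundreds of
thousands of PSRs against a full Ensembl release) are not reproducible at
this scale and are out of scope; `published.py` carries only the printed
reference values that are recomputable from themselves (continuum fold
table, cohort sizes, DE tallies).

## Known limitations

* The fold-closure check against the printed reference table is limited by
  the 2-decimal rounding of the printed inputs; the identity is exact on
  computed matrices and holds within the propagated rounding bound
  (≤ 0.013, observed ≤ 0.0076) on the printed ones.
* With ~40 noisy features and 48 prototypes, the k=1 classifier mislabels a
  noticeable minority of low-risk primaries at desk scale, so end-to-end
  log-rank significance on a single default-seed cohort varies; the power
  properties are assessed on the clinical simulator directly, where the
  class labels are exact.
* Shared-exon PSRs inherit no planted effect (their signal is not modeled
  as a mixture of isoform abundances).
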