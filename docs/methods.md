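# Methods

This note records the models, conventions, parameter choices and known
limitations behind `apakit`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted that the
code does not measure.

## Coordinates and orientation

All internal coordinates are 0-based half-open; GTF I/O converts to/from
1-based inclusive at the boundary. Offsets around a cleavage locus are
transcript-relative: the cleavage base sits at offset 0, negative offsets are
upstream (5'), and sequence is always read on the transcript strand. Exon
chains are stored 5'→3' in transcript orientation, so a minus-strand
transcript lists its highest-coordinate exon first.

## Cleavage extraction

3'-end-enriched libraries in the REV configuration produce reads antisense
to the mRNA, with the cleavage locus at the read's 5' terminus. For a
minus-strand alignment spanning `[a, b)` the locus is therefore `b − 1` on
transcript strand `+`; for a plus-strand alignment it is `a` on transcript
strand `−`. Soft-clipped bases never contribute: the locus is the terminal
*aligned* base. A `fwd` mode (locus at the read's 3' terminus, transcript
strand = alignment strand) covers sense-oriented protocols.

## Atlas filters

* **Internal priming.** Oligo-dT can prime at genomic A stretches rather
  than true polyA tails. An event is removed when the 21-nt window
  [−10, +10] around its locus contains a run of ≥7 consecutive As ("more
  than 6") or ≥9 As in any 10-nt subwindow ("more than 8"), literal readings
  of the stated thresholds. Windows truncated by a chromosome edge are
  evaluated on the available bases.
* **Hexamer requirement.** A retained site must have one of 18 catalogued
  polyadenylation-signal hexamers (AATAAA, ATTAAA, … — the canonical signal
  catalogue, fully config-overridable) whose *start* offset lies in
  [−30, −10]. The annotated signal is chosen by catalogue priority first,
  then by proximity to the cleavage site. The filter runs on cluster
  representatives by default (`hexamer_stage="cluster"`) so that jittered
  member positions of a true site are not dropped individually; an
  event-level mode exists.
* **Clustering.** Cleavage is not nucleotide-exact; pooled events within
  ±5 nt of a dominant locus are absorbed by one-pass greedy clustering:
  repeatedly seed on the unassigned position with the highest pooled count
  (ties to the 5'-most) and absorb unassigned positions within the radius.
  One-pass (not iterated to convergence) is a deliberate choice and is what
  the oracle test simulates.
* **Spacing.** Dominant sites are ranked by descending pooled count and
  accepted only if ≥125 nt from every previously accepted representative on
  the same chromosome and transcript strand, so retained sites carry their
  own signal and cis-regulatory context. Ties break to the 5'-most
  position everywhere, making the pipeline deterministic.

## Gene assignment and structure classes

Because 3'UTR isoforms are under-annotated, each gene is extended past its
annotated 3' end by 5 kb, or half the intergenic gap when the next gene
(either strand by default) is closer than 10 kb. A site maps to a gene when
it falls in `[gene start, extended end)` in transcript orientation on the
matching strand; ambiguity resolves to the nearest annotated 3' end, then to
the smaller gene id. Location classes use the precedence 3'UTR > exon >
intron > downstream-extension; extension sites are pooled with the 3'UTR
bucket in summaries.

For proximal/distal pairs (5'-most and 3'-most retained sites of a
multi-site gene), pair types follow annotated isoforms: *same-exon* when one
exon of one transcript holds both sites; *skipped-exon* when the proximal
site's exon is fully intronic in a distal-containing transcript;
*composite-exon* when the proximal site's exon runs past a 5' splice donor
used by a distal-containing transcript (intron retention). Precedence is
same > skipped > composite; pairs matching no rule are labelled composite
and flagged rather than silently forced. A transcript whose terminal exon
reaches the gene's annotated 3' end is treated as extending into the
downstream extension, so extension sites behave as terminal-exon sites;
shorter isoforms are *not* extended, because their annotated 3' boundary is
real isoform structure. Classification is verified exactly against a naive
brute-force oracle on 1,000 random gene models.

## Quantification and testing

PSI = proximal/(proximal+distal) per gene and sample, undefined at zero
total. Before pairing, sites pass three abundance filters in order: present
(nonzero) in ≥25% of all samples; summed count ≥10 in the tumor group *and*
in the non-involved group (the conservative reading of "in either"); pooled
count ≥5% of the gene's strongest surviving site.

Differential usage is a per-gene two-sided paired Wilcoxon signed-rank on
matched tumor/normal PSI with BH FDR across genes (the negative-binomial
exon-level GLM used by dedicated differential-usage packages is out of
scope by design; the paired test is self-contained and calibrates well —
the suite checks sensitivity ≥0.8 and empirical FDR ≤0.10 at q<0.05 with a
planted |ΔPSI| of 0.3 over 20 pairs, and KS-uniform null p-values). A gene
is *shortened* when q < α and median ΔPSI > 0.

PSI–expression coupling is gene-wise Spearman Rho over shared samples
(constant vectors skipped). The cohort-level statistic — the number of genes
with Rho above 0.1 (one-sided by default; |Rho| mode available) — gets an
empirical p by jointly permuting the sample columns of the PSI matrix
(preserving gene–gene correlation; per-gene shuffling is available), with
the add-one estimator (1 + hits)/(n_perm + 1) so p is never 0. Genes with
missing values are dropped from the permutation statistic.

## Indices

The PA-machinery index z-scores each machinery gene's expression across
samples (sd 0 → z = 0, unbiased sd) and takes the per-sample median over the
gene set; it is invariant to affine rescaling of any single gene. PSI-load
is the per-sample median of defined PSIs ("median" is the stated group-level
summary; mean is a config alternative). Mutation fold change is
median-load(mutated)/median-load(wildtype) per driver gene with a two-sided
rank-sum p and BH across drivers, flagged at q < 0.1 and |FC − 1| > 0.1 (the
stated "FC > 0.1" threshold read as distance from 1). Interval semantics are
any-overlap by default (containment available). PDUI conversion is
PSI = 1 − PDUI with missing preserved and out-of-range values rejected.

## Survival model

Feature selection is a single multivariate L1-Cox over all gene PSI columns
with clinical covariates unpenalized (penalty factor 0); the phrase
"for each gene" is read as describing per-gene coefficients, since only a
joint model yields genes *independently* associated with survival (a
univariate screen can be emulated by calling the selector per gene). The
penalty is chosen by 5-fold cross-validation maximizing held-out Breslow log
partial likelihood, computed by a small in-package evaluator over the
coefficient path. The final model is an unpenalized multivariate Cox
(lifelines, Breslow ties) on the selected genes plus covariates;
PI_k = Σ β_i χ_ik uses gene terms only and matches the fitted definition to
machine precision (≤1e-12, asserted). LOOCV refits the model n times, each
time scoring only the held-out sample; non-convergent folds yield missing
PI. Risk groups split at the median PI, with the source's labelling (PI
above the median → "low-risk") preserved verbatim and the conventional
orientation available; the log-rank test is two-sided, and a
covariate-adjusted Cox hazard ratio between groups is reported, optionally
within levels of a grouping column (e.g. race).

## Synthetic data

The generator emulates the statistical structure of a tumor/normal 3'-end
cohort, not its sequence biology. Defaults (chosen once, as study
conditions): 200 genes at 8-kb pitch on one synthetic chromosome, 75%
multi-site (~350 sites), pair-type mix 50/29/21% same/composite/skipped
(the proportions observed among shortened switches in the motivating
cohort), 44% of multi-site genes switched with 88% of switches shortened,
|ΔPSI| = 0.3, baseline normal-tissue PSI uniform on [0.2, 0.8] (keeps shifts
representable without clipping for most genes; clipping is recorded in the
truth), and 40 internal-priming decoys.

Each planted site carries AATAAA at offset −20 with its jitter-padded
priming window sanitized of A-runs; each decoy carries a 12-A run across its
locus (so the A-run test trips even after ±5 jitter) beneath a 32-nt A-free
upstream pattern that provably cannot contain any catalogued hexamer. Decoys
sit ≥125 nt from planted sites. Reads follow the REV convention (antisense
alignment, cleavage base at the 5' terminus), with Gaussian cleavage jitter
clipped to ±5 nt, Poisson per-gene depth (default 100 reads/gene/sample),
optional terminal soft clips on the non-cleavage end, and single-end
all-matched CIGARs — the pipeline consumes alignments, so no FASTQ, quality,
UMI or error model is simulated.

Subject-level PSI heterogeneity (Gaussian, sd 0.1, shared between a
subject's tumor and normal samples) is added on top of the per-gene
baseline: real cohorts vary between patients, and without it PSI could not
carry survival or expression signal at all. Survival times come from an
exponential Cox model with linear predictor Σ β_g PSI_g plus optional
covariate effects, administratively censored (default horizon 60, baseline
hazard 0.02). `beta_for_group_hr(hr, sd)` converts a target median-split
group hazard ratio into a coefficient via the normal half-mean gap
2·σ·√(2/π). Expression is coupled to PSI per gene through a Gaussian copula
whose normal-score correlation 2·sin(πρ/6) hits the target Spearman ρ
(exact rank matching at |ρ| = 1); mRNA–protein concordance increases in
median PSI through a linear monotone map with additive noise.

What passing tests on these cohorts do **not** show: robustness to
mis-annotation, overlapping genes, multi-chromosome structure, sequencing
error, depth heterogeneity across genes, batch effects, or non-exponential
hazards. The generator's geometry is deliberately clean so that filter and
recovery failures are attributable to the pipeline, not the fixture.

## Problem sizes and numerics

The acceptance computations use the scales the checks are defined at: the
200-gene/20-pair cohort through the full SAM path for atlas recovery and PSI
fidelity; 200 genes × 20 pairs at depth 200 for switch calibration; 100
genes × 20 pairs × 1,000 permutations (50 seeds in the suite, one seed in
the script) for the permutation null; and 10 seeds of a 98-tumor cohort for
log-rank power. Randomness always flows through `numpy.random.default_rng`
seeded from the caller, and identical (config, seed) reproduce byte-identical
outputs. BH adjustment uses the standard step-up (verified against a
brute-force oracle), Wilcoxon tests use the exact distribution where SciPy
selects it, and the L1-Cox path uses the default alpha grid with
`alpha_min_ratio = 0.01`.

## Known limitations

* ~20% of true polyA sites lack a canonical hexamer and are knowingly
  missed, as in the motivating study; no downstream-element or UGUA
  detection is attempted.
* The hexamer catalogue and machinery gene set are data, shipped as
  configuration, not code.
* The per-gene covariate-adjusted regression of PSI on ancestry/stage is
  not implemented; the paired Wilcoxon design covers the tumor/normal
  contrast only.
* Atlas construction holds all events in memory; cohorts far beyond desk
  scale would need a chromosome-partitioned driver.
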