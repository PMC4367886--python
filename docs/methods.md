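# Methods

`linemeth` analyses DNA methylation of individual LINE-1 retrotransposon
promoters from bisulfite amplicon sequencing and from assay-level
(pyrosequencing-style) mean-methylation tables. This note describes the
models and procedures, the parameters that matter, what the synthetic data
generator does and does not emulate, and the design choices made where the
design was genuinely open.

## Read-level model

A bisulfite amplicon read reports the methylation state of every CpG on one
DNA molecule: unmethylated cytosines deaminate and are sequenced as T,
5-methylcytosines resist conversion and stay C. The core object is the
reads × CpG call matrix for one locus in one sample, with entries
methylated / unmethylated / missing.

**Alignment.** Reads are aligned to the unconverted reference semi-globally
(free end gaps on both sequences) with affine gap costs (match +2, mismatch
−3, open −5, extend −2) and bisulfite-aware asymmetric scoring: a read T
against a reference C scores as a match (the expected conversion), while a
read C against a reference T remains a mismatch, so a molecule's methylation
state cannot bias its placement. Both orientations are tried and the better
score kept. Reads are discarded when shorter than 20 nt, when aligned
identity (conversion-aware) falls below 0.80, or when fewer than half the
read's bases land in aligned columns — the last filter is needed because an
overlap alignment of an unrelated read degenerates to a short, spuriously
high-identity segment.

**Calling and conversion QC.** At each CpG cytosine, read C → methylated,
read T → unmethylated, gap or other base → missing. Non-CpG reference
cytosines measure conversion efficiency: the per-read fraction still read as
C (retention) must not exceed 0.05 or the molecule is judged incompletely
converted and dropped. The identity, coverage, and retention thresholds are
conventional QC defaults, exposed in the function signatures.

## Pattern metrics

**Per-CpG means** are column-wise fractions of methylated calls among
non-missing calls; a CpG with coverage below `min_coverage` (default 10
reads) is flagged missing rather than reported from thin data.

**Methylation entropy** summarises single-molecule heterogeneity in sliding
windows of `b` consecutive CpGs (default 4, stride 1). Each read fully
observed in a window contributes one epiallele (its length-`b` pattern), and

    ME = (1/b) · Σ_i (n_i/N) · log2(N/n_i)

over observed epialleles `i` with counts `n_i` out of `N` reads. ME is 0
when one pattern dominates and 1 when all 2^b patterns are equiprobable.
Reads with a missing call inside a window are excluded from that window
only (listwise per window); windows with fewer than `min_reads` (default
10) complete reads are reported missing.

**Paired comparisons** between tumor and normal profiles (per-CpG means, or
entropy per window) use the two-sided Wilcoxon signed-rank test, paired
over sites/windows. Zero differences are dropped; the exact null
distribution is used for n ≤ 25 untied differences, otherwise the normal
approximation with continuity correction.

**Change calls.** A locus in a tumor is called hypomethylated when its mean
methylation lies more than 10 percentage points below the paired normal
tissue, hypermethylated when more than 10 points above, otherwise
unchanged — strict inequalities, so a delta of exactly ±10 is unchanged.
The rule is antisymmetric under swapping tumor and normal. Per-sample
summaries count hypo/hyper loci and categorise pairs as
none / hypo_only / hyper_only / both.

## Architecture classification

Deep sequencing shows three recurring single-molecule architectures:
uniform (all molecules alike, methylated or unmethylated), allelic
(molecules split into a nearly-fully-methylated and a nearly-fully-
unmethylated class), and patchy (consistent alternating methylated/
demethylated runs that drive window entropy up and down along the locus).
The qualitative taxonomy is operationalised as a threshold rule over
per-read mean methylation and the entropy track:

* f_hi / f_lo = fraction of reads with mean ≥ 0.8 / ≤ 0.2;
* `uniform_methylated` if f_hi ≥ 0.9; `uniform_unmethylated` if f_lo ≥ 0.9;
* `allelic` if f_hi ≥ 0.2, f_lo ≥ 0.2 and f_hi + f_lo ≥ 0.8;
* `patchy` if the entropy range across windows (max − min) ≥ 0.3 and no
  uniform rule fired — allelic heterogeneity keeps entropy stable while
  patchy methylation makes it fluctuate;
* otherwise `indeterminate`, a first-class outcome rather than a forced
  nearest class (mixtures of architectures legitimately land here).

Every constant is configurable and echoed in the call's evidence so a label
is reproducible from its reported numbers. The rule is invariant to read
order and to duplicating the read set.

## Consensus projection and hypomethylation seeds

The individually assayed loci share a consensus coordinate frame (CpG
indices with representative base-pair positions), supplied as a curated map
table or derived from an aligned-FASTA multiple sequence alignment.
Projecting every (locus, sample) profile onto that frame and averaging —
unweighted over observations, with indices supported by fewer than
`min_obs` (default 3) observations masked — yields group consensus
profiles.

Hotspots are called on the tumor-minus-normal delta track: a
hypomethylation-prone site ("seed") is a strict local minimum at least
`k`·MAD (default k = 1.5) below the median delta *and* at least 10
percentage points below it in absolute terms; protected sites are the
mirrored local maxima. The absolute floor matters: on a near-flat track the
MAD is itself sampling noise, and without the floor noise-level local
minima would be flagged. The rule is invariant to adding a constant to all
deltas. Spacings between consecutive seeds are summarised (median, IQR)
with the fraction falling in the 40–60 and 80–100 nt bands; no spectral or
autocorrelation analysis is attempted. Whether consensus averaging should
weight loci by read count is not obvious; unweighted per-observation
averaging is used and flagged.

## Diagnostic marker cascade

Markers (per-locus percentage methylation, optionally split-locus and
global assays) are screened per marker — Wilcoxon signed-rank for paired
tumor/normal designs, Kruskal–Wallis (tie-corrected, chi-square p) for
independent group designs such as patient vs healthy blood — and corrected
by Benjamini–Hochberg step-up FDR. Markers with q < 0.05 enter a
multivariate logistic regression producing a per-sample tumor probability
π; class separation is the area under the ROC curve, computed by the
tie-corrected midrank (Mann–Whitney) formula, which equals the trapezoidal
area under the step ROC.

Two numerical choices matter on small cohorts:

* **Ridge penalty.** FDR-selected markers frequently separate small
  cohorts perfectly, making the logistic MLE infinite; a small L2 penalty
  (λ = 10⁻⁴ on standardised predictors) keeps the fit defined without
  materially shrinking coefficients away from separation.
* **Out-of-fold AUC.** In-sample AUC on markers selected for significance
  is optimistic, so the headline number is a 5-fold cross-validated AUC
  (scaler and classifier refit per fold), reported as the mean of per-fold
  AUCs — pooling probabilities across folds mixes fold-specific scales and
  is pessimistically biased under the null. For paired designs the folds
  never split a tumor-normal pair: holding out one member while training
  on the other leaks the pair's shared methylation baseline and
  anti-correlates held-out scores (null AUC ≈ 0.37 instead of 0.5 in our
  calibration runs). With grouped, stratified folds the null mean
  out-of-fold AUC is ≈ 0.49.

Marker selection happens once on the full cohort before cross-validation;
the out-of-fold AUC therefore removes fit optimism but not selection
optimism, a limitation shared with the screening-then-modelling design it
implements.

## Synthetic data generator

No patient data are distributed, so the generator emulates the study
conditions with known ground truth. Its defaults are the analysis
conditions: 11 loci (5 autosomal, 6 X-linked) sharing a consensus frame,
paired cohorts of 20 tumor-normal pairs, 300 reads per locus (read-depth
per amplicon is not constrained by published values; 100–1000 is the
realistic band and 300 gives comfortable power for window entropy at
`min_reads` 10), and an effective pyrosequencing depth of 100 for cohort
means.

**Epiallele models.** `uniform`: i.i.d. Bernoulli(base) per CpG.
`allelic`: a molecule is drawn from the methylated class with probability
`allelic_fraction` (per-CpG Bernoulli(base)) else from the unmethylated
class (Bernoulli(1 − base)). `patchy`: a Bernoulli(base) background in
which each seed CpG is demethylated with probability p and its neighbours
with p·decay^d (d in CpG steps, symmetric, independent per seed and
molecule). Analytic per-CpG means exist for all three and are checked
against empirical draws within four binomial standard deviations.

**Canonical parameterisations** (the documented conditions of the recovery
studies): uniform at 0.95/0.05; allelic as an even mixture of 0.95/0.05
classes; patchy as a 0.95 background with three quartile seeds, p = 0.9,
decay = 0.3. The patchy decay is deliberately local: with wide spreading
the entropy track is uniformly elevated and the "fluctuating entropy"
phenotype that defines the class disappears.

**Sequencing layer.** Reads are rendered by in-silico bisulfite conversion
of the top strand only (one strand per amplicon): non-CpG cytosines
convert to T except with probability `conversion_failure_rate`; methylated
CpG cytosines stay C except with `inappropriate_conversion_rate`; a final
uniform per-base substitution applies `sequencing_error_rate`. Cohort
tables draw per-sample means as binomial proportions at the effective
depth. A separate Gaussian marker-table generator backs the diagnostic
calibration studies, where the relevant condition is the marker's total
sampling SD (5 points, split evenly between a pair-level offset shared by
both members of a pair and residual noise).

**Default loci.** The 11 references are mutated copies of one synthetic
CpG-island-like scaffold (fixed internal seed, independent of user seeds):
point substitutions at ~2% of non-CpG positions (to A/T, which cannot
create a CpG) and loss of ~12% of CpGs (CG→CA), so every locus carries an
exact consensus map by construction. Irregular CpG spacing (12–40 bp) is
the default; a fixed-spacing scaffold supports planting seeds at exact
base-pair intervals.

**What the generator does not emulate** — and hence what passing recovery
studies do not show about real data: platform-specific homopolymer errors,
PCR duplicates and chimeras, strand asymmetries, cross-locus mapping
ambiguity within the LINE-1 family (amplicon specificity is assumed),
biological covariance between loci beyond the shared pair baseline, and
tissue composition effects. Recovery rates measured here are properties of
the stated generative models at the stated sizes.

## Determinism and numerics

All randomness flows through a single seeded NumPy generator per run; no
global RNG state is used, and identical configurations reproduce outputs
byte-for-byte. Coordinates are 0-based half-open everywhere; matrices
serialise to TSV with 1/0/NA cells. Degenerate inputs are first-class:
all-missing CpG columns, constant markers (undefined Spearman ρ, flagged),
all-zero difference vectors (p = 1), single-class label vectors (error),
and empty FDR selections (model skipped with an explicit reason) are all
handled and tested. Validation oracles (hash-count entropy, Gotoh DP
alignment score, sign-flip Wilcoxon enumeration, rank-sum Kruskal–Wallis,
explicit BH step-up) are implemented independently of the code paths they
check and live in `linemeth.validation`.
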