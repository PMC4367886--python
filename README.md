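# linemeth

Locus-specific analysis of LINE-1 retrotransposon promoter methylation from
bisulfite amplicon sequencing.

Global LINE-1 hypomethylation is a hallmark of many cancers, but global
assays average over ~500,000 copies and hide what happens at individual,
still-mobilisable elements. `linemeth` implements the analysis layer for
studying *specific* LINE-1 promoters — a panel of 5 autosomal and 6
X-linked loci — in paired tumor/normal cohorts:

* **Read-level methylation calling** — bisulfite-aware semi-global
  alignment (read T vs reference C scores as a match) and per-read per-CpG
  calls into a reads × CpG matrix, with conversion-efficiency QC.
* **Pattern metrics** — per-CpG methylation averages and sliding-window
  methylation entropy over epialleles,
  `ME = (1/b) Σᵢ (nᵢ/N) log₂(N/nᵢ)` for windows of b = 4 CpGs,
  with paired Wilcoxon comparisons of tumor vs normal profiles.
* **Architecture classification** — each matrix is labelled uniformly
  methylated / uniformly unmethylated / allelic (bimodal molecules) /
  patchy (alternating runs with fluctuating entropy) / indeterminate, by a
  transparent, fully configurable threshold rule.
* **Change calls** — a locus is hypo-/hypermethylated in a tumor when its
  mean differs from the paired normal tissue by strictly more than 10
  percentage points (down/up), with per-sample hypo/hyper summaries.
* **Hypomethylation seeds** — per-CpG profiles projected onto the shared
  LINE-1 consensus frame, averaged across samples and loci, with recurrent
  hypomethylated CpGs ("seeds") and protected CpGs called as robust local
  extrema of the tumor-normal delta, and their base-pair spacings
  summarised against the 40–60 / 80–100 nt bands.
* **Diagnostics** — per-marker Wilcoxon signed-rank (paired) or
  Kruskal–Wallis (groups) screens, Benjamini–Hochberg FDR, ridge-stabilised
  multivariate logistic regression, and ROC/AUC with a pair-aware
  cross-validated AUC as the headline number.
* **Synthetic data** — a ground-truth-known generator for all of the above
  (uniform / allelic / patchy epiallele models, bisulfite conversion with
  configurable error rates, paired cohort tables), since no patient data
  are public.

## Worked example

Simulate one tumor/normal pair at the L1X8 locus — allelic hypomethylation
in the tumor against a uniformly methylated normal tissue — then call the
matrix, compare profiles, and classify the pattern:

```python
import numpy as np
from linemeth import (default_loci, SimulationConfig, canonical_model,
                      simulate_sample, build_matrix, per_cpg_mean,
                      methylation_entropy, classify_pattern,
                      compare_profiles, call_change)

locus = default_loci()[10]  # L1X8
config = SimulationConfig(
    loci=[locus],
    tumor_models={locus.locus_id: canonical_model("allelic")},
    normal_models={locus.locus_id: canonical_model("uniform_methylated")},
    n_reads=300, rng_seed=1,
)
t_reads, _ = simulate_sample(config, "tumor", sample_id="T01")
n_reads, _ = simulate_sample(config, "normal", sample_id="N01")
t_mat, _ = build_matrix(t_reads[locus.locus_id], locus, "T01")
n_mat, _ = build_matrix(n_reads[locus.locus_id], locus, "N01")
t_prof, n_prof = per_cpg_mean(t_mat), per_cpg_mean(n_mat)
stat, p, n = compare_profiles(t_prof, n_prof)
call = call_change(100 * np.nanmean(t_prof.mean), 100 * np.nanmean(n_prof.mean),
                   locus_id=locus.locus_id, sample_pair_id="P01")
print(f"{locus.locus_id}: tumor {100*np.nanmean(t_prof.mean):.1f}%, "
      f"normal {100*np.nanmean(n_prof.mean):.1f}%")
print(f"delta {call.delta:+.1f} points -> {call.label} (Wilcoxon p = {p:.2e})")
print(f"pattern: {classify_pattern(t_mat).label}")
```

```
L1X8: tumor 51.0%, normal 94.9%
delta -43.9 points -> hypomethylated (Wilcoxon p = 1.29e-05)
pattern: allelic
```

The tumor's even mixture of fully methylated and fully unmethylated
molecules halves the mean (51% vs 95%), is highly significant across the
25 CpGs, and is recognised as *allelic* rather than patchy because the
entropy track stays flat.

The diagnostic cascade on a simulated 20-pair cohort with one marker
shifted −15 points in tumors:

```python
from linemeth import simulate_marker_table, run_marker_cascade, model_report
table = simulate_marker_table(n_pairs=20, markers=6, tumor_shifts={"M01": -15.0},
                              marker_sd=3.5, pair_sd=3.5, rng=1)
print(model_report(run_marker_cascade(table, design="paired", rng_seed=0)))
```

```
marker       statistic           p           q  selected
M01              0.000   1.907e-06   1.144e-05  *
M02             95.000      0.7285      0.8742
...
Selected markers: M01
In-sample AUC:   1.000
Out-of-fold AUC: 1.000
```

Only the shifted marker survives FDR, and the pair-aware cross-validated
AUC confirms the separation is real rather than fit optimism.

A `linemeth` console command exposes the same pipeline as subcommands
(`simulate`, `extract`, `metrics`, `classify-patterns`, `seeds`,
`diagnose`, `report`); run `linemeth --help`.

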