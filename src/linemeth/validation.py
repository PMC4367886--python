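"""Independent oracles and simulation studies validating the pipeline.

Every oracle here recomputes a quantity by a route deliberately different
from the implementation it checks: entropy by hash-counting epialleles in
pure Python, alignment by a hand-written Gotoh dynamic program, the Wilcoxon
p-value by full sign-flip enumeration, the Kruskal-Wallis statistic from the
rank-sum definition, and BH q-values by the explicit step-up loop.  The
studies run the generator -> pipeline loop under known ground truth and
measure recovery (pattern classes, planted hotspots, diagnostic calibration).
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .bisulfite_io import (
    GAP_EXTEND_SCORE,
    GAP_OPEN_SCORE,
    MATCH_SCORE,
    MISMATCH_SCORE,
    MISSING,
    LocusReference,
    ReadMethylationMatrix,
    align_read,
    build_matrix,
)
from .diagnostics import bh_fdr, fit_logistic, marker_test_paired, run_marker_cascade
from .pattern_classification import classify_pattern, confusion_report
from .pattern_metrics import methylation_entropy, per_cpg_mean
from .seed_analysis import build_consensus_profile, find_hotspots, hotspot_periodicity
from .synthetic import (
    EpialleleModel,
    SimulationConfig,
    canonical_model,
    consensus_scaffold,
    mutate_scaffold,
    simulate_marker_table,
    simulate_matrix,
    simulate_sample,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def entropy_oracle(matrix: ReadMethylationMatrix, b: int = 4, min_reads: int = 1) -> np.ndarray:
    """Brute-force window entropy: collect epialleles as tuples, count, apply
    the (1/b) * sum (n_i/N) log2(N/n_i) formula with explicit loops."""
    n_windows = matrix.n_cpg - b + 1
    out = np.full(n_windows, np.nan)
    for w in range(n_windows):
        counts: dict[tuple, int] = {}
        for row in matrix.calls:
            pattern = tuple(int(v) for v in row[w : w + b])
            if MISSING in pattern:
                continue
            counts[pattern] = counts.get(pattern, 0) + 1
        n = sum(counts.values())
        if n < min_reads or n == 0:
            continue
        me = 0.0
        for c in counts.values():
            me += (c / n) * np.log2(n / c)
        out[w] = me / b
    return out


def gotoh_overlap_score(ref: str, read: str) -> float:
    """Optimal bisulfite-aware overlap alignment score by explicit Gotoh DP.

    Affine gaps (open applies to the first gap base, extend to each further
    base), end gaps free on both sequences, ref C vs read T scored as match.
    """

    def score(a: str, b: str) -> float:
        if a == b or (a == "C" and b == "T"):
            return MATCH_SCORE
        return MISMATCH_SCORE

    n, m = len(ref), len(read)
    neg = -np.inf
    H = np.full((n + 1, m + 1), neg)
    E = np.full((n + 1, m + 1), neg)  # gap in read (ref base vs -)
    F = np.full((n + 1, m + 1), neg)  # gap in ref (- vs read base)
    H[0, 0] = 0.0
    for i in range(1, n + 1):
        H[i, 0] = 0.0  # free leading gap in read
    for j in range(1, m + 1):
        H[0, j] = 0.0  # free leading gap in ref
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] + GAP_OPEN_SCORE, E[i - 1, j] + GAP_EXTEND_SCORE)
            F[i, j] = max(H[i, j - 1] + GAP_OPEN_SCORE, F[i, j - 1] + GAP_EXTEND_SCORE)
            H[i, j] = max(H[i - 1, j - 1] + score(ref[i - 1], read[j - 1]), E[i, j], F[i, j])
    return float(max(H[:, m].max(), H[n, :].max()))


def sign_flip_wilcoxon_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign assignments.

    Uses average ranks of |d| (zero differences must be removed beforehand);
    p = 2 * min(P(W+ <= w), P(W+ >= w)), capped at 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    absd = np.abs(d)
    order = np.argsort(absd, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_abs = absd[order]
    pos = 1
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        avg = (pos + pos + (j - i)) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        pos += j - i + 1
        i = j + 1
    w_obs = float(np.sum(ranks[d > 0]))
    w_all = []
    for signs in product((0, 1), repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.asarray(w_all)
    total = len(w_all)
    p_low = np.sum(w_all <= w_obs + 1e-12) / total
    p_high = np.sum(w_all >= w_obs - 1e-12) / total
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def kruskal_h_oracle(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H from the rank-sum definition with tie correction."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n_total)
    i = 0
    sorted_vals = pooled[order]
    while i < n_total:
        j = i
        while j + 1 < n_total and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        avg = (i + 1 + j + 1) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        ng = len(g)
        r_sum = float(np.sum(ranks[start : start + ng]))
        h += r_sum * r_sum / ng
        start += ng
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return float(h / correction) if correction > 0 else float("nan")


def bh_stepup_oracle(p_values: np.ndarray) -> np.ndarray:
    """BH q-values by the explicit step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# studies
# ---------------------------------------------------------------------------


def _study_locus(n_cpg: int = 12, spacing: int | None = None) -> LocusReference:
    seq, positions = consensus_scaffold(n_cpg=n_cpg, spacing=spacing)
    return LocusReference(
        locus_id="L1SIM",
        sequence=seq,
        cpg_positions=positions,
        consensus_cpg_index=tuple(range(len(positions))),
        consensus_bp_position=positions,
    )


def roundtrip_study(n_runs: int = 50, n_reads: int = 20, n_cpg: int = 12, seed: int = 0) -> dict:
    """Simulate error-free reads, align, call, and compare to ground truth.

    Cycles through the three epiallele architectures.  Returns cell-level
    agreement over all runs; with all error rates zero every cell must match.
    """
    locus = _study_locus(n_cpg=n_cpg)
    rng = np.random.default_rng(seed)
    kinds = ("uniform_methylated", "allelic", "patchy")
    n_cells = 0
    n_mismatch = 0
    n_row_mismatch = 0
    for run in range(n_runs):
        model = canonical_model(kinds[run % len(kinds)], n_cpg=locus.n_cpg)
        config = SimulationConfig(
            loci=[locus],
            tumor_models={locus.locus_id: model},
            normal_models={locus.locus_id: model},
            n_reads=n_reads,
            rng_seed=int(rng.integers(2**31 - 1)),
        )
        reads, truth = simulate_sample(config, "tumor", sample_id=f"run{run}")
        matrix, qc = build_matrix(reads[locus.locus_id], locus, sample_id=f"run{run}")
        states = truth.read_states[(f"run{run}", locus.locus_id)]
        if matrix.calls.shape != states.shape:
            n_row_mismatch += abs(matrix.calls.shape[0] - states.shape[0])
            continue
        n_cells += states.size
        n_mismatch += int(np.sum(matrix.calls != states))
    return {
        "n_runs": n_runs,
        "n_cells": n_cells,
        "n_mismatch": n_mismatch,
        "n_row_mismatch": n_row_mismatch,
        "cell_agreement": 1.0 - (n_mismatch / n_cells if n_cells else np.nan),
    }


def _random_bisulfite_read(ref: str, rng: np.random.Generator) -> str:
    """A read derived from ``ref`` by bisulfite conversion plus light damage."""
    read = [("T" if (b == "C" and rng.random() < 0.8) else b) for b in ref]
    # occasional substitutions and a possible short indel
    for i in range(len(read)):
        if rng.random() < 0.05:
            read[i] = "ACGT"[rng.integers(4)]
    if rng.random() < 0.5 and len(read) > 6:
        pos = int(rng.integers(1, len(read) - 3))
        if rng.random() < 0.5:
            del read[pos : pos + int(rng.integers(1, 3))]
        else:
            read.insert(pos, "ACGT"[rng.integers(4)])
    start = int(rng.integers(0, 3))
    end = len(read) - int(rng.integers(0, 3))
    return "".join(read[start:end])


def alignment_oracle_study(n_fixtures: int = 200, seed: int = 0) -> dict:
    """Compare align_read scores with the Gotoh DP oracle on small fixtures.

    References are random 20-40 nt sequences; reads are damaged bisulfite
    conversions of them (<= 30 nt after trimming) plus fully random reads.
    Agreement is exact score equality.
    """
    rng = np.random.default_rng(seed)
    n_agree = 0
    max_diff = 0.0
    n_done = 0
    while n_done < n_fixtures:
        ref_len = int(rng.integers(20, 41))
        ref = "".join("ACGT"[i] for i in rng.integers(4, size=ref_len))
        if rng.random() < 0.8:
            read = _random_bisulfite_read(ref, rng)
        else:
            read = "".join("ACGT"[i] for i in rng.integers(4, size=int(rng.integers(20, 31))))
        if len(read) < 20 or len(read) > 30:
            continue
        try:
            ref_obj = LocusReference(locus_id="FIX", sequence=ref, cpg_positions=())
        except ValueError:
            continue
        aln = align_read(read, ref_obj, min_identity=0.0, min_aligned_fraction=0.0,
                         both_orientations=False)
        oracle = gotoh_overlap_score(ref, read)
        diff = abs(aln.score - oracle)
        max_diff = max(max_diff, diff)
        if diff < 1e-9:
            n_agree += 1
        n_done += 1
    return {"n_fixtures": n_done, "n_agree": n_agree, "agreement": n_agree / n_done, "max_diff": max_diff}


def pattern_recovery_study(
    n_reps: int = 100, n_reads: int = 500, n_cpg: int = 25, seed: int = 0
) -> dict:
    """Classify matrices simulated from the canonical architectures.

    Returns per-class recall over ``n_reps`` replicates of each class plus
    the full predicted x true confusion matrix.
    """
    rng = np.random.default_rng(seed)
    kinds = ("uniform_methylated", "uniform_unmethylated", "allelic", "patchy")
    calls = []
    truth = []
    for rep in range(n_reps):
        for kind in kinds:
            model = canonical_model(kind, n_cpg=n_cpg)
            matrix = simulate_matrix(model, n_cpg, n_reads, rng, locus_id=kind, sample_id=f"rep{rep}")
            calls.append(classify_pattern(matrix))
            truth.append(kind)
    confusion, recall = confusion_report(calls, truth)
    return {
        "n_reps": n_reps,
        "confusion": confusion,
        "recall": {k: float(v) for k, v in recall.items()},
    }


def hotspot_recovery_study(
    n_reps: int = 100,
    seed: int = 0,
    n_cpg: int = 28,
    spacing: int | None = None,
    seed_indices: tuple[int, ...] = (5, 13, 21),
    n_samples: int = 3,
    n_loci: int = 2,
    n_reads: int = 300,
    base_methylation: float = 0.85,
    seed_demethylation_prob: float = 0.6,
    spread_decay: float = 0.3,
) -> dict:
    """Plant demethylation seeds at known consensus indices and recover them.

    Each replicate simulates ``n_samples`` tumor/normal sample pairs over
    ``n_loci`` loci sharing the scaffold frame (no CpG loss, so local and
    consensus indices coincide), builds group consensus profiles, and calls
    hotspots.  Reports mean recall of the planted set, mean false positives
    per run, and the across-replicate median hotspot spacing in bp.
    """
    scaffold, positions = consensus_scaffold(n_cpg=n_cpg, spacing=spacing)
    loc_rng = np.random.default_rng(12345)
    loci = [
        mutate_scaffold(scaffold, positions, f"L1SIM{i}", "autosomal", loc_rng, cpg_loss_rate=0.0)
        for i in range(n_loci)
    ]
    references = {l.locus_id: l for l in loci}
    tumor_model = EpialleleModel(
        kind="patchy",
        base_methylation=base_methylation,
        seed_cpg_indices=tuple(seed_indices),
        seed_demethylation_prob=seed_demethylation_prob,
        spread_decay=spread_decay,
    )
    normal_model = EpialleleModel(kind="uniform", base_methylation=base_methylation)
    rng = np.random.default_rng(seed)
    planted = set(int(i) for i in seed_indices)
    recalls, fps, medians = [], [], []
    for rep in range(n_reps):
        tumor_profiles, normal_profiles = [], []
        for locus in loci:
            for s in range(n_samples):
                tm = simulate_matrix(tumor_model, locus.n_cpg, n_reads, rng,
                                     locus_id=locus.locus_id, sample_id=f"T{s}")
                nm = simulate_matrix(normal_model, locus.n_cpg, n_reads, rng,
                                     locus_id=locus.locus_id, sample_id=f"N{s}")
                tumor_profiles.append(per_cpg_mean(tm))
                normal_profiles.append(per_cpg_mean(nm))
        tumor_cons = build_consensus_profile(tumor_profiles, references, group="tumor")
        normal_cons = build_consensus_profile(normal_profiles, references, group="normal")
        hs = find_hotspots(tumor_cons, normal_cons)
        found = set(int(i) for i in hs.hypo_indices)
        recalls.append(len(found & planted) / len(planted))
        fps.append(len(found - planted))
        summary = hotspot_periodicity(hs)
        if not np.isnan(summary["median"]):
            medians.append(summary["median"])
    return {
        "n_reps": n_reps,
        "mean_recall": float(np.mean(recalls)),
        "mean_false_positives": float(np.mean(fps)),
        "median_spacing_bp": float(np.median(medians)) if medians else np.nan,
    }


_MARKER_SD_TOTAL = 5.0  # total per-value sampling SD, split pair vs residual
_MARKER_SD_COMPONENT = _MARKER_SD_TOTAL / np.sqrt(2.0)


def diagnostics_null_study(
    n_reps: int = 200,
    seed: int = 0,
    n_pairs: int = 20,
    n_markers: int = 14,
    auc_reps: int = 50,
) -> dict:
    """Type-I calibration of the marker cascade on null paired cohorts.

    No marker carries a group effect; reports the overall fraction of
    (replicate, marker) results with q < 0.05 and, over the first
    ``auc_reps`` replicates, the mean out-of-fold AUC of a logistic model
    forced to use all markers (selection would usually return none).
    Marker values have total SD 5 points, split evenly between a pair-level
    offset and residual noise.
    """
    rng = np.random.default_rng(seed)
    n_selected = 0
    n_tested = 0
    oof_aucs = []
    for rep in range(n_reps):
        table = simulate_marker_table(
            n_pairs=n_pairs, markers=n_markers,
            marker_sd=_MARKER_SD_COMPONENT, pair_sd=_MARKER_SD_COMPONENT, rng=rng,
        )
        markers = [c for c in table.columns if c.startswith("M")]
        pvals = [marker_test_paired(table, m)[1] for m in markers]
        _, sel = bh_fdr(np.asarray(pvals))
        n_selected += int(sel.sum())
        n_tested += len(markers)
        if rep < auc_reps:
            model = fit_logistic(table, markers, rng_seed=rep, groups=table["pair_id"])
            oof_aucs.append(model.auc_oof)
    return {
        "n_reps": n_reps,
        "frac_selected": n_selected / n_tested,
        "mean_oof_auc": float(np.mean(oof_aucs)),
    }


def diagnostics_effect_study(
    n_reps: int = 100,
    seed: int = 0,
    n_pairs: int = 20,
    n_markers: int = 14,
    shift: float = -15.0,
) -> dict:
    """Power of the cascade with one marker shifted -15 points in tumors.

    Marker values carry total SD 5 (pair + residual components); the shifted
    marker should pass FDR selection and the fitted model should reach
    out-of-fold AUC >= 0.9 in nearly every replicate.
    """
    rng = np.random.default_rng(seed)
    shifted = "M01"
    n_sel = 0
    n_auc_ok = 0
    aucs = []
    for rep in range(n_reps):
        table = simulate_marker_table(
            n_pairs=n_pairs, markers=n_markers,
            tumor_shifts={shifted: shift},
            marker_sd=_MARKER_SD_COMPONENT, pair_sd=_MARKER_SD_COMPONENT, rng=rng,
        )
        model = run_marker_cascade(table, design="paired", rng_seed=rep)
        if shifted in model.selected:
            n_sel += 1
        if not model.skipped_reason and not np.isnan(model.auc_oof):
            aucs.append(model.auc_oof)
            if model.auc_oof >= 0.9:
                n_auc_ok += 1
    return {
        "n_reps": n_reps,
        "selection_rate": n_sel / n_reps,
        "auc_ge_090_rate": n_auc_ok / n_reps,
        "mean_oof_auc": float(np.mean(aucs)) if aucs else np.nan,
    }
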