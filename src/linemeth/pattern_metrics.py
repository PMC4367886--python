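"""Per-CpG methylation profiles, sliding-window methylation entropy,
paired profile comparisons, and locus-level hypo/hypermethylation calls.

Methylation entropy follows the epiallele formulation of Xie and colleagues:
within a window of ``b`` consecutive CpGs, each read contributes one length-b
epiallele (its methylation pattern across the window), and

    ME = (1/b) * sum_i (n_i / N) * log2(N / n_i)

over the observed epialleles i, where ``n_i`` is the count of epiallele i and
``N`` the number of reads fully observed in the window.  ME is 0 when a
single pattern dominates and reaches 1 when all 2^b patterns are
equiprobable.

Hypo- and hypermethylation of a locus in a tumor relative to its paired
normal tissue are conservatively defined as a change of more than 10
percentage points in absolute methylation (strict inequality), downward and
upward respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bisulfite_io import MISSING, ReadMethylationMatrix

DEFAULT_MIN_COVERAGE = 10
DEFAULT_WINDOW_SIZE = 4
DEFAULT_MIN_WINDOW_READS = 10
DEFAULT_CHANGE_THRESHOLD = 10.0
EXACT_WILCOXON_MAX_N = 25


@dataclass
class MethylationProfile:
    """Per-CpG mean methylation (fraction in [0, 1]) with coverage.

    Means are NaN wherever fewer than ``min_coverage`` non-missing calls
    support the CpG.
    """

    locus_id: str
    sample_id: str
    mean: np.ndarray
    coverage: np.ndarray
    min_coverage: int = DEFAULT_MIN_COVERAGE

    @property
    def n_cpg(self) -> int:
        return len(self.mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_id,
                "sample_id": self.sample_id,
                "cpg_index": np.arange(self.n_cpg),
                "mean_methylation": self.mean,
                "coverage": self.coverage,
            }
        )


@dataclass
class EntropyProfile:
    """Sliding-window methylation entropy (stride 1, window size ``b``)."""

    locus_id: str
    sample_id: str
    window_start: np.ndarray
    entropy: np.ndarray
    n_reads: np.ndarray
    b: int = DEFAULT_WINDOW_SIZE

    @property
    def n_windows(self) -> int:
        return len(self.window_start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_id,
                "sample_id": self.sample_id,
                "window_start": self.window_start,
                "window_size": self.b,
                "entropy": self.entropy,
                "n_reads": self.n_reads,
            }
        )

    def to_bedgraph(self, path: str | Path, cpg_positions: Sequence[int]) -> None:
        """Write entropy against locus coordinates (window start C to end G)."""
        with open(path, "w") as fh:
            for s, e_val in zip(self.window_start, self.entropy):
                if np.isnan(e_val):
                    continue
                start = cpg_positions[s]
                end = cpg_positions[s + self.b - 1] + 2
                fh.write(f"{self.locus_id}\t{start}\t{end}\t{e_val:.4f}\n")


@dataclass
class ChangeCall:
    locus_id: str
    sample_pair_id: str
    delta: float  # tumor - normal, percentage points
    label: str  # hypomethylated / hypermethylated / unchanged
    threshold: float = DEFAULT_CHANGE_THRESHOLD


@dataclass
class SampleSummary:
    sample_pair_id: str
    n_hypo_loci: int
    n_hyper_loci: int
    category: str  # none / hypo_only / hyper_only / both


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def per_cpg_mean(
    matrix: ReadMethylationMatrix, min_coverage: int = DEFAULT_MIN_COVERAGE
) -> MethylationProfile:
    """Column-wise fraction of methylated calls among non-missing calls."""
    if matrix.n_reads == 0:
        raise ValueError(f"{matrix.locus_id}/{matrix.sample_id}: empty matrix")
    calls = matrix.calls
    observed = calls != MISSING
    coverage = observed.sum(axis=0)
    meth = ((calls == 1) & observed).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(coverage > 0, meth / np.maximum(coverage, 1), np.nan)
    mean = np.where(coverage >= min_coverage, mean, np.nan)
    return MethylationProfile(
        locus_id=matrix.locus_id,
        sample_id=matrix.sample_id,
        mean=mean,
        coverage=coverage,
        min_coverage=min_coverage,
    )


def methylation_entropy(
    matrix: ReadMethylationMatrix,
    b: int = DEFAULT_WINDOW_SIZE,
    min_reads: int = DEFAULT_MIN_WINDOW_READS,
) -> EntropyProfile:
    """Sliding-window epiallele entropy, one value per window of b CpGs.

    Reads with any missing call inside a window are excluded from that window
    only.  Windows supported by fewer than ``min_reads`` complete reads get
    NaN entropy.
    """
    if b < 1:
        raise ValueError("window size b must be >= 1")
    if matrix.n_cpg < b:
        raise ValueError(
            f"{matrix.locus_id}: {matrix.n_cpg} CpGs is fewer than window size {b}"
        )
    n_windows = matrix.n_cpg - b + 1
    starts = np.arange(n_windows)
    entropy = np.full(n_windows, np.nan)
    n_used = np.zeros(n_windows, dtype=int)
    weights = 1 << np.arange(b - 1, -1, -1)
    for w in range(n_windows):
        sub = matrix.calls[:, w : w + b]
        complete = ~np.any(sub == MISSING, axis=1)
        n = int(complete.sum())
        n_used[w] = n
        if n < min_reads:
            continue
        codes = sub[complete].astype(np.int64) @ weights
        counts = np.unique(codes, return_counts=True)[1]
        frac = counts / n
        entropy[w] = float(np.sum(frac * np.log2(n / counts)) / b)
    return EntropyProfile(
        locus_id=matrix.locus_id,
        sample_id=matrix.sample_id,
        window_start=starts,
        entropy=entropy,
        n_reads=n_used,
        b=b,
    )


# ---------------------------------------------------------------------------
# paired comparisons
# ---------------------------------------------------------------------------


def paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (Wilcoxon's original treatment).  The exact
    null distribution is used for n <= 25 without tied absolute differences;
    otherwise the normal approximation with continuity correction.  Returns
    (statistic, p); all differences zero gives (0, 1).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= EXACT_WILCOXON_MAX_N and not has_ties:
        res = stats.wilcoxon(d, method="exact")
    else:
        res = stats.wilcoxon(d, method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)


def compare_profiles(
    tumor: MethylationProfile, normal: MethylationProfile, min_shared: int = 5
) -> tuple[float, float, int]:
    """Paired Wilcoxon over per-CpG means shared by both profiles.

    Returns (statistic, p, n_shared).  Raises ValueError below ``min_shared``
    jointly defined CpGs.
    """
    if tumor.n_cpg != normal.n_cpg:
        raise ValueError("profiles have different CpG counts")
    shared = ~np.isnan(tumor.mean) & ~np.isnan(normal.mean)
    n = int(shared.sum())
    if n < min_shared:
        raise ValueError(f"only {n} CpGs defined in both profiles (need >= {min_shared})")
    stat, p = paired_wilcoxon(tumor.mean[shared], normal.mean[shared])
    return stat, p, n


def compare_entropy(
    tumor: EntropyProfile, normal: EntropyProfile, min_shared: int = 5
) -> tuple[float, float, int]:
    """Paired Wilcoxon over entropy windows shared by both profiles."""
    if tumor.b != normal.b:
        raise ValueError("entropy profiles use different window sizes")
    common = np.intersect1d(tumor.window_start, normal.window_start)
    if len(common) == 0:
        raise ValueError("entropy profiles have disjoint window sets")
    t_map = {int(s): v for s, v in zip(tumor.window_start, tumor.entropy)}
    n_map = {int(s): v for s, v in zip(normal.window_start, normal.entropy)}
    t_vals = np.array([t_map[int(s)] for s in common])
    n_vals = np.array([n_map[int(s)] for s in common])
    shared = ~np.isnan(t_vals) & ~np.isnan(n_vals)
    n = int(shared.sum())
    if n < min_shared:
        raise ValueError(f"only {n} windows defined in both profiles (need >= {min_shared})")
    stat, p = paired_wilcoxon(t_vals[shared], n_vals[shared])
    return stat, p, n


# ---------------------------------------------------------------------------
# change calls
# ---------------------------------------------------------------------------


def call_change(
    tumor_mean: float,
    normal_mean: float,
    locus_id: str = "",
    sample_pair_id: str = "",
    threshold: float = DEFAULT_CHANGE_THRESHOLD,
) -> ChangeCall:
    """Label a paired tumor-normal difference (0-100 scale, strict +-threshold).

    A decrease of more than ``threshold`` points is hypomethylated, an
    increase of more than ``threshold`` points hypermethylated, anything else
    (including exactly +-threshold) unchanged.
    """
    if np.isnan(tumor_mean) or np.isnan(normal_mean):
        raise ValueError(f"{locus_id}/{sample_pair_id}: missing mean, no call possible")
    delta = float(tumor_mean) - float(normal_mean)
    if delta < -threshold:
        label = "hypomethylated"
    elif delta > threshold:
        label = "hypermethylated"
    else:
        label = "unchanged"
    return ChangeCall(
        locus_id=locus_id, sample_pair_id=sample_pair_id, delta=delta, label=label, threshold=threshold
    )


def summarize_sample(calls: Sequence[ChangeCall]) -> SampleSummary:
    """Count hypo/hyper loci for one sample pair and categorise it."""
    if not calls:
        raise ValueError("summarize_sample requires at least one change call")
    pair_ids = {c.sample_pair_id for c in calls}
    if len(pair_ids) > 1:
        raise ValueError(f"calls span multiple sample pairs: {sorted(pair_ids)}")
    n_hypo = sum(c.label == "hypomethylated" for c in calls)
    n_hyper = sum(c.label == "hypermethylated" for c in calls)
    if n_hypo and n_hyper:
        category = "both"
    elif n_hypo:
        category = "hypo_only"
    elif n_hyper:
        category = "hyper_only"
    else:
        category = "none"
    return SampleSummary(
        sample_pair_id=pair_ids.pop(), n_hypo_loci=n_hypo, n_hyper_loci=n_hyper, category=category
    )


def cohort_change_calls(
    table: pd.DataFrame,
    markers: Sequence[str] | None = None,
    threshold: float = DEFAULT_CHANGE_THRESHOLD,
) -> pd.DataFrame:
    """Change calls for every (pair, marker) of a wide paired cohort table."""
    if markers is None:
        markers = [c for c in table.columns if c not in ("sample_id", "pair_id", "group", "tissue", "sex")]
    rows = []
    for pair_id, grp in table.groupby("pair_id"):
        tumor = grp[grp["group"] == "tumor"]
        normal = grp[grp["group"] == "normal"]
        if len(tumor) != 1 or len(normal) != 1:
            raise ValueError(f"pair {pair_id} is not a single tumor-normal pair")
        for m in markers:
            call = call_change(
                float(tumor[m].iloc[0]), float(normal[m].iloc[0]),
                locus_id=m, sample_pair_id=str(pair_id), threshold=threshold,
            )
            rows.append(
                {"pair_id": pair_id, "locus_id": m, "delta": call.delta, "label": call.label}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inter-locus correlation
# ---------------------------------------------------------------------------


def inter_locus_correlation(
    table: pd.DataFrame,
    group: str,
    markers: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman correlation between locus markers within one sample group.

    Returns (rho, p, significant) DataFrames indexed by marker; significance
    is Bonferroni-adjusted over the number of tested (off-diagonal) pairs.
    Constant markers yield NaN rho, flagged not significant.
    """
    sub = table[table["group"] == group]
    if markers is None:
        markers = [c for c in table.columns if c not in ("sample_id", "pair_id", "group", "tissue", "sex")]
    if len(sub) < 5:
        raise ValueError(f"need >= 5 samples in group {group!r}, have {len(sub)}")
    k = len(markers)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = sub[markers[i]].to_numpy(dtype=float)
            y = sub[markers[j]].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    n_tests = k * (k - 1) // 2
    sig = (pmat * n_tests < alpha) & ~np.isnan(pmat)
    np.fill_diagonal(sig, False)
    idx = list(markers)
    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(pmat, index=idx, columns=idx),
        pd.DataFrame(sig, index=idx, columns=idx),
    )
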