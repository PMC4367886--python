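"""Tumor-vs-normal biomarker cascade over per-locus methylation markers.

The cascade mirrors standard paired-biopsy biomarker practice: each marker
(percentage methylation of one locus or a global assay) is tested for a
tumor-normal difference with the Wilcoxon signed-rank test (paired designs)
or the Kruskal-Wallis test (independent groups, e.g. patient vs healthy
blood across cancer types); p-values are corrected by Benjamini-Hochberg
step-up FDR; markers with q < 0.05 enter a multivariate logistic regression
giving each sample a probability of being tumor; and class separation is
measured by the area under the ROC curve (1 = perfect, 0.5 = chance).

FDR-selected markers on small cohorts frequently separate the classes
perfectly, so the logistic fit carries a small ridge penalty on standardised
predictors to keep the MLE finite.  Because an in-sample AUC on markers that
were themselves selected for significance is optimistic, the model reports
a 5-fold out-of-fold AUC as the headline number, with the in-sample AUC
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .pattern_metrics import paired_wilcoxon

METADATA_COLUMNS = ("sample_id", "pair_id", "group", "tissue", "sex")
DEFAULT_FDR_ALPHA = 0.05
DEFAULT_RIDGE_LAMBDA = 1e-4
DEFAULT_N_FOLDS = 5


def marker_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def validate_marker_table(table: pd.DataFrame, paired: bool = True) -> None:
    """Check the MarkerTable contract (metadata columns; pairing if paired)."""
    for col in ("sample_id", "group"):
        if col not in table.columns:
            raise ValueError(f"marker table lacks required column {col!r}")
    if paired:
        if "pair_id" not in table.columns:
            raise ValueError("paired marker table lacks pair_id column")
        counts = table.groupby("pair_id")["group"].apply(
            lambda g: sorted(g.tolist()) == ["normal", "tumor"]
        )
        bad = counts[~counts].index.tolist()
        if bad:
            raise ValueError(f"pairs without exactly one tumor and one normal record: {bad}")


# ---------------------------------------------------------------------------
# per-marker tests
# ---------------------------------------------------------------------------


def _paired_values(table: pd.DataFrame, marker: str) -> tuple[np.ndarray, np.ndarray]:
    wide = table.pivot_table(index="pair_id", columns="group", values=marker, aggfunc="first")
    wide = wide.dropna(subset=["tumor", "normal"])
    return wide["tumor"].to_numpy(dtype=float), wide["normal"].to_numpy(dtype=float)


def marker_test_paired(table: pd.DataFrame, marker: str, min_pairs: int = 5) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank over complete tumor-normal pairs.

    Exact null for n <= 25 untied differences, normal approximation with
    continuity correction beyond.  Returns (statistic, p).
    """
    tumor, normal = _paired_values(table, marker)
    if len(tumor) < min_pairs:
        raise ValueError(f"{marker}: only {len(tumor)} complete pairs (need >= {min_pairs})")
    return paired_wilcoxon(tumor, normal)


def marker_test_groups(
    table: pd.DataFrame, marker: str, group_col: str = "group", min_per_group: int = 3
) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across sample groups, chi-square p."""
    groups = [
        g[marker].to_numpy(dtype=float) for _, g in table.groupby(group_col) if len(g) > 0
    ]
    if len(groups) < 2:
        raise ValueError(f"{marker}: need >= 2 groups, have {len(groups)}")
    for g in groups:
        if len(g) < min_per_group:
            raise ValueError(f"{marker}: group with {len(g)} samples (need >= {min_per_group})")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values: Sequence[float], alpha: float = DEFAULT_FDR_ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and the q < alpha selection mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < alpha


# ---------------------------------------------------------------------------
# logistic model and ROC
# ---------------------------------------------------------------------------


@dataclass
class MarkerModel:
    """Per-marker statistics plus the multivariate logistic classifier."""

    marker_stats: pd.DataFrame  # marker, statistic, p, q, selected
    selected: list[str] = field(default_factory=list)
    intercept: float = np.nan
    coefficients: pd.Series | None = None  # on standardised predictors
    probabilities: pd.Series | None = None  # in-sample pi per sample_id
    oof_probabilities: pd.Series | None = None
    roc: pd.DataFrame | None = None  # fpr, tpr, threshold (in-sample)
    auc_insample: float = np.nan
    auc_oof: float = np.nan
    skipped_reason: str = ""


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[pd.DataFrame, float]:
    """ROC step curve and tie-corrected rank (Mann-Whitney) AUC.

    ``labels`` are 1 for the positive (tumor) class.  AUC is computed from
    midranks, which handles tied scores exactly (all-tied scores give 0.5).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(scores)
    auc = (float(np.sum(ranks[labels == 1])) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # step ROC over the distinct thresholds, highest first
    order = np.argsort(-scores, kind="mergesort")
    s_sorted, l_sorted = scores[order], labels[order]
    tps = np.cumsum(l_sorted == 1)
    fps = np.cumsum(l_sorted == 0)
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    roc = pd.DataFrame(
        {
            "fpr": np.r_[0.0, fps[distinct] / n_neg],
            "tpr": np.r_[0.0, tps[distinct] / n_pos],
            "threshold": np.r_[np.inf, s_sorted[distinct]],
        }
    )
    return roc, float(auc)


def _fit_penalised_logistic(X: np.ndarray, y: np.ndarray, ridge_lambda: float) -> LogisticRegression:
    clf = LogisticRegression(C=1.0 / ridge_lambda, solver="lbfgs", max_iter=10_000)
    clf.fit(X, y)
    return clf


def fit_logistic(
    table: pd.DataFrame,
    selected: Sequence[str],
    positive_group: str = "tumor",
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
    n_folds: int = DEFAULT_N_FOLDS,
    rng_seed: int = 0,
    marker_stats: pd.DataFrame | None = None,
    groups: Sequence | None = None,
) -> MarkerModel:
    """Penalised multivariate logistic regression over the selected markers.

    Predictors are standardised; the ridge penalty (default lambda = 1e-4)
    keeps coefficients finite under perfect separation.  Out-of-fold
    probabilities come from stratified ``n_folds``-fold refits (scaler and
    classifier refit per fold).  When ``groups`` (e.g. pair ids) are given,
    folds never split a group: holding out one member of a tumor-normal pair
    while training on the other leaks the shared pair-level methylation
    baseline and biases the held-out AUC.  The out-of-fold AUC is the mean
    of the per-fold AUCs rather than the AUC of the pooled probabilities,
    which mixes fold-specific probability scales.
    """
    stats_df = marker_stats if marker_stats is not None else pd.DataFrame({"marker": list(selected)})
    if len(selected) == 0:
        return MarkerModel(marker_stats=stats_df, skipped_reason="no marker passed FDR")
    y = (table["group"] == positive_group).to_numpy(dtype=int)
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("need >= 2 samples in each class")
    X = table[list(selected)].to_numpy(dtype=float)
    sample_ids = table["sample_id"].astype(str)

    scaler = StandardScaler().fit(X)
    clf = _fit_penalised_logistic(scaler.transform(X), y, ridge_lambda)
    pi = clf.predict_proba(scaler.transform(X))[:, 1]
    roc, auc_in = roc_auc(pi, y)

    oof = np.full(len(y), np.nan)
    fold_aucs = []
    n_folds_eff = min(n_folds, int(y.sum()), int((1 - y).sum()))
    if n_folds_eff >= 2:
        if groups is not None:
            splitter = StratifiedGroupKFold(n_splits=n_folds_eff, shuffle=True, random_state=rng_seed)
            splits = splitter.split(X, y, groups=np.asarray(groups))
        else:
            splitter = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=rng_seed)
            splits = splitter.split(X, y)
        for train, test in splits:
            sc = StandardScaler().fit(X[train])
            fold_clf = _fit_penalised_logistic(sc.transform(X[train]), y[train], ridge_lambda)
            oof[test] = fold_clf.predict_proba(sc.transform(X[test]))[:, 1]
            if len(set(y[test])) == 2:
                _, fold_auc = roc_auc(oof[test], y[test])
                fold_aucs.append(fold_auc)
        auc_oof = float(np.mean(fold_aucs)) if fold_aucs else np.nan
    else:
        auc_oof = np.nan

    return MarkerModel(
        marker_stats=stats_df,
        selected=list(selected),
        intercept=float(clf.intercept_[0]),
        coefficients=pd.Series(clf.coef_[0], index=list(selected)),
        probabilities=pd.Series(pi, index=sample_ids, name="pi"),
        oof_probabilities=pd.Series(oof, index=sample_ids, name="pi_oof"),
        roc=roc,
        auc_insample=auc_in,
        auc_oof=float(auc_oof),
    )


def run_marker_cascade(
    table: pd.DataFrame,
    design: str = "paired",
    alpha: float = DEFAULT_FDR_ALPHA,
    positive_group: str = "tumor",
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
    n_folds: int = DEFAULT_N_FOLDS,
    rng_seed: int = 0,
) -> MarkerModel:
    """Full cascade: per-marker test -> BH FDR -> logistic model -> ROC/AUC.

    ``design`` is "paired" (Wilcoxon signed-rank per marker) or "groups"
    (Kruskal-Wallis across the group column, e.g. blood cohorts).
    """
    if design not in ("paired", "groups"):
        raise ValueError(f"design must be 'paired' or 'groups', got {design!r}")
    validate_marker_table(table, paired=(design == "paired"))
    markers = marker_columns(table)
    if not markers:
        raise ValueError("marker table has no marker columns")
    records = []
    for m in markers:
        if design == "paired":
            stat, p = marker_test_paired(table, m)
        else:
            stat, p = marker_test_groups(table, m)
        records.append({"marker": m, "statistic": stat, "p": p})
    stats_df = pd.DataFrame(records)
    q, sel = bh_fdr(stats_df["p"].to_numpy(), alpha=alpha)
    stats_df["q"] = q
    stats_df["selected"] = sel
    selected = stats_df.loc[stats_df["selected"], "marker"].tolist()
    if design == "paired":
        return fit_logistic(
            table, selected, positive_group=positive_group, ridge_lambda=ridge_lambda,
            n_folds=n_folds, rng_seed=rng_seed, marker_stats=stats_df,
            groups=table["pair_id"],
        )
    # groups design: binary tumor-vs-rest probability model only when the
    # positive group exists; otherwise report the marker screen alone.
    if positive_group in set(table["group"]):
        binary = table.copy()
        binary["group"] = np.where(binary["group"] == positive_group, positive_group, "other")
        return fit_logistic(
            binary, selected, positive_group=positive_group, ridge_lambda=ridge_lambda,
            n_folds=n_folds, rng_seed=rng_seed, marker_stats=stats_df,
        )
    return MarkerModel(marker_stats=stats_df, selected=selected,
                       skipped_reason=f"group {positive_group!r} absent; marker screen only")


def model_report(model: MarkerModel) -> str:
    """Plain-text summary of a fitted marker cascade."""
    lines = ["Marker cascade report", "=" * 21, ""]
    df = model.marker_stats
    if "p" in df.columns:
        lines.append(f"{'marker':<12}{'statistic':>10}{'p':>12}{'q':>12}  selected")
        for _, row in df.iterrows():
            lines.append(
                f"{row['marker']:<12}{row['statistic']:>10.3f}{row['p']:>12.4g}"
                f"{row['q']:>12.4g}  {'*' if row['selected'] else ''}"
            )
        lines.append("")
    if model.skipped_reason:
        lines.append(f"Model: skipped ({model.skipped_reason})")
    else:
        lines.append(f"Selected markers: {', '.join(model.selected)}")
        lines.append(f"In-sample AUC:   {model.auc_insample:.3f}")
        lines.append(f"Out-of-fold AUC: {model.auc_oof:.3f}")
    return "\n".join(lines)
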