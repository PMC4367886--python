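"""Rule-based classification of read-level methylation architectures.

Deep sequencing of LINE-1 promoter amplicons shows three recurring
single-molecule architectures: loci where molecules are uniformly methylated
(or uniformly unmethylated), allelic methylation where molecules fall into a
nearly-fully-methylated and a nearly-fully-unmethylated class, and patchy
methylation with alternating runs that drive window entropy up and down along
the locus.  The descriptive taxonomy is operationalised here as a transparent
threshold rule over three pieces of evidence:

* the fraction of reads with per-read mean methylation >= ``read_hi`` (f_hi)
  and <= ``read_lo`` (f_lo) — a bimodality summary;
* the mean window entropy;
* the entropy range (max - min) across windows, which separates patchy
  (fluctuating) from allelic (stable) heterogeneity.

Every constant is configurable and echoed in the PatternCall evidence, so a
call is always reproducible from its reported numbers.  ``indeterminate`` is
a first-class outcome: matrices that fit no rule are not forced into the
nearest class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bisulfite_io import MISSING, ReadMethylationMatrix
from .pattern_metrics import EntropyProfile, methylation_entropy

PATTERN_LABELS = (
    "uniform_methylated",
    "uniform_unmethylated",
    "allelic",
    "patchy",
    "indeterminate",
)
TRUE_LABELS = PATTERN_LABELS[:4]


@dataclass(frozen=True)
class PatternConfig:
    """Thresholds of the architecture decision rule."""

    read_hi: float = 0.8  # per-read mean >= read_hi counts as a methylated molecule
    read_lo: float = 0.2  # per-read mean <= read_lo counts as an unmethylated molecule
    uniform_fraction: float = 0.9  # f_hi (or f_lo) needed for a uniform call
    allelic_min_fraction: float = 0.2  # both classes at least this abundant
    allelic_total_fraction: float = 0.8  # f_hi + f_lo needed for an allelic call
    entropy_range: float = 0.3  # max - min window entropy needed for a patchy call
    min_reads: int = 10
    min_cpgs: int = 4


@dataclass
class PatternCall:
    locus_id: str
    sample_id: str
    label: str
    f_hi: float = np.nan
    f_lo: float = np.nan
    mean_entropy: float = np.nan
    entropy_range: float = np.nan
    reason: str = ""
    config: PatternConfig = field(default_factory=PatternConfig)


def classify_pattern(
    matrix: ReadMethylationMatrix,
    entropy: EntropyProfile | None = None,
    config: PatternConfig | None = None,
) -> PatternCall:
    """Assign one architecture label to a reads x CpG matrix.

    Decision order: uniform_methylated (f_hi >= uniform_fraction),
    uniform_unmethylated (f_lo >= uniform_fraction), allelic (both tails
    populated and jointly dominant), patchy (entropy range across windows at
    least ``entropy_range``), else indeterminate.  The two uniform outcomes
    are mutually exclusive by construction (the tails cannot both hold 90% of
    reads).  ``entropy`` defaults to the matrix's own 4-CpG window profile.
    """
    cfg = config or PatternConfig()
    if matrix.n_reads < cfg.min_reads:
        return PatternCall(
            matrix.locus_id, matrix.sample_id, "indeterminate",
            reason=f"only {matrix.n_reads} reads (need >= {cfg.min_reads})", config=cfg,
        )
    if matrix.n_cpg < cfg.min_cpgs:
        return PatternCall(
            matrix.locus_id, matrix.sample_id, "indeterminate",
            reason=f"only {matrix.n_cpg} CpGs (need >= {cfg.min_cpgs})", config=cfg,
        )
    if entropy is None:
        entropy = methylation_entropy(matrix)
    calls = matrix.calls
    observed = calls != MISSING
    n_obs = observed.sum(axis=1)
    valid = n_obs > 0
    read_mean = np.where(valid, ((calls == 1) & observed).sum(axis=1) / np.maximum(n_obs, 1), np.nan)
    read_mean = read_mean[valid]
    if len(read_mean) == 0:
        return PatternCall(
            matrix.locus_id, matrix.sample_id, "indeterminate",
            reason="no read covers any CpG", config=cfg,
        )
    f_hi = float(np.mean(read_mean >= cfg.read_hi))
    f_lo = float(np.mean(read_mean <= cfg.read_lo))
    ent = entropy.entropy[~np.isnan(entropy.entropy)]
    mean_ent = float(np.mean(ent)) if len(ent) else np.nan
    ent_range = float(np.max(ent) - np.min(ent)) if len(ent) else np.nan
    evidence = dict(f_hi=f_hi, f_lo=f_lo, mean_entropy=mean_ent, entropy_range=ent_range)
    if f_hi >= cfg.uniform_fraction:
        label, reason = "uniform_methylated", f"f_hi={f_hi:.3f} >= {cfg.uniform_fraction}"
    elif f_lo >= cfg.uniform_fraction:
        label, reason = "uniform_unmethylated", f"f_lo={f_lo:.3f} >= {cfg.uniform_fraction}"
    elif (
        f_hi >= cfg.allelic_min_fraction
        and f_lo >= cfg.allelic_min_fraction
        and f_hi + f_lo >= cfg.allelic_total_fraction
    ):
        label, reason = "allelic", f"f_hi={f_hi:.3f}, f_lo={f_lo:.3f}, sum={f_hi + f_lo:.3f}"
    elif not np.isnan(ent_range) and ent_range >= cfg.entropy_range:
        label, reason = "patchy", f"entropy range {ent_range:.3f} >= {cfg.entropy_range}"
    else:
        label, reason = "indeterminate", "no rule fired"
    return PatternCall(matrix.locus_id, matrix.sample_id, label, reason=reason, config=cfg, **evidence)


def confusion_report(
    calls: Sequence[PatternCall],
    truth: Mapping[tuple[str, str], str] | Sequence[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Predicted x true confusion matrix and per-class recall.

    ``truth`` is either a sequence aligned with ``calls`` or a mapping from
    (sample_id, locus_id) to the generating architecture.  True labels must
    come from the four generative classes; predictions may additionally be
    indeterminate (5 x 4 matrix).
    """
    if len(calls) == 0:
        raise ValueError("confusion_report requires at least one call")
    if isinstance(truth, Mapping):
        true_labels = [truth[(c.sample_id, c.locus_id)] for c in calls]
    else:
        true_labels = list(truth)
        if len(true_labels) != len(calls):
            raise ValueError("truth sequence length does not match calls")
    bad = sorted(set(true_labels) - set(TRUE_LABELS))
    if bad:
        raise ValueError(f"unknown true labels {bad}; expected one of {TRUE_LABELS}")
    matrix = pd.DataFrame(0, index=list(PATTERN_LABELS), columns=list(TRUE_LABELS))
    for call, t in zip(calls, true_labels):
        matrix.loc[call.label, t] += 1
    totals = matrix.sum(axis=0)
    recall = pd.Series(
        {t: (matrix.loc[t, t] / totals[t] if totals[t] else np.nan) for t in TRUE_LABELS},
        name="recall",
    )
    return matrix, recall


def calls_to_frame(calls: Sequence[PatternCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [c.locus_id for c in calls],
            "sample_id": [c.sample_id for c in calls],
            "label": [c.label for c in calls],
            "f_hi": [c.f_hi for c in calls],
            "f_lo": [c.f_lo for c in calls],
            "mean_entropy": [c.mean_entropy for c in calls],
            "entropy_range": [c.entropy_range for c in calls],
            "reason": [c.reason for c in calls],
        }
    )
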