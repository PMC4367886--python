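"""Ground-truth-known simulation of bisulfite amplicon data.

The generator emulates the statistical structure of a locus-specific LINE-1
promoter methylation study: 11 loci (5 autosomal, 6 X-linked) sharing a common
consensus coordinate frame, paired tumor-normal cohorts of ~20 pairs per
tissue, and read sets of a few hundred molecules per locus.  Single-molecule
methylation patterns come in three architectures observed in deep-sequencing
heat maps:

* ``uniform`` — every CpG on every molecule is an i.i.d. Bernoulli draw at one
  methylation level (uniformly methylated or unmethylated loci);
* ``allelic`` — molecules fall into two classes, one nearly fully methylated
  and one nearly fully unmethylated, mixed at ``allelic_fraction``;
* ``patchy`` — a methylated background in which designated "seed" CpGs are
  demethylated with high probability and demethylation spreads to neighbours
  with geometrically decaying probability (distance in CpG steps).

Only the bisulfite top strand is simulated.  All randomness flows through a
single :class:`numpy.random.Generator`; identical seeds give byte-identical
output.  The default locus set is synthetic: the study's amplicon sequences
are not public, so loci are generated as mutated copies of one fixed scaffold
(internal constant seed) and carry exact consensus CpG maps by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bisulfite_io import LocusReference, ReadMethylationMatrix, find_cpg_positions

# fixed internal seed for the default locus set only; user seeds never touch it
_SCAFFOLD_SEED = 58075

DEFAULT_N_READS = 300
DEFAULT_N_PAIRS = 20
DEFAULT_EFFECTIVE_DEPTH = 100
DEFAULT_CHANGE_THRESHOLD = 10.0

AUTOSOMAL_LOCI = ("L1C2", "L1C6", "L1C10", "L1C11", "L1C20")
X_LINKED_LOCI = ("L1X1", "L1X3", "L1X4", "L1X5", "L1X6", "L1X8")


# ---------------------------------------------------------------------------
# epiallele models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EpialleleModel:
    """Generative model for single-molecule methylation patterns.

    ``base_methylation`` may be a scalar or a per-CpG vector of Bernoulli
    parameters.  ``allelic_fraction`` is the mixture weight of the methylated
    molecule class (allelic kind).  For the patchy kind, each CpG listed in
    ``seed_cpg_indices`` is demethylated with ``seed_demethylation_prob`` and
    its neighbours with that probability times ``spread_decay`` per CpG step
    of distance, independently per seed and molecule.
    """

    kind: str
    base_methylation: float | tuple[float, ...] = 0.9
    allelic_fraction: float = 0.5
    seed_cpg_indices: tuple[int, ...] = ()
    seed_demethylation_prob: float = 0.0
    spread_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "allelic", "patchy"):
            raise ValueError(f"invalid epiallele kind {self.kind!r}")
        base = np.atleast_1d(np.asarray(self.base_methylation, dtype=float))
        for name, val in (
            ("base_methylation", base),
            ("allelic_fraction", np.atleast_1d(self.allelic_fraction)),
            ("seed_demethylation_prob", np.atleast_1d(self.seed_demethylation_prob)),
            ("spread_decay", np.atleast_1d(self.spread_decay)),
        ):
            if np.any(np.asarray(val) < 0) or np.any(np.asarray(val) > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.kind != "patchy" and self.seed_cpg_indices:
            raise ValueError("seed_cpg_indices only allowed for kind='patchy'")

    def _base_vector(self, n_cpg: int) -> np.ndarray:
        base = np.asarray(self.base_methylation, dtype=float)
        if base.ndim == 0:
            return np.full(n_cpg, float(base))
        if base.shape != (n_cpg,):
            raise ValueError(f"base_methylation length {base.shape} != n_cpg {n_cpg}")
        return base

    def _validate_seeds(self, n_cpg: int) -> None:
        for s in self.seed_cpg_indices:
            if not 0 <= s < n_cpg:
                raise ValueError(f"seed CpG index {s} outside [0, {n_cpg})")

    def demethylation_survival(self, n_cpg: int) -> np.ndarray:
        """Per-CpG probability of escaping every seed's demethylation."""
        survive = np.ones(n_cpg)
        idx = np.arange(n_cpg)
        for s in self.seed_cpg_indices:
            q = self.seed_demethylation_prob * np.where(
                idx == s, 1.0, self.spread_decay ** np.abs(idx - s)
            )
            survive *= 1.0 - q
        return survive

    def analytic_mean(self, n_cpg: int) -> np.ndarray:
        """Expected methylation probability at each CpG under this model."""
        base = self._base_vector(n_cpg)
        if self.kind == "uniform":
            return base
        if self.kind == "allelic":
            return self.allelic_fraction * base + (1.0 - self.allelic_fraction) * (1.0 - base)
        self._validate_seeds(n_cpg)
        return base * self.demethylation_survival(n_cpg)


def draw_epialleles(
    model: EpialleleModel, n_cpg: int, n_reads: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_reads`` methylation state vectors (1 = M, 0 = U)."""
    if n_cpg < 1:
        raise ValueError("n_cpg must be >= 1")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    base = model._base_vector(n_cpg)
    if model.kind == "uniform":
        return (rng.random((n_reads, n_cpg)) < base).astype(np.int8)
    if model.kind == "allelic":
        high = rng.random(n_reads) < model.allelic_fraction
        probs = np.where(high[:, None], base[None, :], (1.0 - base)[None, :])
        return (rng.random((n_reads, n_cpg)) < probs).astype(np.int8)
    model._validate_seeds(n_cpg)
    states = rng.random((n_reads, n_cpg)) < base
    idx = np.arange(n_cpg)
    for s in model.seed_cpg_indices:
        q = model.seed_demethylation_prob * np.where(
            idx == s, 1.0, model.spread_decay ** np.abs(idx - s)
        )
        states &= ~(rng.random((n_reads, n_cpg)) < q)
    return states.astype(np.int8)


def draw_epiallele(model: EpialleleModel, n_cpg: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a single methylation state vector."""
    return draw_epialleles(model, n_cpg, 1, rng)[0]


def canonical_model(kind: str, n_cpg: int | None = None) -> EpialleleModel:
    """Well-separated reference parameterisations of the three architectures.

    These are the documented defaults behind the pattern-recovery studies:
    uniform at 0.95 (or 0.05 for the unmethylated face), an even allelic
    mixture of 0.95/0.05 molecule classes, and a 0.95-methylated background
    with three strong, locally spreading seeds (demethylation probability
    0.9, spread decay 0.3) at the quartile CpGs of the locus.  The patchy
    spreading is kept local so the entropy track fluctuates — high around
    seeds, low over the protected background — rather than being uniformly
    elevated.
    """
    if kind == "uniform_methylated":
        return EpialleleModel(kind="uniform", base_methylation=0.95)
    if kind == "uniform_unmethylated":
        return EpialleleModel(kind="uniform", base_methylation=0.05)
    if kind == "allelic":
        return EpialleleModel(kind="allelic", base_methylation=0.95, allelic_fraction=0.5)
    if kind == "patchy":
        if n_cpg is None:
            raise ValueError("patchy canonical model needs n_cpg to place seeds")
        seeds = tuple(int(round(q * (n_cpg - 1))) for q in (0.2, 0.5, 0.8))
        return EpialleleModel(
            kind="patchy",
            base_methylation=0.95,
            seed_cpg_indices=seeds,
            seed_demethylation_prob=0.9,
            spread_decay=0.3,
        )
    raise ValueError(f"unknown canonical kind {kind!r}")


# ---------------------------------------------------------------------------
# bisulfite conversion of a state vector into a read sequence
# ---------------------------------------------------------------------------


def bisulfite_convert(
    reference_segment: str,
    states: Sequence[int] | np.ndarray,
    conversion_failure_rate: float = 0.0,
    inappropriate_conversion_rate: float = 0.0,
    sequencing_error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> str:
    """Render one molecule's methylation states as a bisulfite-converted read.

    Unmethylated cytosines deaminate and are sequenced as T; methylated CpG
    cytosines resist conversion and stay C.  ``conversion_failure_rate`` is
    the chance an unmethylated C escapes conversion (read as C);
    ``inappropriate_conversion_rate`` the chance a methylated C converts
    anyway (read as T).  A final uniform per-base substitution layer applies
    ``sequencing_error_rate``.  Top strand only.
    """
    if rng is None:
        rng = np.random.default_rng()
    for name, r in (
        ("conversion_failure_rate", conversion_failure_rate),
        ("inappropriate_conversion_rate", inappropriate_conversion_rate),
        ("sequencing_error_rate", sequencing_error_rate),
    ):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    seq = reference_segment.upper()
    cpg_positions = find_cpg_positions(seq)
    states = np.asarray(states)
    if states.shape != (len(cpg_positions),):
        raise ValueError(
            f"states length {states.shape} does not match {len(cpg_positions)} CpGs in segment"
        )
    out = list(seq)
    cpg_set = set(cpg_positions)
    for i, b in enumerate(seq):
        if b == "C" and i not in cpg_set:
            if rng.random() >= conversion_failure_rate:
                out[i] = "T"
    for p, st in zip(cpg_positions, states):
        if st == 1:
            out[p] = "T" if rng.random() < inappropriate_conversion_rate else "C"
        else:
            out[p] = "C" if rng.random() < conversion_failure_rate else "T"
    if sequencing_error_rate > 0.0:
        err = rng.random(len(out)) < sequencing_error_rate
        alphabet = "ACGT"
        for i in np.flatnonzero(err):
            choices = [c for c in alphabet if c != out[i]]
            out[i] = choices[rng.integers(3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Everything needed to simulate one cohort, including the RNG seed."""

    loci: list[LocusReference]
    tumor_models: Mapping[str, EpialleleModel]
    normal_models: Mapping[str, EpialleleModel]
    n_reads: int = DEFAULT_N_READS
    conversion_failure_rate: float = 0.0
    inappropriate_conversion_rate: float = 0.0
    sequencing_error_rate: float = 0.0
    n_pairs: int = DEFAULT_N_PAIRS
    effective_depth: int = DEFAULT_EFFECTIVE_DEPTH
    change_threshold: float = DEFAULT_CHANGE_THRESHOLD
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.effective_depth < 1:
            raise ValueError("effective_depth must be >= 1")
        for name in ("conversion_failure_rate", "inappropriate_conversion_rate", "sequencing_error_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for locus in self.loci:
            for side, models in (("tumor", self.tumor_models), ("normal", self.normal_models)):
                if locus.locus_id not in models:
                    raise ValueError(f"no {side} model for locus {locus.locus_id}")

    def model_for(self, locus_id: str, condition: str) -> EpialleleModel:
        if condition == "tumor":
            return self.tumor_models[locus_id]
        if condition == "normal":
            return self.normal_models[locus_id]
        raise ValueError(f"condition must be 'tumor' or 'normal', got {condition!r}")


@dataclass
class GroundTruth:
    """Truth recorded alongside simulated data, keyed by (sample_id, locus_id)."""

    read_states: dict = field(default_factory=dict)  # -> reads x n_cpg int8 {0,1}
    per_cpg_mean: dict = field(default_factory=dict)  # realized mean of read_states
    model_mean: dict = field(default_factory=dict)  # analytic per-CpG probability
    pattern_kind: dict = field(default_factory=dict)  # generating architecture
    cohort: pd.DataFrame | None = None  # pair_id, locus_id, true_delta, expected_label

    def update(self, other: "GroundTruth") -> None:
        self.read_states.update(other.read_states)
        self.per_cpg_mean.update(other.per_cpg_mean)
        self.model_mean.update(other.model_mean)
        self.pattern_kind.update(other.pattern_kind)


# ---------------------------------------------------------------------------
# sample- and cohort-level simulation
# ---------------------------------------------------------------------------


def simulate_matrix(
    model: EpialleleModel,
    n_cpg: int,
    n_reads: int,
    rng: np.random.Generator,
    locus_id: str = "locus",
    sample_id: str = "sample",
) -> ReadMethylationMatrix:
    """Draw a reads x CpG matrix of true states directly (no sequencing layer)."""
    states = draw_epialleles(model, n_cpg, n_reads, rng)
    return ReadMethylationMatrix(locus_id=locus_id, sample_id=sample_id, calls=states)


def simulate_sample(
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], GroundTruth]:
    """Simulate one sample: per-locus bisulfite reads plus ground truth.

    Returns ``(reads_by_locus, truth)`` where each read is an
    ``(id, sequence)`` tuple.  ``condition`` selects the tumor or normal
    epiallele model per locus.
    """
    if condition not in ("tumor", "normal"):
        raise ValueError(f"condition must be 'tumor' or 'normal', got {condition!r}")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if sample_id is None:
        sample_id = condition
    truth = GroundTruth()
    reads_by_locus: dict[str, list[tuple[str, str]]] = {}
    for locus in config.loci:
        model = config.model_for(locus.locus_id, condition)
        states = draw_epialleles(model, locus.n_cpg, config.n_reads, rng)
        reads = []
        for i, row in enumerate(states):
            seq = bisulfite_convert(
                locus.sequence,
                row,
                conversion_failure_rate=config.conversion_failure_rate,
                inappropriate_conversion_rate=config.inappropriate_conversion_rate,
                sequencing_error_rate=config.sequencing_error_rate,
                rng=rng,
            )
            reads.append((f"{sample_id}|{locus.locus_id}|read_{i}", seq))
        key = (sample_id, locus.locus_id)
        reads_by_locus[locus.locus_id] = reads
        truth.read_states[key] = states
        truth.per_cpg_mean[key] = states.mean(axis=0)
        truth.model_mean[key] = model.analytic_mean(locus.n_cpg)
        truth.pattern_kind[key] = model.kind
    return reads_by_locus, truth


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a paired tumor-normal cohort of per-locus mean methylation.

    Each sample's per-locus value is a binomial proportion at
    ``effective_depth`` around the model's mean methylation (pyrosequencing-
    style measurement noise), reported on the 0-100 scale.  Returns a wide
    marker table (sample_id, pair_id, group, one column per locus) plus
    ground truth with the model-level delta and expected change label per
    pair and locus.
    """
    rng = np.random.default_rng(config.rng_seed)
    rows = []
    truth_rows = []
    locus_means = {}
    for locus in config.loci:
        p_t = float(np.mean(config.model_for(locus.locus_id, "tumor").analytic_mean(locus.n_cpg)))
        p_n = float(np.mean(config.model_for(locus.locus_id, "normal").analytic_mean(locus.n_cpg)))
        locus_means[locus.locus_id] = (p_t, p_n)
    for i in range(config.n_pairs):
        pair_id = f"P{i + 1:03d}"
        for group in ("tumor", "normal"):
            row = {"sample_id": f"{pair_id}_{group[0].upper()}", "pair_id": pair_id, "group": group}
            for locus in config.loci:
                p = locus_means[locus.locus_id][0 if group == "tumor" else 1]
                value = rng.binomial(config.effective_depth, p) / config.effective_depth * 100.0
                row[locus.locus_id] = value
            rows.append(row)
        for locus in config.loci:
            p_t, p_n = locus_means[locus.locus_id]
            delta = (p_t - p_n) * 100.0
            if delta < -config.change_threshold:
                label = "hypomethylated"
            elif delta > config.change_threshold:
                label = "hypermethylated"
            else:
                label = "unchanged"
            truth_rows.append(
                {"pair_id": pair_id, "locus_id": locus.locus_id, "true_delta": delta, "expected_label": label}
            )
    table = pd.DataFrame(rows)
    truth = GroundTruth(cohort=pd.DataFrame(truth_rows))
    return table, truth


def simulate_marker_table(
    n_pairs: int = DEFAULT_N_PAIRS,
    markers: Sequence[str] | int = 14,
    base_level: float = 75.0,
    tumor_shifts: Mapping[str, float] | None = None,
    marker_sd: float = 5.0,
    pair_sd: float = 5.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Paired marker table with Gaussian per-marker noise (percentage points).

    Each value is ``base + pair_offset + shift(group, marker) + N(0, marker_sd)``
    clipped to [0, 100]; pair offsets are shared between the tumor and normal
    member of a pair (N(0, pair_sd)).  ``tumor_shifts`` maps marker name to
    the tumor-minus-normal shift in points (default: no effect anywhere — a
    null cohort).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if isinstance(markers, int):
        markers = [f"M{j + 1:02d}" for j in range(markers)]
    tumor_shifts = dict(tumor_shifts or {})
    rows = []
    for i in range(n_pairs):
        pair_id = f"P{i + 1:03d}"
        offsets = {m: rng.normal(0.0, pair_sd) for m in markers}
        for group in ("tumor", "normal"):
            row = {"sample_id": f"{pair_id}_{group[0].upper()}", "pair_id": pair_id, "group": group}
            for m in markers:
                shift = tumor_shifts.get(m, 0.0) if group == "tumor" else 0.0
                row[m] = float(np.clip(base_level + offsets[m] + shift + rng.normal(0.0, marker_sd), 0.0, 100.0))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# default locus set (synthetic scaffold + mutated copies)
# ---------------------------------------------------------------------------


def _strip_unintended_cpgs(seq: list[str], keep: set[int]) -> None:
    i = 0
    while i < len(seq) - 1:
        if seq[i] == "C" and seq[i + 1] == "G" and i not in keep:
            seq[i + 1] = "A"
        i += 1


def consensus_scaffold(
    n_cpg: int = 28,
    spacing: int | None = None,
    rng_seed: int = _SCAFFOLD_SEED,
) -> tuple[str, tuple[int, ...]]:
    """Build a CpG-island-like scaffold sequence with known CpG positions.

    ``spacing`` fixes the C-to-C distance between consecutive CpGs (useful
    for planting hotspots at exact base-pair intervals); when None, spacings
    are drawn uniformly from 12-40 bp with a fixed internal seed, giving an
    irregular promoter-like CpG density.  Returns (sequence, cpg_positions).
    """
    rng = np.random.default_rng(rng_seed)
    alphabet = np.array(list("ACGT"))
    lead = list(alphabet[rng.integers(4, size=15)])
    seq: list[str] = lead
    positions = []
    for j in range(n_cpg):
        if j > 0:
            gap = (spacing - 2) if spacing is not None else int(rng.integers(10, 39))
            seq.extend(alphabet[rng.integers(4, size=gap)])
        positions.append(len(seq))
        seq.extend(["C", "G"])
    seq.extend(alphabet[rng.integers(4, size=15)])
    _strip_unintended_cpgs(seq, set(positions))
    return "".join(seq), tuple(positions)


def mutate_scaffold(
    scaffold: str,
    cpg_positions: Sequence[int],
    locus_id: str,
    chromosome_class: str,
    rng: np.random.Generator,
    substitution_rate: float = 0.02,
    cpg_loss_rate: float = 0.12,
) -> LocusReference:
    """Derive one locus from the scaffold by point substitutions and CpG loss.

    Substitutions (to A or T, which can never create a new CpG) avoid the two
    bases of retained CpGs; a random subset of scaffold CpGs is lost
    (CG -> CA) and dropped from the locus CpG list and consensus map.
    """
    seq = list(scaffold)
    n = len(cpg_positions)
    keep = np.ones(n, dtype=bool)
    n_lose = int(round(cpg_loss_rate * n))
    if n_lose:
        lost = rng.choice(n, size=n_lose, replace=False)
        keep[lost] = False
    protected = set()
    for j, p in enumerate(cpg_positions):
        if keep[j]:
            protected.update((p, p + 1))
        else:
            seq[p + 1] = "A"
    for i in range(len(seq)):
        if i in protected:
            continue
        if rng.random() < substitution_rate:
            seq[i] = "A" if rng.random() < 0.5 else "T"
    kept_idx = [j for j in range(n) if keep[j]]
    return LocusReference(
        locus_id=locus_id,
        sequence="".join(seq),
        cpg_positions=tuple(cpg_positions[j] for j in kept_idx),
        chromosome_class=chromosome_class,
        consensus_cpg_index=tuple(kept_idx),
        consensus_bp_position=tuple(cpg_positions[j] for j in kept_idx),
    )


def default_loci(
    n_cpg: int = 28,
    spacing: int | None = None,
    cpg_loss_rate: float = 0.12,
) -> list[LocusReference]:
    """The default 11-locus set: 5 autosomal and 6 X-linked LINE-1 promoters.

    All loci derive from one shared scaffold (fixed internal seed) and carry
    consensus CpG maps into the scaffold frame.  Deterministic: repeated
    calls return identical loci regardless of any user-level seeding.
    """
    scaffold, positions = consensus_scaffold(n_cpg=n_cpg, spacing=spacing)
    rng = np.random.default_rng(_SCAFFOLD_SEED + 1)
    loci = []
    for locus_id in AUTOSOMAL_LOCI:
        loci.append(mutate_scaffold(scaffold, positions, locus_id, "autosomal", rng, cpg_loss_rate=cpg_loss_rate))
    for locus_id in X_LINKED_LOCI:
        loci.append(mutate_scaffold(scaffold, positions, locus_id, "X_linked", rng, cpg_loss_rate=cpg_loss_rate))
    return loci


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path, quality: int = 40) -> None:
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def _model_to_dict(model: EpialleleModel) -> dict:
    base = model.base_methylation
    d = {"kind": model.kind, "base_methylation": list(base) if isinstance(base, tuple) else base}
    if model.kind == "allelic":
        d["allelic_fraction"] = model.allelic_fraction
    if model.kind == "patchy":
        d["seed_cpg_indices"] = list(model.seed_cpg_indices)
        d["seed_demethylation_prob"] = model.seed_demethylation_prob
        d["spread_decay"] = model.spread_decay
    return d


def _model_from_dict(d: Mapping) -> EpialleleModel:
    kwargs = dict(d)
    if "base_methylation" in kwargs and isinstance(kwargs["base_methylation"], list):
        kwargs["base_methylation"] = tuple(kwargs["base_methylation"])
    if "seed_cpg_indices" in kwargs:
        kwargs["seed_cpg_indices"] = tuple(kwargs["seed_cpg_indices"])
    return EpialleleModel(**kwargs)


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    """Serialise a SimulationConfig (default loci are written as 'default')."""
    doc = {
        "loci": "default",
        "n_reads": config.n_reads,
        "conversion_failure_rate": config.conversion_failure_rate,
        "inappropriate_conversion_rate": config.inappropriate_conversion_rate,
        "sequencing_error_rate": config.sequencing_error_rate,
        "n_pairs": config.n_pairs,
        "effective_depth": config.effective_depth,
        "change_threshold": config.change_threshold,
        "rng_seed": config.rng_seed,
        "models": {
            locus.locus_id: {
                "tumor": _model_to_dict(config.tumor_models[locus.locus_id]),
                "normal": _model_to_dict(config.normal_models[locus.locus_id]),
            }
            for locus in config.loci
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def config_from_yaml(path: str | Path, loci: list[LocusReference] | None = None) -> SimulationConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if loci is None:
        if doc.get("loci", "default") != "default":
            raise ValueError("non-default loci must be passed explicitly to config_from_yaml")
        loci = default_loci()
    models = doc.get("models", {})
    default_entry = models.get("default")
    tumor_models, normal_models = {}, {}
    for locus in loci:
        entry = models.get(locus.locus_id, default_entry)
        if entry is None:
            raise ValueError(f"no model entry for locus {locus.locus_id}")
        tumor_models[locus.locus_id] = _model_from_dict(entry["tumor"])
        normal_models[locus.locus_id] = _model_from_dict(entry["normal"])
    return SimulationConfig(
        loci=loci,
        tumor_models=tumor_models,
        normal_models=normal_models,
        n_reads=int(doc.get("n_reads", DEFAULT_N_READS)),
        conversion_failure_rate=float(doc.get("conversion_failure_rate", 0.0)),
        inappropriate_conversion_rate=float(doc.get("inappropriate_conversion_rate", 0.0)),
        sequencing_error_rate=float(doc.get("sequencing_error_rate", 0.0)),
        n_pairs=int(doc.get("n_pairs", DEFAULT_N_PAIRS)),
        effective_depth=int(doc.get("effective_depth", DEFAULT_EFFECTIVE_DEPTH)),
        change_threshold=float(doc.get("change_threshold", DEFAULT_CHANGE_THRESHOLD)),
        rng_seed=int(doc.get("rng_seed", 0)),
    )
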