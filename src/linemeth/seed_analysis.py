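"""Consensus-coordinate projection and hypomethylation hotspot ("seed") analysis.

The individually assayed LINE-1 promoter loci share a common consensus frame
(CpG indices plus representative base-pair positions).  Projecting every
(locus, sample) per-CpG profile onto that frame and averaging reveals CpG
sites that are recurrently hypomethylated across samples, loci, and tissues —
candidate "seeds" from which demethylation may spread — alongside sites that
remain protected.  Hotspots are called on the tumor-minus-normal delta track
as local minima that fall robustly below the track's centre (median minus
k * MAD, with an absolute depth floor); protected sites are the mirrored
local maxima.  Spacings between consecutive hypomethylated hotspots are
reported in base pairs, with the fraction falling in the 40-60 and 80-100 nt
bands in which recurrent hypomethylated CpGs tend to be separated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bisulfite_io import LocusReference
from .pattern_metrics import MethylationProfile

DEFAULT_MIN_OBS = 3
DEFAULT_MAD_K = 1.5
DEFAULT_MIN_PROMINENCE = 0.10  # absolute delta depth floor, fraction scale
DEFAULT_SPACING_BANDS = ((40, 60), (80, 100))


@dataclass
class ConsensusProfile:
    """Mean methylation per consensus CpG index for one sample group."""

    group: str
    indices: np.ndarray  # strictly increasing consensus CpG indices
    bp_positions: np.ndarray  # representative base-pair position per index
    mean: np.ndarray  # NaN where n_obs < min_obs
    n_obs: np.ndarray
    min_obs: int = DEFAULT_MIN_OBS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "consensus_cpg_index": self.indices,
                "consensus_bp_position": self.bp_positions,
                "mean_methylation": self.mean,
                "n_obs": self.n_obs,
            }
        )


@dataclass
class HotspotSet:
    """Hypomethylation-prone and protected consensus CpG indices."""

    hypo_indices: np.ndarray
    protected_indices: np.ndarray
    spacings_bp: np.ndarray  # between consecutive hypomethylated hotspots
    delta: np.ndarray  # tumor - normal per shared consensus index
    indices: np.ndarray  # shared consensus indices the delta is defined on
    bp_positions: np.ndarray


def build_consensus_profile(
    profiles: Sequence[MethylationProfile],
    references: Mapping[str, LocusReference],
    group: str = "all",
    min_obs: int = DEFAULT_MIN_OBS,
) -> ConsensusProfile:
    """Unweighted mean over all (locus, sample) observations per consensus index.

    Every profile's locus must carry a consensus CpG map; per-CpG means that
    are NaN (low coverage) do not contribute.  Indices supported by fewer
    than ``min_obs`` observations get NaN means but stay in the profile.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    bp: dict[int, int] = {}
    mapped_any = False
    for prof in profiles:
        ref = references.get(prof.locus_id)
        if ref is None:
            raise KeyError(f"no reference provided for locus {prof.locus_id}")
        if ref.consensus_cpg_index is None:
            raise ValueError(f"{prof.locus_id}: reference carries no consensus CpG map")
        if len(ref.consensus_cpg_index) != prof.n_cpg:
            raise ValueError(f"{prof.locus_id}: profile/consensus map length mismatch")
        bp_positions = ref.consensus_bp_position or ref.consensus_cpg_index
        for local_j, (ci, pos) in enumerate(zip(ref.consensus_cpg_index, bp_positions)):
            val = prof.mean[local_j]
            if np.isnan(val):
                continue
            mapped_any = True
            sums[ci] = sums.get(ci, 0.0) + float(val)
            counts[ci] = counts.get(ci, 0) + 1
            bp.setdefault(ci, int(pos))
    if not mapped_any:
        raise ValueError("no profile observation maps to any consensus index")
    indices = np.array(sorted(counts), dtype=int)
    n_obs = np.array([counts[i] for i in indices])
    mean = np.array([sums[i] / counts[i] for i in indices])
    mean = np.where(n_obs >= min_obs, mean, np.nan)
    return ConsensusProfile(
        group=group,
        indices=indices,
        bp_positions=np.array([bp[i] for i in indices]),
        mean=mean,
        n_obs=n_obs,
        min_obs=min_obs,
    )


def _local_extrema(values: np.ndarray, kind: str) -> np.ndarray:
    """Indices of strict local minima/maxima; endpoints compare to one neighbour."""
    n = len(values)
    if n < 2:
        return np.array([], dtype=int)
    out = []
    for i in range(n):
        left = values[i - 1] if i > 0 else None
        right = values[i + 1] if i < n - 1 else None
        if kind == "min":
            ok = (left is None or values[i] < left) and (right is None or values[i] < right)
        else:
            ok = (left is None or values[i] > left) and (right is None or values[i] > right)
        if ok:
            out.append(i)
    return np.array(out, dtype=int)


def find_hotspots(
    tumor: ConsensusProfile,
    normal: ConsensusProfile,
    k: float = DEFAULT_MAD_K,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_shared: int = 8,
) -> HotspotSet:
    """Call hypomethylation hotspots and protected sites on the delta track.

    The delta (tumor - normal, fraction scale) is computed on consensus
    indices defined in both profiles.  A hypomethylated hotspot is a strict
    local minimum of delta at least ``k`` MADs below the median delta and at
    least ``min_prominence`` below it in absolute terms; protected sites are
    the mirrored local maxima.  The absolute floor keeps sampling noise on a
    near-flat track (where the MAD itself is noise-sized) from being flagged.
    The rule is invariant to adding a constant to all deltas.
    """
    t_map = dict(zip(tumor.indices.tolist(), tumor.mean))
    n_map = dict(zip(normal.indices.tolist(), normal.mean))
    bp_map = dict(zip(tumor.indices.tolist(), tumor.bp_positions.tolist()))
    bp_map.update(zip(normal.indices.tolist(), normal.bp_positions.tolist()))
    shared = sorted(
        i for i in set(t_map) & set(n_map)
        if not np.isnan(t_map[i]) and not np.isnan(n_map[i])
    )
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared consensus indices (need >= {min_shared})")
    indices = np.array(shared, dtype=int)
    delta = np.array([t_map[i] - n_map[i] for i in shared])
    bp_positions = np.array([bp_map[i] for i in shared])
    med = float(np.median(delta))
    mad = float(np.median(np.abs(delta - med)))
    low_cut = med - max(k * mad, min_prominence)
    high_cut = med + max(k * mad, min_prominence)
    minima = _local_extrema(delta, "min")
    maxima = _local_extrema(delta, "max")
    hypo = indices[[i for i in minima if delta[i] <= low_cut]]
    protected = indices[[i for i in maxima if delta[i] >= high_cut]]
    hypo_bp = np.array([bp_map[i] for i in hypo])
    spacings = np.diff(np.sort(hypo_bp)) if len(hypo) >= 2 else np.array([], dtype=int)
    return HotspotSet(
        hypo_indices=hypo,
        protected_indices=protected,
        spacings_bp=spacings,
        delta=delta,
        indices=indices,
        bp_positions=bp_positions,
    )


def hotspot_periodicity(
    hotspots: HotspotSet,
    bands: Sequence[tuple[int, int]] = DEFAULT_SPACING_BANDS,
) -> dict:
    """Spacing summary between consecutive hypomethylated hotspots.

    Returns median and IQR of the base-pair spacings plus the fraction of
    spacings in each configured band (defaults: 40-60 and 80-100 nt).
    With fewer than two hotspots the summary is empty (NaN / zero counts).
    """
    s = np.asarray(hotspots.spacings_bp, dtype=float)
    out: dict = {"n_spacings": int(len(s))}
    if len(s) == 0:
        out.update({"median": np.nan, "iqr": np.nan})
        for lo, hi in bands:
            out[f"frac_{lo}_{hi}"] = np.nan
        return out
    q1, q3 = np.percentile(s, [25, 75])
    out.update({"median": float(np.median(s)), "iqr": float(q3 - q1)})
    for lo, hi in bands:
        out[f"frac_{lo}_{hi}"] = float(np.mean((s >= lo) & (s <= hi)))
    return out


def inter_sample_profile_correlation(
    profiles: Sequence[MethylationProfile],
    min_shared: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation of per-CpG profiles at one locus.

    Each pair is correlated over CpGs with defined means in both samples
    (average ranks for ties).  Pairs sharing fewer than ``min_shared`` CpGs,
    or involving a constant profile, get NaN.
    """
    locus_ids = {p.locus_id for p in profiles}
    if len(locus_ids) > 1:
        raise ValueError(f"profiles span multiple loci: {sorted(locus_ids)}")
    names = [p.sample_id for p in profiles]
    k = len(profiles)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = profiles[i].mean, profiles[j].mean
            shared = ~np.isnan(a) & ~np.isnan(b)
            if shared.sum() < min_shared:
                r, p = np.nan, np.nan
            else:
                x, y = a[shared], b[shared]
                if np.all(x == x[0]) or np.all(y == y[0]):
                    r, p = np.nan, np.nan
                else:
                    r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    return pd.DataFrame(rho, index=names, columns=names), pd.DataFrame(pmat, index=names, columns=names)


# ---------------------------------------------------------------------------
# consensus map I/O
# ---------------------------------------------------------------------------


def write_consensus_map(references: Sequence[LocusReference], path: str | Path) -> None:
    """TSV: locus_id, local_cpg_index, consensus_cpg_index, consensus_bp_position."""
    with open(path, "w") as fh:
        fh.write("locus_id\tlocal_cpg_index\tconsensus_cpg_index\tconsensus_bp_position\n")
        for ref in references:
            if ref.consensus_cpg_index is None:
                continue
            bp = ref.consensus_bp_position or ref.consensus_cpg_index
            for local_j, (ci, pos) in enumerate(zip(ref.consensus_cpg_index, bp)):
                fh.write(f"{ref.locus_id}\t{local_j}\t{ci}\t{pos}\n")


def load_consensus_map(path: str | Path) -> dict[str, tuple[tuple[int, ...], tuple[int, ...]]]:
    """Read a consensus map TSV into locus_id -> (consensus indices, bp positions)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for locus_id, grp in df.groupby("locus_id"):
        grp = grp.sort_values("local_cpg_index")
        out[str(locus_id)] = (
            tuple(int(i) for i in grp["consensus_cpg_index"]),
            tuple(int(p) for p in grp["consensus_bp_position"]),
        )
    return out


def apply_consensus_map(
    ref: LocusReference,
    consensus_map: Mapping[str, tuple[tuple[int, ...], tuple[int, ...]]],
) -> LocusReference:
    """Return a copy of ``ref`` carrying the map entries for its locus."""
    if ref.locus_id not in consensus_map:
        raise KeyError(f"no consensus map entry for {ref.locus_id}")
    indices, bp = consensus_map[ref.locus_id]
    return LocusReference(
        locus_id=ref.locus_id,
        sequence=ref.sequence,
        cpg_positions=ref.cpg_positions,
        chromosome_class=ref.chromosome_class,
        consensus_cpg_index=indices,
        consensus_bp_position=bp,
    )


def consensus_map_from_alignment(aligned_fasta: str | Path) -> dict[str, tuple[tuple[int, ...], tuple[int, ...]]]:
    """Build a consensus map from an aligned-FASTA multiple sequence alignment.

    Alignment columns define the consensus frame: every column in which at
    least one sequence has a CpG becomes a consensus CpG index (numbered in
    column order), with the ungapped column offset in the first sequence as
    the representative base-pair position.  Each locus maps its own CpGs to
    those indices.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(aligned_fasta), "fasta"))
    if not records:
        raise ValueError(f"no records in {aligned_fasta}")
    seqs = {r.id: str(r.seq).upper() for r in records}
    length = len(next(iter(seqs.values())))
    if any(len(s) != length for s in seqs.values()):
        raise ValueError("aligned FASTA records have unequal lengths")

    def next_base_col(seq: str, col: int) -> int | None:
        for c in range(col + 1, len(seq)):
            if seq[c] != "-":
                return c
        return None

    cpg_cols: set[int] = set()
    locus_cpg_cols: dict[str, list[int]] = {rid: [] for rid in seqs}
    for rid, seq in seqs.items():
        for col, base in enumerate(seq):
            if base != "C":
                continue
            nxt = next_base_col(seq, col)
            if nxt is not None and seq[nxt] == "G":
                cpg_cols.add(col)
                locus_cpg_cols[rid].append(col)
    ordered_cols = sorted(cpg_cols)
    col_to_index = {c: i for i, c in enumerate(ordered_cols)}
    first = str(records[0].seq).upper()
    col_to_bp = {}
    bp = 0
    for col, base in enumerate(first):
        col_to_bp[col] = bp
        if base != "-":
            bp += 1
    out = {}
    for rid, cols in locus_cpg_cols.items():
        out[rid] = (
            tuple(col_to_index[c] for c in cols),
            tuple(col_to_bp[c] for c in cols),
        )
    return out
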