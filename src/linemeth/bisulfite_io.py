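"""Reference handling, bisulfite-aware read alignment, and per-read methylation calling.

Bisulfite treatment deaminates unmethylated cytosines to uracil (sequenced as T)
while 5-methylcytosine resists conversion and is sequenced as C.  A read from a
bisulfite amplicon therefore differs from its genomic reference at every
unmethylated C.  Alignment here scores a read T against a reference C as a match
(the expected conversion) while a read C against a reference T stays a mismatch,
so methylation state never biases alignment placement.

Coordinates are 0-based, half-open throughout; BED input follows the standard
dialect.  Only the top (sense) strand is modelled: reverse-complement reads are
recognised by aligning both orientations and keeping the better score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

# methylation call codes used in every reads x CpG matrix
METHYLATED = 1
UNMETHYLATED = 0
MISSING = -1

# alignment scoring (shared with the test oracle's parameterisation)
MATCH_SCORE = 2.0
MISMATCH_SCORE = -3.0
GAP_OPEN_SCORE = -5.0
GAP_EXTEND_SCORE = -2.0

DEFAULT_MIN_IDENTITY = 0.80
DEFAULT_MIN_ALIGNED_FRACTION = 0.5  # of read length; guards against clipped overlaps
DEFAULT_MAX_RETENTION = 0.05
MIN_READ_LENGTH = 20

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_cpg_positions(sequence: str) -> list[int]:
    """Offsets of the C of every CpG dinucleotide in ``sequence``."""
    seq = sequence.upper()
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


@dataclass(frozen=True)
class LocusReference:
    """One LINE-1 promoter amplicon reference.

    Parameters
    ----------
    locus_id
        Identifier such as ``L1C2`` (autosomal) or ``L1X8`` (X-linked).
    sequence
        Genomic (unconverted) top-strand sequence.
    cpg_positions
        Strictly increasing 0-based offsets of the C of each CpG.
    chromosome_class
        ``"autosomal"`` or ``"X_linked"``.
    consensus_cpg_index
        Optional map from each local CpG to its index in the shared
        LINE-1 consensus coordinate frame (strictly increasing).
    consensus_bp_position
        Optional representative base-pair position (in the consensus frame)
        for each mapped CpG; same length as ``consensus_cpg_index``.
    """

    locus_id: str
    sequence: str
    cpg_positions: tuple[int, ...]
    chromosome_class: str = "autosomal"
    consensus_cpg_index: tuple[int, ...] | None = None
    consensus_bp_position: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.locus_id}: empty reference sequence")
        if self.chromosome_class not in ("autosomal", "X_linked"):
            raise ValueError(f"{self.locus_id}: bad chromosome_class {self.chromosome_class!r}")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        pos = tuple(int(p) for p in self.cpg_positions)
        object.__setattr__(self, "cpg_positions", pos)
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"{self.locus_id}: cpg_positions not strictly increasing")
        for p in pos:
            if p < 0 or p + 1 >= len(seq) or seq[p : p + 2] != "CG":
                raise ValueError(f"{self.locus_id}: position {p} is not a CpG cytosine")
        if self.consensus_cpg_index is not None:
            ci = tuple(int(i) for i in self.consensus_cpg_index)
            object.__setattr__(self, "consensus_cpg_index", ci)
            if len(ci) != len(pos):
                raise ValueError(f"{self.locus_id}: consensus map length mismatch")
            if any(b <= a for a, b in zip(ci, ci[1:])):
                raise ValueError(f"{self.locus_id}: consensus indices not strictly increasing")
        if self.consensus_bp_position is not None:
            if self.consensus_cpg_index is None:
                raise ValueError(f"{self.locus_id}: consensus_bp_position without consensus_cpg_index")
            bp = tuple(int(p) for p in self.consensus_bp_position)
            object.__setattr__(self, "consensus_bp_position", bp)
            if len(bp) != len(self.consensus_cpg_index):
                raise ValueError(f"{self.locus_id}: consensus bp position length mismatch")

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    def non_cpg_c_positions(self) -> list[int]:
        cpg = set(self.cpg_positions)
        return [i for i, b in enumerate(self.sequence) if b == "C" and i not in cpg]


def load_reference(
    fasta_path: str | Path,
    bed_path: str | Path | None = None,
    chromosome_class: str | None = None,
) -> LocusReference:
    """Load a single-locus reference from FASTA, CpG positions from BED.

    If ``bed_path`` is None the CpG positions are derived by scanning the
    sequence for ``CG``.  BED intervals must have length 1 or 2 and start on
    the C of a CpG.  ``chromosome_class`` defaults to X_linked when the
    record id contains ``X`` after the ``L1`` prefix, autosomal otherwise.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"{rec.id}: empty reference sequence")
    if bed_path is None:
        positions = find_cpg_positions(seq)
    else:
        positions = []
        for line_no, line in enumerate(Path(bed_path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{line_no}: malformed BED line")
            start, end = int(fields[1]), int(fields[2])
            if end - start not in (1, 2):
                raise ValueError(f"{rec.id}: BED interval {start}-{end} must span 1 or 2 bases")
            if seq[start : start + 2] != "CG":
                raise ValueError(f"{rec.id}: BED position {start} is not a CpG cytosine")
            positions.append(start)
        positions.sort()
    if chromosome_class is None:
        chromosome_class = "X_linked" if rec.id.upper().startswith("L1X") else "autosomal"
    return LocusReference(
        locus_id=rec.id,
        sequence=seq,
        cpg_positions=tuple(positions),
        chromosome_class=chromosome_class,
    )


def write_reference(ref: LocusReference, fasta_path: str | Path, bed_path: str | Path | None = None) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{ref.locus_id}\n")
        for i in range(0, len(ref.sequence), 70):
            fh.write(ref.sequence[i : i + 70] + "\n")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for j, p in enumerate(ref.cpg_positions):
                fh.write(f"{ref.locus_id}\t{p}\t{p + 2}\tCpG_{j}\n")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _bisulfite_matrix() -> substitution_matrices.Array:
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = MATCH_SCORE if a == b else MISMATCH_SCORE
    # reference C read as T: expected bisulfite conversion, scored as match.
    # The reverse (read C vs reference T) stays a mismatch.
    mat["C", "T"] = MATCH_SCORE
    for a in "ACGTN":
        mat[a, "N"] = 0.0
        mat["N", a] = 0.0
    return mat


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _bisulfite_matrix()
    aligner.open_gap_score = GAP_OPEN_SCORE
    aligner.extend_gap_score = GAP_EXTEND_SCORE
    # semi-global: end gaps free on both sequences (overlap alignment)
    aligner.end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class ReadAlignment:
    """Alignment of one read against a locus reference.

    ``ref_bases[i]`` is the read base aligned to reference position ``i``,
    or None where the read has a gap / does not cover the position.
    """

    read_id: str
    score: float
    identity: float
    orientation: str  # "forward" or "reverse"
    ref_bases: list[str | None]
    n_aligned_columns: int


class ReadRejected(Exception):
    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


def align_read(
    read: str,
    ref: LocusReference,
    read_id: str = "read",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aligned_fraction: float = DEFAULT_MIN_ALIGNED_FRACTION,
    both_orientations: bool = True,
) -> ReadAlignment:
    """Semi-global bisulfite-aware alignment of one read to the reference.

    Raises ReadRejected when the read is shorter than 20 nt, the aligned
    identity (read T vs reference C counted as identical) falls below
    ``min_identity``, or fewer than ``min_aligned_fraction`` of the read's
    bases land in aligned columns (free end gaps let an unrelated read clip
    down to a short spuriously high-identity overlap, so identity alone is
    not a sufficient filter).
    """
    read = read.upper()
    if len(read) < MIN_READ_LENGTH:
        raise ReadRejected("too_short", f"{read_id}: {len(read)} nt")
    candidates = [("forward", read)]
    if both_orientations:
        candidates.append(("reverse", reverse_complement(read)))
    best: tuple[float, str, str] | None = None
    for orientation, seq in candidates:
        score = _ALIGNER.score(ref.sequence, seq)
        if best is None or score > best[0]:
            best = (score, orientation, seq)
    score, orientation, seq = best
    aln = _ALIGNER.align(ref.sequence, seq)[0]
    indices = aln.indices  # 2 x L, -1 at gaps
    ref_bases: list[str | None] = [None] * len(ref.sequence)
    matches = 0
    aligned = 0
    for ri, qi in zip(indices[0], indices[1]):
        if ri < 0:
            continue
        if qi < 0:
            continue  # gap in read at this reference position
        base = seq[qi]
        ref_bases[ri] = base
        aligned += 1
        rbase = ref.sequence[ri]
        if base == rbase or (rbase == "C" and base == "T"):
            matches += 1
    identity = matches / aligned if aligned else 0.0
    if aligned < min_aligned_fraction * len(read):
        raise ReadRejected(
            "poor_coverage", f"{read_id}: only {aligned}/{len(read)} bases aligned"
        )
    if identity < min_identity:
        raise ReadRejected("low_identity", f"{read_id}: identity {identity:.3f}")
    return ReadAlignment(
        read_id=read_id,
        score=float(score),
        identity=identity,
        orientation=orientation,
        ref_bases=ref_bases,
        n_aligned_columns=aligned,
    )


# ---------------------------------------------------------------------------
# methylation calling
# ---------------------------------------------------------------------------


@dataclass
class ReadCall:
    read_id: str
    states: np.ndarray  # length n_cpg over {1, 0, -1}
    retention: float  # fraction of covered non-CpG reference Cs read as C


def call_read(
    alignment: ReadAlignment,
    ref: LocusReference,
    max_retention: float = DEFAULT_MAX_RETENTION,
) -> ReadCall:
    """Call per-CpG methylation states from an alignment.

    At each CpG cytosine a read C is methylated, a read T unmethylated, and a
    gap or any other base missing.  Non-CpG reference cytosines covered by the
    read measure bisulfite conversion efficiency: the fraction still read as C
    (retention) must not exceed ``max_retention``, otherwise the molecule is
    judged incompletely converted and rejected.
    """
    states = np.full(ref.n_cpg, MISSING, dtype=np.int8)
    covered_cpg = 0
    for j, p in enumerate(ref.cpg_positions):
        base = alignment.ref_bases[p]
        if base == "C":
            states[j] = METHYLATED
            covered_cpg += 1
        elif base == "T":
            states[j] = UNMETHYLATED
            covered_cpg += 1
    if covered_cpg == 0:
        raise ReadRejected("no_cpg", alignment.read_id)
    retained = 0
    covered_c = 0
    for p in ref.non_cpg_c_positions():
        base = alignment.ref_bases[p]
        if base == "C":
            retained += 1
            covered_c += 1
        elif base is not None:
            covered_c += 1
    retention = retained / covered_c if covered_c else 0.0
    if retention > max_retention:
        raise ReadRejected("retention", f"{alignment.read_id}: {retention:.3f}")
    return ReadCall(read_id=alignment.read_id, states=states, retention=retention)


# ---------------------------------------------------------------------------
# reads x CpG matrix
# ---------------------------------------------------------------------------


@dataclass
class ReadMethylationMatrix:
    """Reads x CpG methylation calls for one locus in one sample.

    ``calls`` is int8 with 1 = methylated, 0 = unmethylated, -1 = missing —
    one row per retained read, one column per CpG of the locus.
    """

    locus_id: str
    sample_id: str
    calls: np.ndarray
    read_ids: list[str] = field(default_factory=list)
    retention: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D reads x CpG array")
        if not self.read_ids:
            self.read_ids = [f"read_{i}" for i in range(self.calls.shape[0])]
        if len(self.read_ids) != self.calls.shape[0]:
            raise ValueError("read_ids length does not match number of rows")

    @property
    def n_reads(self) -> int:
        return self.calls.shape[0]

    @property
    def n_cpg(self) -> int:
        return self.calls.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            cols = "\t".join(f"CpG_{j}" for j in range(self.n_cpg))
            fh.write(f"read_id\t{cols}\n")
            for rid, row in zip(self.read_ids, self.calls):
                vals = "\t".join("NA" if v == MISSING else str(int(v)) for v in row)
                fh.write(f"{rid}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, locus_id: str = "", sample_id: str = "") -> "ReadMethylationMatrix":
        lines = Path(path).read_text().splitlines()
        read_ids, rows = [], []
        for line in lines[1:]:
            fields = line.rstrip("\n").split("\t")
            read_ids.append(fields[0])
            rows.append([MISSING if v == "NA" else int(v) for v in fields[1:]])
        return cls(locus_id=locus_id, sample_id=sample_id, calls=np.array(rows, dtype=np.int8), read_ids=read_ids)


@dataclass
class QCReport:
    locus_id: str
    sample_id: str
    n_input: int = 0
    n_retained: int = 0
    n_too_short: int = 0
    n_low_identity: int = 0
    n_poor_coverage: int = 0
    n_high_retention: int = 0
    n_no_cpg: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _iter_reads(reads) -> Iterable[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            yield rec.id, str(rec.seq)
    else:
        for item in reads:
            if isinstance(item, tuple):
                yield item
            elif isinstance(item, str):
                yield f"read_{id(item)}", item
            else:  # SeqRecord
                yield item.id, str(item.seq)


def build_matrix(
    reads,
    ref: LocusReference,
    sample_id: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_retention: float = DEFAULT_MAX_RETENTION,
) -> tuple[ReadMethylationMatrix, QCReport]:
    """Align and call every read, returning the retained matrix plus QC counts.

    Reads may be a FASTQ/FASTA path, an iterable of (id, sequence) tuples, or
    SeqRecords.  Duplicate reads are kept (no deduplication); row order follows
    input order.  Raises ValueError when no read survives the filters.
    """
    qc = QCReport(locus_id=ref.locus_id, sample_id=sample_id)
    read_ids: list[str] = []
    rows: list[np.ndarray] = []
    retentions: list[float] = []
    for rid, seq in _iter_reads(reads):
        qc.n_input += 1
        try:
            aln = align_read(seq, ref, read_id=rid, min_identity=min_identity)
            call = call_read(aln, ref, max_retention=max_retention)
        except ReadRejected as exc:
            if exc.reason == "too_short":
                qc.n_too_short += 1
            elif exc.reason == "low_identity":
                qc.n_low_identity += 1
            elif exc.reason == "poor_coverage":
                qc.n_poor_coverage += 1
            elif exc.reason == "retention":
                qc.n_high_retention += 1
            else:
                qc.n_no_cpg += 1
            continue
        read_ids.append(rid)
        rows.append(call.states)
        retentions.append(call.retention)
    if not rows:
        raise ValueError(f"{ref.locus_id}/{sample_id}: zero reads retained after QC")
    qc.n_retained = len(rows)
    matrix = ReadMethylationMatrix(
        locus_id=ref.locus_id,
        sample_id=sample_id,
        calls=np.vstack(rows),
        read_ids=read_ids,
        retention=np.array(retentions),
    )
    return matrix, qc


def write_qc_report(reports: Sequence[QCReport], path: str | Path) -> None:
    keys = [
        "locus_id", "sample_id", "n_input", "n_retained",
        "n_too_short", "n_low_identity", "n_poor_coverage", "n_high_retention", "n_no_cpg",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for r in reports:
            d = r.as_dict()
            fh.write("\t".join(str(d[k]) for k in keys) + "\n")
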