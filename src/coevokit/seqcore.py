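"""Sequence and alignment primitives.

Sequences, gapped multiple alignments, pairwise global/local alignment with
percent identity/similarity reporting, per-column conservation of an
alignment, PROSITE-like positional motif scanning, and repeat-interval
masking.  These are the substrate every downstream co-evolution statistic
is computed on.

Conventions
-----------
* Residue offsets are 1-based throughout, matching the "Cys-34" style of
  the molecular-evolution literature.
* The gap character is ``'-'``.
* FASTA headers use a pipe-delimited dialect ``id|species|paralog``; the
  species defaults to the id when absent, extra fields are tolerated.
* Global alignment follows the EMBOSS ``needle`` convention: affine gaps
  (default BLOSUM62, gap open 10, gap extend 0.5) with penalty-free end
  gaps, and identity/similarity percentages computed over the full
  alignment length including gap columns.  Similarity counts identities
  plus substitutions with a strictly positive matrix score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "Sequence",
    "MSA",
    "SubstitutionMatrix",
    "PairwiseAlignment",
    "MotifPattern",
    "IntervalSet",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_msa",
    "write_msa",
    "global_align",
    "local_align",
    "column_conservation",
    "invariant_residue_counts",
    "scan_motif",
    "mask_intervals",
    "read_intervals_tsv",
    "DEFAULT_GAP_OPEN",
    "DEFAULT_GAP_EXTEND",
]

logger = logging.getLogger(__name__)

GAP = "-"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
NUCLEOTIDE_ALPHABET = "ACGTN"

#: Default parameters of the classical EMBOSS pairwise tools (needle/water).
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


class ParseError(ValueError):
    """Raised on malformed sequence input; the message names the line."""


@dataclass(frozen=True)
class Sequence:
    """An ungapped protein or nucleotide sequence with panel metadata."""

    id: str
    residues: str
    species: str = ""
    paralog: str | None = None
    molecule: str = "protein"

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        if GAP in self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be ungapped")
        if self.molecule not in ("protein", "nucleotide"):
            raise ValueError(f"unknown molecule type {self.molecule!r}")
        if not self.species:
            object.__setattr__(self, "species", self.id)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MSARow:
    id: str
    species: str
    gapped: str
    paralog: str | None = None

    @property
    def ungapped(self) -> str:
        return self.gapped.replace(GAP, "")


class MSA:
    """A gapped multiple alignment; all rows share one column count."""

    def __init__(self, rows: TypingSequence[MSARow]):
        rows = list(rows)
        if not rows:
            raise ValueError("MSA must have at least one row")
        lengths = {len(r.gapped) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"MSA rows have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in MSA")
        self.rows = rows
        self.length = lengths.pop()

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.rows]

    def row(self, id: str) -> MSARow:
        for r in self.rows:
            if r.id == id:
                return r
        raise KeyError(id)


class SubstitutionMatrix:
    """Symmetric residue scoring lookup wrapping a Biopython matrix.

    'X' scores through the matrix's own X row when present, else 0
    against everything.
    """

    def __init__(self, array: substitution_matrices.Array, name: str = ""):
        self.array = array
        self.name = name
        self.alphabet = str(array.alphabet)

    @classmethod
    def load(cls, name: str = "BLOSUM62") -> "SubstitutionMatrix":
        return cls(substitution_matrices.load(name), name=name)

    @classmethod
    def from_match_mismatch(
        cls, alphabet: str, match: float, mismatch: float, name: str = "toy"
    ) -> "SubstitutionMatrix":
        arr = substitution_matrices.Array(alphabet, dims=2)
        for a in alphabet:
            for b in alphabet:
                arr[a, b] = match if a == b else mismatch
        return cls(arr, name=name)

    def score(self, a: str, b: str) -> float:
        try:
            return float(self.array[a, b])
        except (KeyError, IndexError):
            if "X" in (a, b):
                return 0.0
            raise ValueError(f"residue pair ({a!r}, {b!r}) outside matrix alphabet")

    def validate(self, seq: Sequence) -> None:
        extra = set(seq.residues) - set(self.alphabet)
        if extra:
            raise ValueError(
                f"sequence {seq.id!r} contains residues outside the "
                f"matrix alphabet: {sorted(extra)}"
            )


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    mode: str

    @property
    def length(self) -> int:
        return len(self.aligned_a)


def _percentages(
    aligned_a: str, aligned_b: str, matrix: SubstitutionMatrix
) -> tuple[float, float]:
    """Identity / similarity over the alignment length including gaps."""
    n = len(aligned_a)
    if n == 0:
        return 0.0, 0.0
    ident = simil = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP or y == GAP:
            continue
        if x == y:
            ident += 1
            simil += 1
        elif matrix.score(x, y) > 0:
            simil += 1
    return 100.0 * ident / n, 100.0 * simil / n


def _make_aligner(
    matrix: SubstitutionMatrix, gap_open: float, gap_extend: float, mode: str
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix.array
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    if mode == "global":
        # needle convention: end gaps are free
        aligner.mode = "global"
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    else:
        aligner.mode = "local"
    return aligner


def _align(
    a: Sequence,
    b: Sequence,
    matrix: SubstitutionMatrix,
    gap_open: float,
    gap_extend: float,
    mode: str,
) -> PairwiseAlignment:
    if a.molecule != b.molecule:
        raise ValueError(
            f"molecule types differ: {a.id}={a.molecule}, {b.id}={b.molecule}"
        )
    if not (gap_open >= gap_extend >= 0):
        raise ValueError("require gap_open >= gap_extend >= 0")
    matrix.validate(a)
    matrix.validate(b)
    # canonical argument order: optimal alignments can be tied, and the DP
    # tie-break depends on which sequence is first; aligning the
    # lexicographically smaller sequence first makes identity/similarity
    # symmetric in argument order
    swapped = a.residues > b.residues
    if swapped:
        a, b = b, a
    aligner = _make_aligner(matrix, gap_open, gap_extend, mode)
    alignments = aligner.align(a.residues, b.residues)
    try:
        best = alignments[0]
    except IndexError:
        # Smith-Waterman with no positive-scoring segment pair
        return PairwiseAlignment("", "", 0.0, 0.0, 0.0, mode)
    score = float(best.score)
    if mode == "local" and score <= 0:
        return PairwiseAlignment("", "", 0.0, 0.0, 0.0, mode)
    aligned_a, aligned_b = str(best[0]), str(best[1])
    if swapped:
        aligned_a, aligned_b = aligned_b, aligned_a
    ident, simil = _percentages(aligned_a, aligned_b, matrix)
    return PairwiseAlignment(aligned_a, aligned_b, score, ident, simil, mode)


def global_align(
    a: Sequence,
    b: Sequence,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch alignment with affine, end-free gaps.

    An internal gap of length L costs ``gap_open + (L - 1) * gap_extend``;
    terminal gaps cost nothing (the classical global tool's convention,
    required for sequences of very different lengths such as a 164- vs a
    351-residue ortholog pair).
    """
    matrix = matrix or SubstitutionMatrix.load("BLOSUM62")
    return _align(a, b, matrix, gap_open, gap_extend, "global")


def local_align(
    a: Sequence,
    b: Sequence,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Highest-scoring Smith-Waterman local segment pair (floor at zero)."""
    matrix = matrix or SubstitutionMatrix.load("BLOSUM62")
    return _align(a, b, matrix, gap_open, gap_extend, "local")


# ---------------------------------------------------------------------------
# FASTA I/O — pipe-delimited "id|species|paralog" header dialect


def _parse_header(line: str) -> tuple[str, str, str | None]:
    fields = line[1:].strip().split("|")
    seq_id = fields[0].strip()
    species = fields[1].strip() if len(fields) > 1 and fields[1].strip() else seq_id
    paralog = fields[2].strip() if len(fields) > 2 and fields[2].strip() else None
    if len(fields) > 3:
        logger.info("header %r: ignoring %d extra field(s)", seq_id, len(fields) - 3)
    return seq_id, species, paralog


def _iter_fasta_records(path: str | Path):
    """Yield (header_lineno, id, species, paralog, raw_sequence) per record."""
    header = None
    chunks: list[str] = []
    header_line = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield (header_line, *header, "".join(chunks))
                header = _parse_header(line)
                header_line = lineno
                chunks = []
            elif line.strip():
                if header is None:
                    raise ParseError(
                        f"{path}: line {lineno}: sequence data before any header"
                    )
                chunks.append(line.strip())
    if header is not None:
        yield (header_line, *header, "".join(chunks))


def read_fasta(path: str | Path, molecule: str = "protein") -> list[Sequence]:
    """Read ungapped sequences; empty file yields an empty list."""
    seqs = []
    seen: set[str] = set()
    for lineno, seq_id, species, paralog, raw in _iter_fasta_records(path):
        if not raw:
            raise ParseError(
                f"{path}: line {lineno}: header {seq_id!r} has no sequence"
            )
        if seq_id in seen:
            raise ParseError(f"{path}: line {lineno}: duplicate id {seq_id!r}")
        seen.add(seq_id)
        seqs.append(
            Sequence(seq_id, raw.upper(), species=species, paralog=paralog,
                     molecule=molecule)
        )
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = s.id
            if s.species != s.id or s.paralog:
                header += f"|{s.species}"
            if s.paralog:
                header += f"|{s.paralog}"
            fh.write(f">{header}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_msa(path: str | Path) -> MSA:
    """Read a gapped FASTA alignment."""
    rows = []
    for lineno, seq_id, species, paralog, raw in _iter_fasta_records(path):
        if not raw:
            raise ParseError(
                f"{path}: line {lineno}: header {seq_id!r} has no sequence"
            )
        rows.append(MSARow(seq_id, species, raw.upper(), paralog=paralog))
    return MSA(rows)


def write_msa(msa: MSA, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in msa.rows:
            header = r.id
            if r.species != r.id or r.paralog:
                header += f"|{r.species}"
            if r.paralog:
                header += f"|{r.paralog}"
            fh.write(f">{header}\n")
            for i in range(0, len(r.gapped), width):
                fh.write(r.gapped[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Conservation


def column_conservation(msa: MSA) -> pd.DataFrame:
    """Per-column conservation of an alignment.

    A column is invariant iff every row carries the same residue and no
    row carries a gap there.  Returns a frame with 1-based column index,
    the consensus residue (the invariant residue, or None for variable
    columns), the invariance flag and the gap count.
    """
    records = []
    for c in range(msa.length):
        col = [r.gapped[c] for r in msa.rows]
        gaps = col.count(GAP)
        residues = set(col) - {GAP}
        invariant = gaps == 0 and len(residues) == 1
        records.append(
            {
                "column_1based": c + 1,
                "residue": residues.pop() if invariant else None,
                "is_invariant": invariant,
                "gap_count": gaps,
            }
        )
    return pd.DataFrame.from_records(records)


def invariant_residue_counts(msa: MSA) -> dict[str, int]:
    """Count invariant columns per residue (e.g. how many invariant Cys)."""
    report = column_conservation(msa)
    inv = report[report.is_invariant]
    return inv.groupby("residue").size().to_dict()


# ---------------------------------------------------------------------------
# Motif scanning


@dataclass(frozen=True)
class MotifPattern:
    """Ordered residue-set pattern, e.g. C-F-[AT]-C-[FY] or the fuzzier CXXC.

    Each element is the set of residues allowed at that position; the
    wildcard element is the full alphabet (and includes 'X' itself).  An
    optional 1-based anchor records where the motif is expected to start
    in a reference sequence.
    """

    elements: tuple[frozenset[str], ...]
    anchor: int | None = None
    alphabet: str = PROTEIN_ALPHABET

    def __post_init__(self):
        if not self.elements:
            raise ValueError("empty motif pattern")
        for e in self.elements:
            if not e or not set(e) <= set(self.alphabet):
                raise ValueError(f"element {set(e)} outside alphabet")

    def __len__(self) -> int:
        return len(self.elements)

    @classmethod
    def from_string(
        cls,
        text: str,
        anchor: int | None = None,
        alphabet: str = PROTEIN_ALPHABET,
    ) -> "MotifPattern":
        """Parse ``"C-X-X-C"`` / ``"CXXC"`` / ``"CF[AT]C[FY]"`` notation.

        ``X`` is the any-residue wildcard; ``[..]`` encloses alternatives.
        """
        text = text.replace("-", "")
        elements: list[frozenset[str]] = []
        i = 0
        while i < len(text):
            ch = text[i]
            if ch == "[":
                j = text.index("]", i)
                elements.append(frozenset(text[i + 1 : j]))
                i = j + 1
            elif ch == "X":
                elements.append(frozenset(alphabet))
                i += 1
            else:
                elements.append(frozenset(ch))
                i += 1
        return cls(tuple(elements), anchor=anchor, alphabet=alphabet)


def scan_motif(seq: Sequence, pattern: MotifPattern) -> list[int]:
    """All 1-based offsets where the pattern matches; overlaps reported."""
    res = seq.residues
    k = len(pattern)
    hits = []
    for start in range(len(res) - k + 1):
        if all(res[start + i] in pattern.elements[i] for i in range(k)):
            hits.append(start + 1)
    return hits


def motif_at_anchor(seq: Sequence, pattern: MotifPattern) -> bool:
    """Whether the pattern matches at its expected (anchor) offset."""
    if pattern.anchor is None:
        raise ValueError("pattern has no anchor")
    return pattern.anchor in scan_motif(seq, pattern)


# ---------------------------------------------------------------------------
# Interval masking


@dataclass(frozen=True)
class IntervalSet:
    """1-based inclusive intervals on a named sequence (repeat mask etc.)."""

    name: str
    intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        for start, end in self.intervals:
            if not (1 <= start <= end):
                raise ValueError(f"bad interval ({start}, {end})")

    def __len__(self) -> int:
        return len(self.intervals)


def read_intervals_tsv(path: str | Path) -> dict[str, IntervalSet]:
    """Read a 3-column TSV (name, start, end; 1-based inclusive).

    Note this is *not* BED: BED proper is 0-based half-open.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["name", "start", "end"], comment="#"
    )
    out = {}
    for name, grp in df.groupby("name", sort=False):
        out[str(name)] = IntervalSet(
            str(name), tuple(zip(grp.start.astype(int), grp.end.astype(int)))
        )
    return out


def mask_intervals(seq: Sequence, mask: IntervalSet) -> Sequence:
    """Replace residues inside the intervals by N (nucleotide) or X (protein).

    Idempotent; length is preserved.  Out-of-bounds intervals are an error.
    """
    fill = "N" if seq.molecule == "nucleotide" else "X"
    residues = list(seq.residues)
    for start, end in mask.intervals:
        if end > len(residues):
            raise ValueError(
                f"interval ({start}, {end}) out of bounds for "
                f"{seq.id!r} of length {len(residues)}"
            )
        for i in range(start - 1, end):
            residues[i] = fill
    return Sequence(
        seq.id, "".join(residues), species=seq.species, paralog=seq.paralog,
        molecule=seq.molecule,
    )
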