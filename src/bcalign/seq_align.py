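"""Global sequence alignment and alignment I/O.

The structural aligner takes a pairwise *sequence* alignment as input and
optimizes a convex combination of structural deviation and deviation from
that alignment.  This module produces the input alignment (Needleman-Wunsch,
affine gaps, open 8 / extend 1 — penalties chosen to favor compact
alignments at domain terminals), computes sequence identity, and reads and
writes alignments as pairwise FASTA or two-column residue-pair tables so
that alignments from any external method can be injected.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "SequenceAlignment", "needleman_wunsch", "sequence_identity",
    "read_fasta_alignment", "write_fasta_alignment", "read_pair_table",
    "identity_alignment",
]

DEFAULT_GAP_OPEN = 8.0
DEFAULT_GAP_EXTEND = 1.0
DEFAULT_MATRIX = "BLOSUM62"

Column = Tuple[Optional[int], Optional[int]]


@dataclasses.dataclass(frozen=True)
class SequenceAlignment:
    """A global pairwise alignment as an ordered list of columns.

    Each column pairs a 0-based position of sequence A (or ``None`` for a
    gap) with a position of sequence B (or ``None``).  ``exact_pairs`` is
    the sub-list of columns aligned on both sides — the "exact matching
    residue pairs" that anchor the structural alignment.
    """

    columns: Tuple[Column, ...]
    score: Optional[float] = None
    matrix_name: str = ""

    def __post_init__(self):
        cols = tuple((a, b) for a, b in self.columns)
        prev_a = prev_b = -1
        for a, b in cols:
            if a is None and b is None:
                raise ValueError("gap-gap column")
            if a is not None:
                if a <= prev_a:
                    raise ValueError("positions must strictly increase")
                prev_a = a
            if b is not None:
                if b <= prev_b:
                    raise ValueError("positions must strictly increase")
                prev_b = b
        object.__setattr__(self, "columns", cols)

    @property
    def exact_pairs(self) -> List[Tuple[int, int]]:
        return [(a, b) for a, b in self.columns
                if a is not None and b is not None]

    def __len__(self) -> int:
        return len(self.columns)


def identity_alignment(n: int) -> SequenceAlignment:
    """The trivial alignment pairing position i with position i."""
    return SequenceAlignment(tuple((i, i) for i in range(n)))


def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # Biopython convention: open_gap_score is charged for the first gapped
    # position, extend_gap_score for each further one.
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def _sanitize(seq: str) -> str:
    # Substitution matrices carry no row for X/unknowns in some tables;
    # BLOSUM62 from Biopython does include X, so only uppercase here.
    return seq.upper()


def needleman_wunsch(seq_a: str, seq_b: str, *,
                     gap_open: float = DEFAULT_GAP_OPEN,
                     gap_extend: float = DEFAULT_GAP_EXTEND,
                     matrix_name: str = DEFAULT_MATRIX) -> SequenceAlignment:
    """Optimal global alignment under ``matrix_name`` with affine gap
    penalties (default open 8, extend 1, subtracted from the score).

    Ties between co-optimal alignments are broken deterministically by
    taking the first alignment in the aligner's enumeration order.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(matrix_name, gap_open, gap_extend)
    alignment = aligner.align(_sanitize(seq_a), _sanitize(seq_b))[0]
    columns: List[Column] = []
    ia, ib = 0, 0
    for col_a, col_b in zip(*alignment):
        a = ia if col_a != "-" else None
        b = ib if col_b != "-" else None
        if col_a != "-":
            ia += 1
        if col_b != "-":
            ib += 1
        columns.append((a, b))
    return SequenceAlignment(tuple(columns), score=float(alignment.score),
                             matrix_name=matrix_name)


def sequence_identity(alignment: SequenceAlignment,
                      seq_a: str, seq_b: str) -> float:
    """Percent identical residues over non-gap (both-aligned) columns."""
    pairs = alignment.exact_pairs
    if not pairs:
        raise ValueError("sequence identity undefined: no non-gap columns")
    same = sum(1 for a, b in pairs if seq_a[a].upper() == seq_b[b].upper())
    return 100.0 * same / len(pairs)


# ---------------------------------------------------------------------------
# alignment I/O

def write_fasta_alignment(alignment: SequenceAlignment, seq_a: str, seq_b: str,
                          path, names: Tuple[str, str] = ("A", "B")) -> None:
    row_a = "".join(seq_a[a] if a is not None else "-"
                    for a, _ in alignment.columns)
    row_b = "".join(seq_b[b] if b is not None else "-"
                    for _, b in alignment.columns)
    Path(path).write_text(
        f">{names[0]}\n{row_a}\n>{names[1]}\n{row_b}\n")


def read_fasta_alignment(path) -> SequenceAlignment:
    """Read a pairwise FASTA alignment (two gapped rows of equal length)."""
    rows: List[str] = []
    current: List[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current:
                rows.append("".join(current))
                current = []
        else:
            current.append(line)
    if current:
        rows.append("".join(current))
    if len(rows) != 2 or len(rows[0]) != len(rows[1]):
        raise ValueError("expected a pairwise FASTA alignment with two "
                         "equal-length gapped rows")
    columns: List[Column] = []
    ia = ib = 0
    for ca, cb in zip(rows[0], rows[1]):
        a = b = None
        if ca not in "-.":
            a = ia
            ia += 1
        if cb not in "-.":
            b = ib
            ib += 1
        if a is None and b is None:
            continue
        columns.append((a, b))
    return SequenceAlignment(tuple(columns))


def read_pair_table(path, len_a: int, len_b: int) -> SequenceAlignment:
    """Read a two-column table of aligned residue positions (0-based).

    Positions of either sequence that appear in no pair become gap columns,
    interleaved in sequence order, so an externally produced structure-based
    alignment can drive the pipeline.
    """
    pairs: List[Tuple[int, int]] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        a_str, b_str = line.split()[:2]
        pairs.append((int(a_str), int(b_str)))
    pairs.sort()
    columns: List[Column] = []
    ia = ib = 0
    for a, b in pairs:
        if not (0 <= a < len_a and 0 <= b < len_b):
            raise ValueError(f"pair ({a}, {b}) outside sequence ranges")
        while ia < a:
            columns.append((ia, None))
            ia += 1
        while ib < b:
            columns.append((None, ib))
            ib += 1
        columns.append((a, b))
        ia, ib = a + 1, b + 1
    while ia < len_a:
        columns.append((ia, None))
        ia += 1
    while ib < len_b:
        columns.append((None, ib))
        ib += 1
    return SequenceAlignment(tuple(columns))
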