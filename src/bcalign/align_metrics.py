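"""Metrics on the space of residue alignments.

Two alignments a1: I1 <-> J1 and a2: I2 <-> J2 of the same pair of chains
are compared on the residues they both align, I* = I1 n I2 and
J* = J1 n J2:

* ``rmsd_align`` — root of the average of the two direction-wise mean
  squared index differences (an RMSD in residue units, on alignments rather
  than coordinates);
* ``aad`` — the corresponding one-norm, the average alignment displacement;
* ``mal`` — the misalignment length, the number of residues aligned by
  exactly one of the two alignments;
* ``rmsd_align_seq`` — ``rmsd_align`` of an alignment against the exact
  matching residue pairs of the input sequence alignment; this is the
  sequence-deviation term the structural aligner weights by (1 - k).

Alignment images may be fractional: a residue can be aligned to a pseudo
alpha carbon half way between two residues, giving e.g. a displacement of
0.5 residues.  MAL counts whole residues only.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, Iterable, Mapping, Tuple

from .seq_align import SequenceAlignment

__all__ = ["ResidueCorrespondence", "rmsd_align", "aad", "mal",
           "rmsd_align_seq", "from_exact_pairs"]


@dataclasses.dataclass(frozen=True)
class ResidueCorrespondence:
    """A (possibly fractional) monotone correspondence between residue sets.

    ``forward`` maps whole residue indices on chain A to real-valued
    positions on chain B (fractional values are pseudo alpha carbons);
    ``backward`` maps whole residues on B to positions on A.  If
    ``backward`` is omitted it is derived from the integer-valued entries
    of ``forward``.
    """

    forward: Mapping[int, float]
    backward: Mapping[int, float] = None  # type: ignore[assignment]

    def __post_init__(self):
        fwd = {int(i): float(x) for i, x in self.forward.items()}
        keys = sorted(fwd)
        vals = [fwd[i] for i in keys]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("correspondence must be monotone non-decreasing")
        object.__setattr__(self, "forward", fwd)
        if self.backward is None:
            bwd = {int(round(x)): float(i) for i, x in fwd.items()
                   if float(x).is_integer()}
        else:
            bwd = {int(j): float(y) for j, y in self.backward.items()}
        object.__setattr__(self, "backward", bwd)

    @property
    def aligned_a(self) -> set:
        return set(self.forward)

    @property
    def aligned_b(self) -> set:
        return set(self.backward)

    def inverse(self) -> "ResidueCorrespondence":
        return ResidueCorrespondence(self.backward, self.forward)


def _common(a1: Mapping[int, float], a2: Mapping[int, float]) -> Iterable[int]:
    return sorted(set(a1) & set(a2))


def _direction_terms(a1: "ResidueCorrespondence", a2: "ResidueCorrespondence",
                     power: float) -> Tuple[float, float]:
    i_star = _common(a1.forward, a2.forward)
    j_star = _common(a1.backward, a2.backward)
    if not i_star or not j_star:
        raise ValueError("no common aligned residues")
    ta = sum(abs(a1.forward[i] - a2.forward[i]) ** power for i in i_star)
    tb = sum(abs(a1.backward[j] - a2.backward[j]) ** power for j in j_star)
    return ta / (2 * len(i_star)), tb / (2 * len(j_star))


def rmsd_align(a1: ResidueCorrespondence, a2: ResidueCorrespondence) -> float:
    """Averaged two-norm distance between alignments, in residue units."""
    ta, tb = _direction_terms(a1, a2, 2.0)
    return math.sqrt(ta + tb)


def aad(a1: ResidueCorrespondence, a2: ResidueCorrespondence) -> float:
    """Average alignment displacement (one-norm), in residue units."""
    ta, tb = _direction_terms(a1, a2, 1.0)
    return ta + tb


def mal(a1: ResidueCorrespondence, a2: ResidueCorrespondence) -> int:
    """Misalignment length: residues aligned by exactly one alignment."""
    return (len(a1.aligned_a ^ a2.aligned_a)
            + len(a1.aligned_b ^ a2.aligned_b))


def from_exact_pairs(pairs) -> ResidueCorrespondence:
    """Correspondence from integer (i, j) pairs, both directions exact."""
    pairs = list(pairs)
    fwd: Dict[int, float] = {int(i): float(j) for i, j in pairs}
    bwd: Dict[int, float] = {int(j): float(i) for i, j in pairs}
    return ResidueCorrespondence(fwd, bwd)


def rmsd_align_seq(a: ResidueCorrespondence,
                   seq_alignment: SequenceAlignment) -> float:
    """Deviation of a structural alignment from its input sequence
    alignment's exact matching residue pairs, in residue units."""
    a_s = from_exact_pairs(seq_alignment.exact_pairs)
    return rmsd_align(a, a_s)
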