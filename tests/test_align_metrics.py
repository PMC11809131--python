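import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcalign.align_metrics import (ResidueCorrespondence, aad,
                                   from_exact_pairs, mal, rmsd_align,
                                   rmsd_align_seq)
from bcalign.seq_align import SequenceAlignment


def identity(n):
    return from_exact_pairs((i, i) for i in range(n))


def test_identity_distances_are_zero():
    a = identity(50)
    assert rmsd_align(a, a) == 0.0
    assert aad(a, a) == 0.0
    assert mal(a, a) == 0


def test_rmsd_align_single_unit_displacement():
    """100 shared pairs, one moved by a whole residue in both directions:
    sqrt(1/200 + 1/200) = 0.1."""
    a1 = identity(100)
    fwd = {i: float(i) for i in range(100)}
    bwd = {i: float(i) for i in range(100)}
    fwd[10] = 11.0
    bwd[10] = 11.0
    a2 = ResidueCorrespondence(fwd, bwd)
    assert rmsd_align(a1, a2) == pytest.approx(math.sqrt(1 / 200 + 1 / 200))


def test_aad_worked_half_residue_example():
    """One whole-residue and one half-residue (pseudo alpha carbon) change
    over 100 aligned residues gives AAD = 0.015 exactly."""
    a1 = identity(100)
    fwd = {i: float(i) for i in range(100)}
    bwd = {i: float(i) for i in range(100)}
    fwd[20] = 21.0
    bwd[20] = 21.0
    fwd[60] = 60.5
    bwd[60] = 60.5
    a2 = ResidueCorrespondence(fwd, bwd)
    assert aad(a1, a2) == pytest.approx(0.015)


def test_mal_counts_residues_aligned_by_one_side_only():
    a1 = from_exact_pairs([(0, 0), (1, 1), (2, 2)])
    a2 = from_exact_pairs([(0, 0), (1, 1), (2, 2), (3, 3)])
    assert mal(a1, a2) == 2          # one extra residue on each chain
    b1 = from_exact_pairs([(0, 0), (1, 1)])
    b2 = from_exact_pairs([(5, 5), (6, 6), (7, 7)])
    assert mal(b1, b2) == 10         # fully disjoint: 2+2+3+3


def test_empty_overlap_is_an_error():
    a1 = from_exact_pairs([(0, 0)])
    a2 = from_exact_pairs([(5, 5)])
    with pytest.raises(ValueError, match="no common"):
        rmsd_align(a1, a2)


def test_rmsd_align_seq_exact_and_displaced():
    aln = SequenceAlignment(tuple((i, i) for i in range(5)))
    a = from_exact_pairs((i, i) for i in range(5))
    assert rmsd_align_seq(a, aln) == 0.0
    # single common pair displaced by 2 in both directions -> 2
    aln1 = SequenceAlignment(((3, 3),))
    a1 = ResidueCorrespondence({3: 5.0}, {3: 5.0})
    assert rmsd_align_seq(a1, aln1) == pytest.approx(2.0)


@st.composite
def correspondence_pairs(draw):
    n = draw(st.integers(3, 20))
    base = list(range(n))

    def perturb():
        fwd = {i: float(i) + draw(st.sampled_from([0.0, 0.5, 1.0, -0.5]))
               for i in base}
        vals = sorted(fwd.values())
        fwd = {i: v for i, v in zip(base, vals)}  # restore monotonicity
        bwd = {i: float(i) + draw(st.sampled_from([0.0, 0.5, 1.0]))
               for i in base}
        bwd = {i: v for i, v in zip(base, sorted(bwd.values()))}
        return ResidueCorrespondence(fwd, bwd)

    return perturb(), perturb(), perturb()


@settings(max_examples=200, deadline=None, derandomize=True)
@given(correspondence_pairs())
def test_metric_properties(triple):
    """Symmetry, AAD <= RMSDalign (mean-abs vs root-mean-square), and the
    triangle inequality on correspondences over a common aligned set."""
    a1, a2, a3 = triple
    assert rmsd_align(a1, a2) == pytest.approx(rmsd_align(a2, a1))
    assert aad(a1, a2) == pytest.approx(aad(a2, a1))
    assert mal(a1, a2) == mal(a2, a1)
    assert aad(a1, a2) <= rmsd_align(a1, a2) + 1e-12
    assert rmsd_align(a1, a3) <= (rmsd_align(a1, a2) + rmsd_align(a2, a3)
                                  + 1e-9)
    assert aad(a1, a3) <= aad(a1, a2) + aad(a2, a3) + 1e-9
    # identity of indiscernibles on the common aligned set
    if rmsd_align(a1, a2) == 0.0:
        assert all(a1.forward[i] == a2.forward[i] for i in a1.forward)
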