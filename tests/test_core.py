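import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bcalign.core import (CurveAlignment, Triangulation, bcalign,
                          cut_terminal, strip_to_curve_alignment, superpose,
                          triangle_sequence_cost, triangulate)
from bcalign.fixtures import helix_curve
from oracles import random_rotation_rmsd_bound, strip_cost_brute_force


# ---------------------------------------------------------------------------
# superposition

def test_superpose_recovers_rigid_motion(rng):
    pts = rng.normal(scale=5, size=(12, 3))
    rot = Rotation.random(rng=rng).as_matrix()
    moved = pts @ rot.T + np.array([3.0, -2.0, 7.0])
    sup = superpose(pts, moved)
    assert sup.rmsd < 1e-9
    assert np.abs(sup.rotation @ sup.rotation.T - np.eye(3)).max() < 1e-9
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0)


def test_superpose_cannot_mirror_chiral_set(rng):
    pts = rng.normal(scale=5, size=(10, 3))
    mirrored = pts * np.array([1.0, 1.0, -1.0])
    assert superpose(pts, mirrored).rmsd > 0.1


def test_superpose_beats_random_rotations(rng):
    """Kabsch RMSD is a lower bound on any random-rotation RMSD."""
    for _ in range(5):
        a = rng.normal(scale=4, size=(5, 3))
        b = rng.normal(scale=4, size=(5, 3))
        sup = superpose(a, b)
        bound = random_rotation_rmsd_bound(a, b, 2000, rng)
        assert sup.rmsd <= bound + 1e-12


def test_superpose_degenerate_inputs():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="collinear"):
        superpose(line, line)
    with pytest.raises(ValueError):
        superpose(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# triangulation DP

def _identity_partners(n):
    return {i: float(i) for i in range(n)}


def test_identical_curves_have_zero_cost_diagonal():
    pts = helix_curve(8)
    tri = triangulate(pts, pts, _identity_partners(8), _identity_partners(8),
                      k=1.0)
    assert tri.total_cost == pytest.approx(0.0, abs=1e-18)
    ca = strip_to_curve_alignment(tri, pts, pts)
    np.testing.assert_allclose(ca.labels_a, np.arange(8.0))
    np.testing.assert_allclose(ca.labels_b, np.arange(8.0))


def test_triangle_sequence_cost_values():
    """Per-bound cost is (1/2)(3.8)^2 d^2: one residue off is 7.22 A^2 and
    the scaling is quadratic."""
    assert triangle_sequence_cost(5.0, 5.0) == 0.0
    one = triangle_sequence_cost(5.0, 4.0)
    assert one == pytest.approx(0.5 * 3.8 ** 2)
    assert triangle_sequence_cost(5.0, 3.0) == pytest.approx(4 * one)
    assert triangle_sequence_cost(5.0, None) == 0.0


@pytest.mark.parametrize("k", [0.01, 0.3, 1.0])
def test_dp_matches_brute_force(rng, k):
    """DP strip cost equals exhaustive enumeration on small windows."""
    for _ in range(25):
        m, n = rng.integers(2, 8, size=2)
        a = rng.normal(scale=5, size=(m, 3))
        b = rng.normal(scale=5, size=(n, 3))
        npairs = int(rng.integers(0, min(m, n) + 1))
        ia = np.sort(rng.choice(m, size=npairs, replace=False))
        ib = np.sort(rng.choice(n, size=npairs, replace=False))
        pa = {int(i): float(j) for i, j in zip(ia, ib)}
        pb = {int(j): float(i) for i, j in zip(ia, ib)}
        tri = triangulate(a, b, pa, pb, k)
        expected = strip_cost_brute_force(a, b, pa, pb, k)
        assert tri.total_cost == pytest.approx(expected, rel=1e-9, abs=1e-9)


def test_k_one_ignores_sequence_alignment(rng):
    a = rng.normal(scale=5, size=(6, 3))
    b = rng.normal(scale=5, size=(7, 3))
    shifted = {i: float(min(i + 1, 6)) for i in range(6)}
    t1 = triangulate(a, b, _identity_partners(6), _identity_partners(6), 1.0)
    t2 = triangulate(a, b, shifted, {}, 1.0)
    assert t1.total_cost == pytest.approx(t2.total_cost)
    assert t1.path == t2.path


def test_strip_invariants(rng):
    """Translated alignments are equal-length, monotone, and cover every
    real alpha carbon of both windows."""
    for _ in range(50):
        m, n = rng.integers(2, 9, size=2)
        a = rng.normal(scale=5, size=(m, 3))
        b = rng.normal(scale=5, size=(n, 3))
        tri = triangulate(a, b, {}, {}, 1.0)
        ca = strip_to_curve_alignment(tri, a, b)
        assert len(ca.points_a) == len(ca.points_b)
        assert np.all(np.diff(ca.labels_a) >= 0)
        assert np.all(np.diff(ca.labels_b) >= 0)
        whole_a = {l for l in ca.labels_a if float(l).is_integer()}
        whole_b = {l for l in ca.labels_b if float(l).is_integer()}
        assert whole_a == set(range(m))
        assert whole_b == set(range(n))


def test_fan_inserts_uniform_pseudo_points():
    """One vertex of A fanning over three vertices of B yields pseudo
    points at thirds of a residue on A."""
    a = np.array([[0.0, 0, 0], [11.4, 0, 0]])
    b = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]])
    tri = triangulate(a, b, {}, {}, 1.0)
    ca = strip_to_curve_alignment(tri, a, b)
    np.testing.assert_allclose(ca.labels_b, [0, 1, 2, 3])
    np.testing.assert_allclose(ca.labels_a, [0, 1 / 3, 2 / 3, 1])
    # pseudo points lie exactly on the backbone segment
    np.testing.assert_allclose(ca.points_a[:, 0], [0, 3.8, 7.6, 11.4])


def test_cut_terminal_removes_divergent_tail():
    """A straight tail pointing away from the shared region is cut."""
    shared = helix_curve(12)
    direction = np.array([30.0, 0.0, 0.0])
    tail = shared[-1] + np.outer(np.arange(1, 11),
                                 direction / np.linalg.norm(direction) * 3.8)
    a = np.vstack([shared, tail])
    b = shared.copy()
    tri = triangulate(a, b, {}, {}, 1.0)
    end = cut_terminal(tri, a, b)
    assert end[1] == len(b) - 1
    assert end[0] <= len(shared)  # cut at or before the divergence point


def test_cut_terminal_equal_lengths_no_cut():
    pts = helix_curve(6)
    tri = triangulate(pts, pts, {}, {}, 1.0)
    assert cut_terminal(tri, pts, pts) == (5, 5)


# ---------------------------------------------------------------------------
# the driver

def test_bcalign_rigid_pair_is_exact(helix_pair):
    curve_a, curve_b, aln, _ = helix_pair
    res = bcalign(curve_a, curve_b, aln, k=1.0)
    assert res.rmsd < 1e-9
    assert res.converged
    assert res.iterations <= 2
    # superposition of the final curve alignment is a fixed point
    ca = res.curve_alignment
    again = superpose(ca.points_a, ca.points_b)
    assert abs(again.rmsd - 0.0) < 1e-9


def test_bcalign_symmetry(helix_pair, displacement_pair):
    for curve_a, curve_b, aln, _ in (helix_pair,):
        fwd = bcalign(curve_a, curve_b, aln, 1.0)
        rev = bcalign(curve_b, curve_a, aln, 1.0)
        assert fwd.rmsd == pytest.approx(rev.rmsd, abs=1e-6)


def test_bcalign_k_tradeoff(displacement_pair):
    """Sequence-register conflict: k = 1 fits structure (low RMSD, high
    RMSDalignseq), k = 0.01 follows the sequence alignment."""
    curve_a, curve_b, aln, _ = displacement_pair
    hi = bcalign(curve_a, curve_b, aln, k=1.0)
    lo = bcalign(curve_a, curve_b, aln, k=0.01)
    assert hi.rmsd <= lo.rmsd + 1e-9
    assert hi.rmsd_align_seq >= lo.rmsd_align_seq - 1e-9
    assert hi.rmsd < 0.1
    assert lo.rmsd_align_seq < 0.05


def test_bcalign_k1_invariant_to_residue_codes(helix_pair):
    """Pure geometry: permuting residue codes cannot change the result."""
    curve_a, curve_b, aln, _ = helix_pair
    res = bcalign(curve_a, curve_b, aln, 1.0)
    from bcalign.io_structures import BackboneCurve
    scrambled = BackboneCurve(curve_b.points, curve_b.residue_numbers,
                              curve_b.residue_codes[::-1], "B", "scrambled")
    res2 = bcalign(curve_a, scrambled, aln, 1.0)
    assert res.rmsd == pytest.approx(res2.rmsd, abs=1e-9)


def test_bcalign_validation(helix_pair):
    curve_a, curve_b, aln, _ = helix_pair
    with pytest.raises(ValueError):
        bcalign(curve_a, curve_b, aln, k=0.0)
    from bcalign.seq_align import SequenceAlignment
    tiny = SequenceAlignment(((0, 0), (1, 1)))
    with pytest.raises(ValueError, match="insufficient sequence anchor"):
        bcalign(curve_a, curve_b, tiny, 1.0)


def test_bcalign_fixed_windows_never_cuts(displacement_pair):
    curve_a, curve_b, aln, _ = displacement_pair
    res = bcalign(curve_a, curve_b, aln, 1.0, fixed_windows=True)
    exact = aln.exact_pairs
    assert res.terminal_cuts["n_a"] == exact[0][0]
    assert res.terminal_cuts["n_b"] == exact[0][1]
    assert res.converged


def test_bcalign_iteration_cap(displacement_pair):
    curve_a, curve_b, aln, _ = displacement_pair
    for k in (0.01, 1.0):
        res = bcalign(curve_a, curve_b, aln, k)
        assert res.iterations <= 20
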