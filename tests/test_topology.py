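import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bcalign.core import CurveAlignment
from bcalign.fixtures import random_curve_alignment
from bcalign.topology import (check_topology, classify, end_contractions,
                              find_moves, mean_overlap,
                              morph_self_intersections, writhe)
from oracles import dense_time_events


def _identity_ca(points_a, points_b):
    labels = np.arange(len(points_a), dtype=float)
    return CurveAlignment(np.asarray(points_a, float),
                          np.asarray(points_b, float), labels, labels.copy())


def test_translation_morph_has_no_events():
    """A rigidly translated planar arc never passes through itself."""
    t = np.linspace(0, np.pi, 12)
    arc = np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)])
    ca = _identity_ca(arc, arc + np.array([3.0, 1.0, 2.0]))
    assert morph_self_intersections(ca) == []


def test_chirality_flip_has_single_resolvable_event(chirality_pair):
    curve_a, curve_b, _, truth = chirality_pair
    ca = _identity_ca(curve_a.points, curve_b.points)
    events = morph_self_intersections(ca)
    assert len(events) == truth["n_events"] == 1
    moves = find_moves(events, ca)
    assert len(moves) == 1
    assert moves[0].kind == "type1"
    assert moves[0].span <= 15
    report = classify(events, moves)
    assert not report.has_essential


def test_blocking_arc_makes_type1_inadmissible(blocked_chirality_pair):
    """A static arc threading the loop pierces the spanned surface."""
    curve_a, curve_b, _, truth = blocked_chirality_pair
    ca = _identity_ca(curve_a.points, curve_b.points)
    events = morph_self_intersections(ca)
    assert len(events) == 1
    assert find_moves(events, ca) == []
    report = classify(events, [])
    assert report.has_essential


def test_threading_pair_is_essential_at_span_cap(threading_pair):
    curve_a, curve_b, _, truth = threading_pair
    ca = _identity_ca(curve_a.points, curve_b.points)
    events = morph_self_intersections(ca)
    assert len(events) >= truth["min_events"]
    assert find_moves(events, ca, max_span=15) == []
    # the chain distance between the crossing segments exceeds the cap
    for e in events:
        assert e.segments[1] - e.segments[0] + 1 > 15


def test_end_contraction_resolves_threading(threading_pair):
    curve_a, curve_b, _, truth = threading_pair
    ca = _identity_ca(curve_a.points, curve_b.points)
    events = morph_self_intersections(ca)
    assert end_contractions(events, ca, enabled=False) == []
    moves = end_contractions(events, ca, enabled=True)
    assert truth["contraction_resolves"]
    assert moves and moves[0].kind == "end_contraction"
    assert moves[0].contraction_depth <= 7.5
    resolved = {i for m in moves for i in m.resolved_events}
    assert resolved == set(range(len(events)))


def test_events_match_dense_time_oracle():
    """Cubic-root events agree with a refined dense-time minimum-distance
    scan in count and segment pairs."""
    for seed in range(40):
        ca = random_curve_alignment(10 + seed % 8, seed=seed)
        events = morph_self_intersections(ca)
        oracle = dense_time_events(ca.points_a, ca.points_b)
        assert sorted(e.segments for e in events) == \
            sorted((i, j) for i, j, _ in oracle)


def test_event_signs_are_writhe_jump_directions():
    """Across each event the Gauss-sum writhe jumps by 2 * sign (the
    continuous drift is removed by Richardson extrapolation)."""
    eps = 1e-8
    checked = 0
    for seed in range(30):
        ca = random_curve_alignment(12, seed=seed)
        events = morph_self_intersections(ca)

        def wr(t):
            return writhe((1 - t) * ca.points_a + t * ca.points_b)

        for e in events:
            j1 = wr(e.time + eps) - wr(e.time - eps)
            j2 = wr(e.time + 2 * eps) - wr(e.time - 2 * eps)
            jump = 2 * j1 - j2
            assert jump == pytest.approx(2 * e.sign, abs=1e-6)
            checked += 1
    assert checked >= 5


def test_rigid_motion_invariance(chirality_pair, rng):
    curve_a, curve_b, _, _ = chirality_pair
    ca = _identity_ca(curve_a.points, curve_b.points)
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(scale=20, size=3)
    ca2 = _identity_ca(curve_a.points @ rot.T + shift,
                       curve_b.points @ rot.T + shift)
    ev1 = morph_self_intersections(ca)
    ev2 = morph_self_intersections(ca2)
    assert [e.segments for e in ev1] == [e.segments for e in ev2]
    assert [e.sign for e in ev1] == [e.sign for e in ev2]
    assert [e.time for e in ev1] == pytest.approx(
        [e.time for e in ev2], abs=1e-9)
    assert mean_overlap(ca) == pytest.approx(mean_overlap(ca2), rel=1e-9)


def test_mean_overlap_behaviour():
    # well separated morph -> zero overlap
    line = np.column_stack([np.arange(8.0) * 3.8, np.zeros(8), np.zeros(8)])
    ca = _identity_ca(line, line + np.array([0, 50.0, 0]))
    assert mean_overlap(ca) == 0.0
    # two residues forced together at t = 0.5
    a = line.copy()
    b = line.copy()
    a[0] = [0.0, 20.0, 0]
    b[0] = [0.0, -20.0, 0]
    a[0], b[0] = [line[4][0], 20.0, 0], [line[4][0], -20.0, 0]
    ca2 = _identity_ca(a, b)
    v1 = mean_overlap(ca2, clash_radius=2.0)
    v2 = mean_overlap(ca2, clash_radius=3.0)
    assert 0 < v1 < v2
    # quadrature refinement changes the value by < 1%
    v64 = mean_overlap(ca2, n_time=64)
    v256 = mean_overlap(ca2, n_time=256)
    assert abs(v64 - v256) / v256 < 0.01


def test_classify_report_fields(chirality_pair):
    curve_a, curve_b, _, _ = chirality_pair
    ca = _identity_ca(curve_a.points, curve_b.points)
    report = check_topology(ca)
    assert report.mean_overlap > 0
    assert len(report.events) == 1
    assert not report.has_essential
    assert report.untangling_ge_140 == (report.untangling_length >= 140.0)
    d = report.to_dict()
    assert d["n_events"] == 1 and d["n_essential"] == 0
    # no-event morph
    line = np.column_stack([np.arange(6.0) * 3.8, np.zeros(6), np.zeros(6)])
    empty = check_topology(_identity_ca(line, line + np.array([0, 30.0, 0])))
    assert empty.events == () and not empty.has_essential
    assert empty.untangling_length == 0.0


def test_unequal_cardinalities_rejected():
    a = np.zeros((5, 3))
    with pytest.raises(ValueError):
        CurveAlignment(a, np.zeros((4, 3)), np.arange(5.0), np.arange(4.0))
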