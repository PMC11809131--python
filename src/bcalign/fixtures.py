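"""Deterministic synthetic backbone-curve pairs with known ground truth.

Real structure pairs with interesting topology are large and must be
downloaded; these generators build small alpha-carbon polygons (consecutive
spacing 3.8 Angstrom) whose alignment and morph topology are known by
construction:

* ``helix`` — an ideal alpha-helical curve (rise 1.5 A, radius 2.3 A) and a
  rigidly moved copy: zero events, RMSD 0.
* ``loop_chirality_pair`` — a ~12-residue loop whose exit strand passes
  over its entry in one conformation and under it in the other (a loop of
  one chirality morphing to the mirror one): exactly one morph
  self-intersection, avoidable by a type 1 move when the surroundings are
  clear; a ``blocked`` variant threads a static arc through the loop so the
  move is inadmissible.
* ``threading_pair`` — a terminal strand passing on opposite sides of a
  fixed open ring, with a long spacer so the self-intersecting arc exceeds
  the move-span cap: the events are essential (but removable by
  end-contraction of the terminal).
* ``loop_displacement_pair`` — identical sequences whose backbone bump
  sits one residue later along chain B, putting the structure-based and
  sequence-based optima one residue apart: the fixture for the
  RMSD-vs-RMSDalignseq trade-off in the weight k.
* ``random_walk`` — self-avoiding fixed-step walks for property tests.

Same spec + seed give bit-identical curves.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Tuple

import numpy as np

from .core import CurveAlignment
from .io_structures import BackboneCurve
from .seq_align import SequenceAlignment, identity_alignment

__all__ = ["FixtureSpec", "make_pair", "helix_curve", "random_walk",
           "random_curve_alignment", "CA_SPACING"]

CA_SPACING = 3.8
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    kind: str                    # helix | loop_chirality_pair | threading_pair
    #                            # | loop_displacement_pair | random_walk
    n_residues: int = 40
    seed: int = 0
    blocked: bool = False        # chirality pair: thread a blocking arc


def _sequence(n: int) -> str:
    return "".join(_AA[i % len(_AA)] for i in range(n))


def _curve(points: np.ndarray, chain_id: str, source: str) -> BackboneCurve:
    n = len(points)
    return BackboneCurve(points, tuple(range(1, n + 1)), _sequence(n),
                         chain_id, source)


def _resample(path: np.ndarray, step: float = CA_SPACING) -> np.ndarray:
    """Place points along a dense polyline so consecutive placed points are
    exactly ``step`` apart (chord distance)."""
    out = [path[0]]
    i = 0
    cur = path[0].astype(float)
    while i < len(path) - 1:
        nxt = path[i + 1]
        d = np.linalg.norm(nxt - cur)
        if d < 1e-12:
            i += 1
            cur = nxt.astype(float)
            continue
        # walk along the polyline until the chord from the last placed
        # point reaches `step`
        lo, hi = 0.0, 1.0
        end_dist = np.linalg.norm((cur + (nxt - cur)) - out[-1])
        if end_dist < step:
            i += 1
            cur = nxt.astype(float)
            continue
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            p = cur + mid * (nxt - cur)
            if np.linalg.norm(p - out[-1]) < step:
                lo = mid
            else:
                hi = mid
        p = cur + hi * (nxt - cur)
        out.append(p)
        cur = p
    return np.array(out)


def helix_curve(n: int, rise: float = HELIX_RISE,
                radius: float = HELIX_RADIUS) -> np.ndarray:
    """Ideal helical alpha-carbon curve with exact 3.8 A chords."""
    chord_sq = CA_SPACING ** 2 - rise ** 2
    theta = 2.0 * np.arcsin(np.sqrt(chord_sq) / (2.0 * radius))
    i = np.arange(n)
    return np.column_stack([radius * np.cos(i * theta),
                            radius * np.sin(i * theta),
                            rise * i])


def random_walk(n: int, rng: np.random.Generator,
                min_separation: float = 4.0,
                max_tries: int = 200) -> np.ndarray:
    """Fixed-step (3.8 A) self-avoiding walk: non-adjacent vertices stay at
    least ``min_separation`` apart, keeping morph crossings transversal."""
    pts = [np.zeros(3)]
    while len(pts) < n:
        placed = False
        for _ in range(max_tries):
            v = rng.normal(size=3)
            v *= CA_SPACING / np.linalg.norm(v)
            cand = pts[-1] + v
            prior = np.array(pts[:-1]) if len(pts) > 1 else None
            if prior is None or np.min(
                    np.linalg.norm(prior - cand, axis=1)) >= min_separation:
                pts.append(cand)
                placed = True
                break
        if not placed:         # back up one step and retry
            pts.pop()
            if not pts:
                pts = [np.zeros(3)]
    return np.array(pts)


def random_curve_alignment(n: int, seed: int,
                           spread: float = 6.0) -> CurveAlignment:
    """Two independent self-avoiding walks as a 1:1 aligned morph; the
    second is offset slightly so the morph sweeps through shared space."""
    rng = np.random.default_rng(seed)
    a = random_walk(n, rng)
    b = random_walk(n, rng) + rng.normal(scale=spread, size=3)
    labels = np.arange(n, dtype=float)
    return CurveAlignment(a, b, labels, labels.copy())


# ---------------------------------------------------------------------------
# constructions with topology ground truth

def _chirality_points(sign: float, blocked: bool) -> np.ndarray:
    """Open loop (12-gon, radius ~7.34 so chords are 3.8 A) whose exit
    strand crosses over (+) or under (-) the loop's entry segment."""
    r = CA_SPACING / (2.0 * np.sin(np.pi / 12))
    ang = np.arange(12) * (2.0 * np.pi / 12)
    ring = np.column_stack([r * np.cos(ang), r * np.sin(ang),
                            np.zeros(12)])
    # exit strand from the last ring vertex toward a point above the middle
    # of the ring's first segment, then onward
    target = 0.5 * (ring[0] + ring[1]) + np.array([0.0, 0.0, sign * 2.0])
    u = target - ring[11]
    u *= CA_SPACING / np.linalg.norm(u)
    exit_pts = [ring[11] + u, ring[11] + 2 * u, ring[11] + 3 * u]
    pts = [*ring, *exit_pts]
    if blocked:
        # a static arc threading the loop along the axis through its center
        top = np.array([0.0, 0.0, 12.0])
        bottom = np.array([0.0, 0.0, -12.0])
        way = np.array([pts[-1], pts[-1] + np.array([0, 14.0, 8.0]),
                        top + np.array([0, 4.0, 2.0]), top, bottom])
        thread = _resample(way)[1:]
        pts = [*pts, *thread]
    return np.array(pts)


def _loop_chirality_pair(blocked: bool):
    a = _chirality_points(+1.0, blocked)
    b = _chirality_points(-1.0, blocked)
    n = len(a)
    truth = {
        "n_events": 1,
        "type1_admissible": not blocked,
        "rmsd_upper_bound": 3.0,
    }
    return (_curve(a, "A", "chirality_A"), _curve(b, "B", "chirality_B"),
            identity_alignment(n), truth)


def _threading_points(side: float) -> np.ndarray:
    """Open ring in the xy plane plus a long outboard spacer and a terminal
    strand crossing the ring's disc at height ``side`` * 5 A."""
    r = CA_SPACING / (2.0 * np.sin(np.pi / 12))
    # ring spans 330 degrees, gap at the bottom
    ang = np.deg2rad(-75.0 + 30.0 * np.arange(12))
    ring = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(12)])
    z_end = side * 5.0
    # outboard spacer (radius > 12, so its sweep stays clear of the ring)
    # followed by a terminal strand that enters the ring's disc and ends
    # above/below its center: it pokes through in one conformation and not
    # in the other (all z flips sign), so the morph drags the terminal
    # through the ring wall far (in chain distance) from the ring segments
    way = np.array([
        ring[-1],
        [-4.0, -16.0, 0.3 * z_end],
        [-16.0, -14.0, 0.6 * z_end],
        [-21.0, -2.0, 0.8 * z_end],
        [-19.0, 8.0, z_end],
        [-13.0, 3.0, z_end],
        [2.0, 3.0, 1.3 * z_end],
    ])
    moving = _resample(way)[1:]
    return np.vstack([ring, moving])


def _threading_pair():
    a = _threading_points(+1.0)
    b = _threading_points(-1.0)
    n = len(a)
    truth = {
        "min_events": 1,
        "resolvable_small_moves": False,
        "contraction_resolves": True,
    }
    return (_curve(a, "A", "threading_A"), _curve(b, "B", "threading_B"),
            identity_alignment(n), truth)


def _displacement_path(bump_at: float) -> np.ndarray:
    """Straight backbone along x with a smooth out-of-line excursion
    ("bump") of about 5 residues starting at x = ``bump_at``."""
    xs = np.linspace(-CA_SPACING, 170.0, 700)
    height = 7.0
    width = 12.0
    z = height * np.exp(-0.5 * ((xs - bump_at - width) / (0.45 * width)) ** 2)
    return np.column_stack([xs, np.zeros_like(xs), z])


def _loop_displacement_pair(n: int = 40):
    """Identical backbones (straight stretch + ~5-residue loop excursion)
    whose sequences are displaced by one residue, so the input sequence
    alignment is a one-residue register shift while the structural optimum
    is the identity: raising k trades sequence-alignment fidelity
    (RMSDalignseq) for structural fit (RMSD)."""
    from .seq_align import needleman_wunsch
    pts = _resample(_displacement_path(25.0))[:n]
    seq_a = _sequence(n)
    # delete one residue before the loop and insert one after it: the
    # optimal sequence alignment shifts the loop region by one residue
    # (flanks stay identity), while the backbones are identical
    lo, hi = 5, 17
    seq_b = seq_a[:lo] + seq_a[lo + 1:hi] + "G" + seq_a[hi:]
    curve_a = BackboneCurve(pts, tuple(range(1, n + 1)), seq_a, "A",
                            "displacement_A")
    curve_b = BackboneCurve(pts.copy(), tuple(range(1, n + 1)), seq_b, "B",
                            "displacement_B")
    aln = needleman_wunsch(seq_a, seq_b)
    truth = {"register_shift": 1, "shift_window": (lo + 1, hi - 1)}
    return (curve_a, curve_b, aln, truth)


def make_pair(spec: FixtureSpec) -> Tuple[BackboneCurve, BackboneCurve,
                                          SequenceAlignment, Dict]:
    """Build a fixture pair: two curves, their input sequence alignment and
    a ground-truth record (expected event counts, admissibility, bounds)."""
    if spec.n_residues < 4:
        raise ValueError("fixtures need at least 4 residues")
    if spec.kind == "helix":
        pts = helix_curve(spec.n_residues)
        rng = np.random.default_rng(spec.seed)
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(rng=rng).as_matrix()
        moved = pts @ rot.T + rng.normal(scale=10.0, size=3)
        truth = {"n_events": 0, "rmsd_upper_bound": 1e-6}
        return (_curve(pts, "A", "helix_A"), _curve(moved, "B", "helix_B"),
                identity_alignment(spec.n_residues), truth)
    if spec.kind == "loop_chirality_pair":
        return _loop_chirality_pair(spec.blocked)
    if spec.kind == "threading_pair":
        return _threading_pair()
    if spec.kind == "loop_displacement_pair":
        return _loop_displacement_pair(spec.n_residues)
    if spec.kind == "random_walk":
        rng = np.random.default_rng(spec.seed)
        a = random_walk(spec.n_residues, rng)
        b = random_walk(spec.n_residues, rng)
        truth = {}
        return (_curve(a, "A", f"walk_{spec.seed}_A"),
                _curve(b, "B", f"walk_{spec.seed}_B"),
                identity_alignment(spec.n_residues), truth)
    raise ValueError(f"unknown fixture kind: {spec.kind!r}")
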