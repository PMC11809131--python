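"""Steric and topological obstructions to morphing one aligned curve into
the other.

Given a gap-free curve alignment, the straight-line interpolation
X_p(t) = (1 - t) A_p + t B_p defines a morph between the two backbones.
This module finds every instant where the morphing chain passes through
itself (a *morph self-intersection*), tries to avoid such events with
local type 1 / type 2 moves that generalize Reidemeister moves (each
rearranging at most 15 backbone line segments), optionally with
end-contractions of chain terminals, classifies unavoidable events as
*essential*, sums the extra motion length of the chosen moves (untangling
length; >= 140 Angstrom is the rule of thumb for a significant structural
variation), and scores steric strain by the MeanOverlap.

Self-intersections are found exactly: for each non-adjacent segment pair
the signed volume spanned by the four moving endpoints is a cubic in t;
its roots in (0, 1) at which the segments truly cross (transversally) are
the events.  The crossing handedness is the direction of the writhe jump:
the polygonal Gauss-sum writhe of the morphing curve jumps by 2 * sign
across each event.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import CurveAlignment

__all__ = ["SelfIntersectionEvent", "UntanglingMove", "TopologyReport",
           "morph_self_intersections", "mean_overlap", "find_moves",
           "end_contractions", "classify", "check_topology", "writhe",
           "write_events_tsv", "write_morph_pdb",
           "MAX_MOVE_SPAN", "MAX_CONTRACTION_DEPTH", "UNTANGLING_THRESHOLD"]

#: A type 1/2 move may rearrange at most this many backbone line segments.
MAX_MOVE_SPAN = 15
#: End-contractions may retract at most this many residues from a terminal.
MAX_CONTRACTION_DEPTH = 7.5
#: Untangling motions at least this long (Angstrom) flag a significant
#: structural variation.
UNTANGLING_THRESHOLD = 140.0

_VOL_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class SelfIntersectionEvent:
    """The morphing chain passes through itself at ``time``: segments
    ``segments[0] < segments[1]`` intersect at ``point``; the writhe of the
    interpolating curve jumps by ``2 * sign`` across the event."""

    time: float
    segments: Tuple[int, int]
    point: np.ndarray
    sign: int


@dataclasses.dataclass(frozen=True)
class UntanglingMove:
    kind: str                       # "type1" | "type2" | "end_contraction"
    resolved_events: Tuple[int, ...]  # indices into the event list
    span: int                       # backbone line segments rearranged
    added_length: float             # Angstrom beyond the linear morph
    contraction_depth: float = 0.0  # residues, terminals only


@dataclasses.dataclass(frozen=True)
class TopologyReport:
    events: Tuple[SelfIntersectionEvent, ...]
    moves: Tuple[UntanglingMove, ...]
    essential_events: Tuple[SelfIntersectionEvent, ...]
    untangling_length: float
    mean_overlap: float
    has_essential: bool
    untangling_ge_140: bool

    def to_dict(self) -> dict:
        return {
            "n_events": len(self.events),
            "events": [{"t": e.time, "i": e.segments[0], "j": e.segments[1],
                        "sign": e.sign, "point": list(map(float, e.point))}
                       for e in self.events],
            "moves": [{"kind": m.kind, "resolved": list(m.resolved_events),
                       "span": m.span, "added_length": m.added_length,
                       "contraction_depth": m.contraction_depth}
                      for m in self.moves],
            "n_essential": len(self.essential_events),
            "untangling_length": self.untangling_length,
            "mean_overlap": self.mean_overlap,
            "has_essential": self.has_essential,
            "untangling_ge_140": self.untangling_ge_140,
        }


# ---------------------------------------------------------------------------
# writhe (polygonal Gauss sum)

def _pair_solid_angle(p1, p2, p3, p4) -> float:
    """Gauss-integral contribution Omega / (4 pi) of segment (p1, p2)
    against segment (p3, p4) (Klenin & Langowski closed form)."""
    r13, r14 = p3 - p1, p4 - p1
    r23, r24 = p3 - p2, p4 - p2
    r34, r12 = p4 - p3, p2 - p1
    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)
    norms = [np.linalg.norm(v) for v in (n1, n2, n3, n4)]
    if min(norms) < 1e-12:
        return 0.0
    n1, n2, n3, n4 = (v / s for v, s in zip((n1, n2, n3, n4), norms))
    s = (math.asin(np.clip(n1 @ n2, -1, 1)) + math.asin(np.clip(n2 @ n3, -1, 1))
         + math.asin(np.clip(n3 @ n4, -1, 1)) + math.asin(np.clip(n4 @ n1, -1, 1)))
    return s / (4.0 * math.pi) * np.sign(np.cross(r34, r12) @ r13)


def writhe(points: np.ndarray) -> float:
    """Gauss-sum writhe of an open polygonal curve."""
    pts = np.asarray(points, dtype=float)
    n_seg = len(pts) - 1
    total = 0.0
    for i in range(n_seg):
        for j in range(i + 2, n_seg):
            total += _pair_solid_angle(pts[i], pts[i + 1], pts[j], pts[j + 1])
    return 2.0 * total


# ---------------------------------------------------------------------------
# self-intersection events

def _morph_points(ca: CurveAlignment, t: float) -> np.ndarray:
    return (1.0 - t) * ca.points_a + t * ca.points_b


def _cubic_coeffs(u0, u1, v0, v1, w0, w1) -> np.ndarray:
    """Coefficients (c0..c3) of ((u0+t u1) x (v0+t v1)) . (w0+t w1)."""
    c_0 = np.cross(u0, v0)
    c_1 = np.cross(u0, v1) + np.cross(u1, v0)
    c_2 = np.cross(u1, v1)
    return np.array([c_0 @ w0,
                     c_1 @ w0 + c_0 @ w1,
                     c_2 @ w0 + c_1 @ w1,
                     c_2 @ w1])


def _real_roots_01(coeffs: np.ndarray, tol: float = 1e-9) -> List[float]:
    """Real roots in the open interval (0, 1) of c0 + c1 t + c2 t^2 + c3 t^3."""
    scale = np.max(np.abs(coeffs))
    if scale < tol:
        return []
    c = coeffs / scale
    # numpy wants highest degree first and a nonzero leading coefficient
    poly = c[::-1]
    while len(poly) > 1 and abs(poly[0]) < 1e-13:
        poly = poly[1:]
    if len(poly) <= 1:
        return []
    roots = np.roots(poly)
    out = []
    for r in roots:
        if abs(r.imag) < 1e-9 and tol < r.real < 1.0 - tol:
            out.append(float(r.real))
    return sorted(out)


def _segment_intersection_params(a, b, c, d) -> Optional[Tuple[float, float, np.ndarray]]:
    """Intersection parameters (u, v) of coplanar segments a-b and c-d, or
    None if they miss each other or are (near) parallel."""
    e1, e2, w = b - a, d - c, c - a
    mat = np.stack([e1, -e2], axis=1)          # (3, 2)
    sol, res, rank, _ = np.linalg.lstsq(mat, w, rcond=None)
    if rank < 2:
        return None                            # parallel: non-transversal
    u, v = float(sol[0]), float(sol[1])
    point = a + u * e1
    gap = np.linalg.norm(point - (c + v * e2))
    seg_scale = max(np.linalg.norm(e1), np.linalg.norm(e2), 1e-12)
    if gap > 1e-6 * max(seg_scale, 1.0) + 1e-9:
        return None
    eps = 1e-9
    if -eps <= u <= 1 + eps and -eps <= v <= 1 + eps:
        return u, v, point
    return None


def morph_self_intersections(ca: CurveAlignment) -> List[SelfIntersectionEvent]:
    """All events where the linearly interpolating chain passes through
    itself, sorted by time.

    For every segment pair (i, j) with |i - j| >= 2 the signed volume of
    the four moving endpoints is a cubic in t; transversal roots in (0, 1)
    at which the segments intersect within both parameter ranges are
    events.  Near-tangential (double) roots are discarded.  The sign is
    the direction of the pair's Gauss-contribution jump across the event.
    """
    pa, pb = ca.points_a, ca.points_b
    if len(pa) != len(pb):
        raise ValueError("alignment has gaps: unequal cardinalities")
    d = pb - pa
    n_seg = len(pa) - 1
    events: List[SelfIntersectionEvent] = []
    for i in range(n_seg):
        a0, da = pa[i], d[i]
        b0, db = pa[i + 1], d[i + 1]
        u0, u1 = b0 - a0, db - da
        for j in range(i + 2, n_seg):
            c0, dc = pa[j], d[j]
            e0, de = pa[j + 1], d[j + 1]
            v0, v1 = e0 - c0, de - dc
            w0, w1 = c0 - a0, dc - da
            coeffs = _cubic_coeffs(u0, u1, v0, v1, w0, w1)
            # normalized-volume tolerance: scale by typical segment lengths
            norm = (np.linalg.norm(u0) + np.linalg.norm(u1)) * \
                   (np.linalg.norm(v0) + np.linalg.norm(v1)) * \
                   (np.linalg.norm(w0) + np.linalg.norm(w1) + 1.0)
            for t in _real_roots_01(coeffs, tol=_VOL_TOL):
                # transversality: the volume must change sign linearly
                deriv = np.polyval(np.polyder(coeffs[::-1]), t)
                if abs(deriv) < _VOL_TOL * max(norm, 1.0):
                    continue
                at, bt = a0 + t * da, b0 + t * db
                ct, dt_ = c0 + t * dc, e0 + t * de
                hit = _segment_intersection_params(at, bt, ct, dt_)
                if hit is None:
                    continue
                _, _, point = hit
                # the crossing handedness is the direction of the Gauss
                # contribution's jump, which for a transversal crossing is
                # the (negated) sign of the volume's time derivative
                sign = -1 if deriv > 0 else 1
                events.append(SelfIntersectionEvent(t, (i, j), point, sign))
    events.sort(key=lambda e: (e.time, e.segments))
    return events


# ---------------------------------------------------------------------------
# MeanOverlap

def mean_overlap(ca: CurveAlignment, clash_radius: float = 2.0,
                 n_time: int = 64) -> float:
    """Average over morph time and residues of one residue's summed sphere
    overlaps (depth max(0, 2 r - d)) with all non-adjacent residues, in
    Angstrom.  Time is integrated by the trapezoid rule on a uniform grid.
    """
    n = len(ca.points_a)
    times = np.linspace(0.0, 1.0, n_time)
    idx = np.arange(n)
    nonadj = np.abs(idx[:, None] - idx[None, :]) >= 2
    per_time = np.empty(n_time)
    for q, t in enumerate(times):
        x = _morph_points(ca, t)
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt(np.sum(diff * diff, axis=2))
        overlap = np.maximum(0.0, 2.0 * clash_radius - dist)
        per_time[q] = np.mean(np.sum(np.where(nonadj, overlap, 0.0), axis=1))
    return float(np.trapezoid(per_time, times))


# ---------------------------------------------------------------------------
# untangling moves

def _segment_triangle_hit(p, q, tri_a, tri_b, tri_c, eps: float = 1e-9) -> bool:
    """Does segment p-q meet triangle (tri_a, tri_b, tri_c)?"""
    d = q - p
    e1, e2 = tri_b - tri_a, tri_c - tri_a
    h = np.cross(d, e2)
    det = e1 @ h
    if abs(det) < 1e-14:
        return False
    f = 1.0 / det
    s = p - tri_a
    u = f * (s @ h)
    if u < -eps or u > 1 + eps:
        return False
    qv = np.cross(s, e1)
    v = f * (d @ qv)
    if v < -eps or u + v > 1 + eps:
        return False
    t = f * (e2 @ qv)
    return -eps <= t <= 1 + eps


def _fan_is_clear(ca: CurveAlignment, apex: np.ndarray,
                  arc_vertices: Sequence[int], excluded: set,
                  times: Sequence[float]) -> bool:
    """Is the triangle fan from ``apex`` over the arc (built at the crossing
    time) disjoint from the rest of the interpolating curve near that time?"""
    n_seg = len(ca.points_a) - 1
    fans = []
    for r in range(len(arc_vertices) - 1):
        fans.append((arc_vertices[r], arc_vertices[r + 1]))
    arc_pts_cache: Dict[float, np.ndarray] = {}
    for t in times:
        x = _morph_points(ca, t)
        arc_pts_cache[t] = x
    # fan triangles are built at the central time (first entry of times is
    # arranged to be the crossing time by the caller)
    x_cross = arc_pts_cache[times[0]]
    triangles = [(apex, x_cross[r0], x_cross[r1]) for r0, r1 in fans]
    for t in times:
        x = arc_pts_cache[t]
        for s in range(n_seg):
            if s in excluded:
                continue
            for ta, tb, tc in triangles:
                if _segment_triangle_hit(x[s], x[s + 1], ta, tb, tc):
                    return False
    return True


def _sample_times(t_lo: float, t_hi: float, center: float,
                  n: int = 5) -> List[float]:
    ts = [center] + list(np.linspace(max(0.0, t_lo), min(1.0, t_hi), n))
    return ts


def find_moves(events: Sequence[SelfIntersectionEvent], ca: CurveAlignment,
               max_span: int = MAX_MOVE_SPAN,
               time_window: float = 0.05) -> List[UntanglingMove]:
    """Admissible type 1 / type 2 moves, selected to resolve the maximal
    number of events at the smallest total added morph length.

    A type 1 move treats one event whose self-intersecting arc (the chain
    between the two crossing segments) spans at most ``max_span`` segments
    and whose spanned surface (triangle fan from the crossing point over
    the arc at the crossing time) is disjoint from the remainder of the
    curve near the crossing time.  A type 2 move treats an opposite-sign
    event pair whose sliding arc satisfies the same span and surface
    conditions.
    """
    candidates: List[UntanglingMove] = []
    for idx, e in enumerate(events):
        i, j = e.segments
        span = j - i + 1
        if span > max_span:
            continue
        arc_vertices = list(range(i + 1, j + 1))
        excluded = set(range(i - 1, j + 2))
        times = _sample_times(e.time - time_window, e.time + time_window,
                              e.time)
        if _fan_is_clear(ca, e.point, arc_vertices, excluded, times):
            x = _morph_points(ca, e.time)
            added = float(sum(2.0 * np.linalg.norm(x[v] - e.point)
                              for v in arc_vertices))
            candidates.append(UntanglingMove("type1", (idx,), span, added))

    for (ia, ea), (ib, eb) in itertools.combinations(enumerate(events), 2):
        if ea.sign * eb.sign != -1:
            continue
        i_lo, i_hi = sorted((ea.segments[0], eb.segments[0]))
        j_lo, j_hi = sorted((ea.segments[1], eb.segments[1]))
        span_i, span_j = i_hi - i_lo + 1, j_hi - j_lo + 1
        if span_i <= span_j:
            lo, hi, span = i_lo, i_hi, span_i
            partner = (ea.segments[1], eb.segments[1])
            partner_span = span_j
        else:
            lo, hi, span = j_lo, j_hi, span_j
            partner = (ea.segments[0], eb.segments[0])
            partner_span = span_i
        # a genuine over-and-back slide crosses the same local stretch of
        # the other arc twice; distant partner segments are not one slide
        if span > max_span or partner_span > max_span:
            continue
        t_mid = 0.5 * (ea.time + eb.time)
        x_mid = 0.5 * (ea.point + eb.point)
        arc_vertices = list(range(lo, hi + 2))
        excluded = set(range(lo - 1, hi + 2))
        for s in partner:
            excluded.update(range(s - 1, s + 2))
        times = _sample_times(min(ea.time, eb.time) - time_window,
                              max(ea.time, eb.time) + time_window, t_mid)
        if _fan_is_clear(ca, x_mid, arc_vertices, excluded, times):
            x = _morph_points(ca, t_mid)
            added = float(sum(np.linalg.norm(x[v] - ea.point)
                              + np.linalg.norm(x[v] - eb.point)
                              for v in arc_vertices))
            candidates.append(UntanglingMove("type2", tuple(sorted((ia, ib))),
                                             span, added))
    return _select_moves(candidates)


def _select_moves(candidates: List[UntanglingMove]) -> List[UntanglingMove]:
    """Subset of moves with disjoint resolved-event sets maximizing the
    number of resolved events, ties broken by minimal total added length."""
    if not candidates:
        return []
    if len(candidates) <= 12:
        best_n, best_len = 0, math.inf
        chosen: List[UntanglingMove] = []
        for r in range(1, len(candidates) + 1):
            for combo in itertools.combinations(range(len(candidates)), r):
                seen: set = set()
                ok = True
                for c in combo:
                    ev = set(candidates[c].resolved_events)
                    if ev & seen:
                        ok = False
                        break
                    seen |= ev
                if not ok:
                    continue
                n_res = len(seen)
                length = sum(candidates[c].added_length for c in combo)
                if n_res > best_n or (n_res == best_n
                                      and length < best_len - 1e-12):
                    best_n, best_len = n_res, length
                    chosen = [candidates[c] for c in combo]
        return chosen
    # greedy fallback for pathological numbers of candidates
    order = sorted(candidates,
                   key=lambda m: (-len(m.resolved_events), m.added_length))
    seen: set = set()
    out = []
    for m in order:
        ev = set(m.resolved_events)
        if ev & seen:
            continue
        seen |= ev
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# end-contractions

def _restricted(ca: CurveAlignment, start: int, stop: int) -> CurveAlignment:
    return CurveAlignment(ca.points_a[start:stop], ca.points_b[start:stop],
                          ca.labels_a[start:stop], ca.labels_b[start:stop])


def _arc_lengths(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def end_contractions(events: Sequence[SelfIntersectionEvent],
                     ca: CurveAlignment,
                     max_depth: float = MAX_CONTRACTION_DEPTH,
                     enabled: bool = False) -> List[UntanglingMove]:
    """Terminal retractions that avoid events (off by default: contraction
    is only physically possible when the domain terminal is a chain
    terminal, so it is provided as an option, not applied).

    A contraction of depth d retracts the terminal d residues along the
    backbone before the morph and re-extends after; events are recounted on
    the remaining sub-curve.  At most one contraction per terminal, at the
    smallest depth resolving the most events, depth capped at ``max_depth``.
    """
    if not enabled or not events:
        return []
    n = len(ca.points_a)
    arc_a = _arc_lengths(ca.points_a)
    arc_b = _arc_lengths(ca.points_b)
    moves: List[UntanglingMove] = []
    resolved_so_far: set = set()
    for terminal in ("N", "C"):
        best = None
        for depth in range(1, int(max_depth) + 1):
            if terminal == "N":
                sub, shift = _restricted(ca, depth, n), depth
            else:
                sub, shift = _restricted(ca, 0, n - depth), 0
            if len(sub) < 4:
                break
            remaining = {(r.segments[0] + shift, r.segments[1] + shift, round(r.time, 6))
                         for r in morph_self_intersections(sub)}
            resolved = [idx for idx, e in enumerate(events)
                        if (*e.segments, round(e.time, 6)) not in remaining
                        and idx not in resolved_so_far]
            if not resolved:
                continue
            if terminal == "N":
                travel = float(sum(2.0 * max(arc_a[depth] - arc_a[p],
                                             arc_b[depth] - arc_b[p])
                                   for p in range(depth)))
            else:
                travel = float(sum(
                    2.0 * max(arc_a[n - 1 - p] - arc_a[n - 1 - depth],
                              arc_b[n - 1 - p] - arc_b[n - 1 - depth])
                    for p in range(depth)))
            cand = UntanglingMove("end_contraction", tuple(resolved),
                                  depth, travel,
                                  contraction_depth=float(min(depth, max_depth)))
            if best is None or len(cand.resolved_events) > len(best.resolved_events):
                best = cand
        if best is not None:
            moves.append(best)
            resolved_so_far.update(best.resolved_events)
    return moves


# ---------------------------------------------------------------------------
# exports

def write_events_tsv(events: Sequence[SelfIntersectionEvent], path) -> None:
    """Event table: t, segment indices, sign and 3D location per row."""
    from pathlib import Path
    lines = ["t\ti\tj\tsign\tx\ty\tz"]
    for e in events:
        x, y, z = e.point
        lines.append(f"{e.time:.6f}\t{e.segments[0]}\t{e.segments[1]}\t"
                     f"{e.sign:+d}\t{x:.3f}\t{y:.3f}\t{z:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_morph_pdb(ca: CurveAlignment, path, n_frames: int = 11) -> None:
    """Multi-model PDB of the linear interpolation for visual inspection
    (all points, pseudo alpha carbons included, as CA pseudo-atoms)."""
    from pathlib import Path
    lines = []
    for frame, t in enumerate(np.linspace(0.0, 1.0, n_frames), start=1):
        lines.append(f"MODEL     {frame:4d}")
        x = _morph_points(ca, t)
        for serial, (p, label) in enumerate(zip(x, ca.labels_a), start=1):
            lines.append(
                f"ATOM  {serial:5d}  CA  GLY A{min(serial, 9999):4d}    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00{label:6.2f}"
                f"           C")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# classification / report

def classify(events: Sequence[SelfIntersectionEvent],
             moves: Sequence[UntanglingMove],
             overlap: float = 0.0) -> TopologyReport:
    """Assemble the topology report: unresolved events are *essential*, the
    untangling length is the (minimized) sum of the chosen moves' added
    lengths, and the threshold flags are set."""
    resolved: set = set()
    for m in moves:
        resolved.update(m.resolved_events)
    essential = tuple(e for idx, e in enumerate(events) if idx not in resolved)
    length = float(sum(m.added_length for m in moves))
    return TopologyReport(
        events=tuple(events), moves=tuple(moves),
        essential_events=essential, untangling_length=length,
        mean_overlap=float(overlap),
        has_essential=bool(essential),
        untangling_ge_140=length >= UNTANGLING_THRESHOLD)


def check_topology(ca: CurveAlignment, *, clash_radius: float = 2.0,
                   max_span: int = MAX_MOVE_SPAN,
                   allow_end_contractions: bool = False,
                   max_contraction: float = MAX_CONTRACTION_DEPTH,
                   n_time_overlap: int = 64) -> TopologyReport:
    """Full topology check of a curve alignment: events, moves, optional
    end-contractions for events no type 1/2 move resolves, essential
    classification, untangling length and MeanOverlap."""
    events = morph_self_intersections(ca)
    moves = find_moves(events, ca, max_span=max_span)
    if allow_end_contractions:
        resolved = set()
        for m in moves:
            resolved.update(m.resolved_events)
        leftover = [e for idx, e in enumerate(events) if idx not in resolved]
        if leftover:
            extra = end_contractions(events, ca, max_depth=max_contraction,
                                     enabled=True)
            for m in extra:
                new = [r for r in m.resolved_events if r not in resolved]
                if new:
                    moves = list(moves) + [dataclasses.replace(
                        m, resolved_events=tuple(new))]
                    resolved.update(new)
    overlap = mean_overlap(ca, clash_radius=clash_radius,
                           n_time=n_time_overlap)
    return classify(events, moves, overlap)
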