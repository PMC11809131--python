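"""Gap-free backbone-curve alignment and superposition (BCAlign).

Two alpha-carbon polygons are aligned by spanning a triangulated surface
between them: every triangle has one edge ("base") on one chain and its
third vertex ("apex") on the other, and a monotone strip of such triangles
connects the alignment windows.  Dynamic programming finds the strip
minimizing

    k * sum(4 * Area^2)  +  (1 - k) * sum(sequence-bound costs)

where the geometric term is the squared cross-product norm of each triangle
(4 Area^2) and the sequence term charges (1/2) * (3.8 A)^2 * (apex -
partner)^2 whenever a base-edge endpoint is an exactly sequence-aligned
residue: the apexes of the two strip triangles flanking such a residue
bound where it can be aligned, and for a consecutively aligned region the
two charges sum to (3.8 A)^2 times the squared residue misalignment.  The
weight k in (0, 1] interpolates from pure structure-based alignment (k = 1)
to sequence-based structural alignment (k -> 0).

The optimal strip is translated into a gap-free *curve alignment*: two
equal-cardinality point lists in which every alpha carbon of either window
appears and fans of triangles insert pseudo alpha carbons (fractional
residue labels) that subdivide the stationary chain's adjacent backbone
segment uniformly.  The aligned curves are put in optimal rigid
superposition in one RMSD call.

The symmetric driver anchors an aligned pair near the middle of the
windows, triangulates the upstream (reversed) and downstream halves out to
the chain terminals, cuts the longer chain's overhang where triangulation
cost per Angstrom of backbone is smallest, stitches, re-superposes and
iterates (at most 20 times) until the alignment agrees with one from a
previous iteration to MAL <= 1 and AAD <= 0.015 residues.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .align_metrics import (ResidueCorrespondence, aad, from_exact_pairs,
                            mal, rmsd_align_seq)
from .io_structures import BackboneCurve
from .seq_align import SequenceAlignment

__all__ = ["Superposition", "Triangulation", "CurveAlignment",
           "BCAlignResult", "superpose", "triangulate",
           "strip_to_curve_alignment", "cut_terminal", "bcalign",
           "write_curve_alignment_tsv",
           "RESIDUE_SCALE", "MAX_ITERATIONS", "MAL_TOL", "AAD_TOL"]

#: Canonical consecutive-alpha-carbon spacing used to convert residue
#: misalignments to Angstrom in the sequence cost.
RESIDUE_SCALE = 3.8
MAX_ITERATIONS = 20
MAL_TOL = 1
AAD_TOL = 0.015


# ---------------------------------------------------------------------------
# superposition

@dataclasses.dataclass(frozen=True)
class Superposition:
    """Proper rigid motion x -> rotation @ x + translation fitted B onto A."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


def superpose(points_a: np.ndarray, points_b: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of B onto A (Kabsch, det = +1)."""
    pa = np.asarray(points_a, dtype=float)
    pb = np.asarray(points_b, dtype=float)
    if pa.shape != pb.shape or pa.ndim != 2 or pa.shape[1] != 3:
        raise ValueError("superpose needs two equal (n, 3) point arrays")
    if len(pa) < 3:
        raise ValueError("superposition needs at least 3 point pairs")
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    a_c, b_c = pa - ca, pb - cb
    if (np.linalg.matrix_rank(a_c, tol=1e-8) < 2
            or np.linalg.matrix_rank(b_c, tol=1e-8) < 2):
        raise ValueError("superposition is degenerate: points are collinear")
    rot, _ = Rotation.align_vectors(a_c, b_c)
    r = rot.as_matrix()
    t = ca - r @ cb
    rmsd = float(np.sqrt(np.mean(np.sum((pb @ r.T + t - pa) ** 2, axis=1))))
    return Superposition(r, t, rmsd)


# ---------------------------------------------------------------------------
# triangulated-surface dynamic programming

@dataclasses.dataclass(frozen=True)
class Triangulation:
    """An optimal monotone triangle strip between two windows.

    ``path`` lists the DP lattice states (i, j) from (0, 0) to the strip's
    terminal state; each step advances exactly one chain by one vertex and
    corresponds to one triangle whose base is the advanced edge and whose
    apex is the stationary vertex on the other chain.  ``cost_table`` holds
    the minimal cost of triangulating every sub-window with the same start,
    which is what terminal cutting inspects.
    """

    path: Tuple[Tuple[int, int], ...]
    total_cost: float
    cost_table: np.ndarray
    k: float

    @property
    def triangles(self) -> List[Tuple[str, int, int]]:
        """(base_chain, base_start, apex) per strip step."""
        out = []
        for (i0, j0), (i1, j1) in zip(self.path, self.path[1:]):
            if i1 == i0 + 1:
                out.append(("A", i0, j0))
            else:
                out.append(("B", j0, i0))
        return out


def triangle_geometric_cost(base_0: np.ndarray, base_1: np.ndarray,
                            apex: np.ndarray) -> float:
    """4 * Area^2 = squared norm of (base_1 - base_0) x (apex - base_0)."""
    cr = np.cross(np.asarray(base_1) - base_0, np.asarray(apex) - base_0)
    return float(cr @ cr)


def triangle_sequence_cost(apex_pos: float, partner: Optional[float]) -> float:
    """Cost of one alignment bound: (1/2)(3.8 A)^2 (apex - partner)^2.

    ``partner`` is the sequence-aligned partner position of a base-edge
    endpoint; ``None`` (not sequence-aligned) contributes nothing.
    """
    if partner is None:
        return 0.0
    return 0.5 * RESIDUE_SCALE ** 2 * (apex_pos - partner) ** 2


def _seq_cost_rows(n_edges: int, n_apex: int,
                   partners: Dict[int, float]) -> np.ndarray:
    """S[e, j]: sequence cost of the triangle with base edge (e, e+1) and
    apex j, summing the bound terms of both base endpoints."""
    s = np.zeros((max(n_edges, 0), n_apex))
    if n_edges <= 0:
        return s
    j = np.arange(n_apex, dtype=float)
    for e in range(n_edges):
        for u in (e, e + 1):
            p = partners.get(u)
            if p is not None:
                s[e] += 0.5 * RESIDUE_SCALE ** 2 * (j - p) ** 2
    return s


def triangulate(points_a: np.ndarray, points_b: np.ndarray,
                partners_a: Dict[int, float], partners_b: Dict[int, float],
                k: float,
                end: Optional[Tuple[int, int]] = None) -> Triangulation:
    """Minimal-cost monotone triangle strip between two point windows.

    ``partners_a[u] = v`` marks window-local residue u of A as sequence
    aligned to position v of B (and symmetrically for ``partners_b``).
    ``end`` selects the strip's terminal state (default: both last
    vertices).  Ties prefer advancing chain A.
    """
    pa = np.asarray(points_a, dtype=float)
    pb = np.asarray(points_b, dtype=float)
    m, n = len(pa), len(pb)
    if m < 1 or n < 1 or (m < 2 and n < 2):
        raise ValueError("empty window: need at least 2 vertices on a chain")
    if not (0.0 < k <= 1.0):
        raise ValueError("k must lie in (0, 1]")

    # geometric cost matrices: GA[e, j] for base edge (e, e+1) on A, apex j
    if m > 1:
        ea = pa[1:] - pa[:-1]                       # (m-1, 3)
        va = pb[None, :, :] - pa[:-1, None, :]      # (m-1, n, 3)
        ga = np.sum(np.cross(ea[:, None, :], va) ** 2, axis=2)
    else:
        ga = np.zeros((0, n))
    if n > 1:
        eb = pb[1:] - pb[:-1]
        vb = pa[None, :, :] - pb[:-1, None, :]
        gb = np.sum(np.cross(eb[:, None, :], vb) ** 2, axis=2)
    else:
        gb = np.zeros((0, m))

    sa = _seq_cost_rows(m - 1, n, partners_a)
    sb = _seq_cost_rows(n - 1, m, partners_b)
    ca = (k * ga + (1.0 - k) * sa).tolist()   # cost of A-advance over edge e, apex j
    cb = (k * gb + (1.0 - k) * sb).tolist()   # cost of B-advance over edge e, apex i

    inf = math.inf
    dp = [[inf] * n for _ in range(m)]
    choice = [[-1] * n for _ in range(m)]     # 0: came from (i-1, j); 1: from (i, j-1)
    dp[0][0] = 0.0
    for i in range(m):
        row = dp[i]
        ch = choice[i]
        above = dp[i - 1] if i > 0 else None
        for j in range(n):
            if i == 0 and j == 0:
                continue
            best, arg = inf, -1
            if above is not None:
                c = above[j] + ca[i - 1][j]
                if c < best:
                    best, arg = c, 0
            if j > 0:
                c = row[j - 1] + cb[j - 1][i]
                if c < best:
                    best, arg = c, 1
            row[j], ch[j] = best, arg

    ei, ej = (m - 1, n - 1) if end is None else end
    path = [(ei, ej)]
    i, j = ei, ej
    while (i, j) != (0, 0):
        if choice[i][j] == 0:
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    path.reverse()
    return Triangulation(tuple(path), float(dp[ei][ej]),
                         np.array(dp), k)


# ---------------------------------------------------------------------------
# strip -> gap-free curve alignment

def _match_and_label(path: Sequence[Tuple[int, int]],
                     points_a: np.ndarray,
                     points_b: np.ndarray,
                     partners_a: Optional[Dict[int, float]] = None,
                     partners_b: Optional[Dict[int, float]] = None,
                     k: float = 1.0) -> Tuple[np.ndarray, np.ndarray]:
    """Fractional label pairs of the gap-free curve alignment of a strip.

    The strip's cross edges (its lattice states) contain strictly-diagonal
    subsequences of exactly matched alpha-carbon pairs; the one minimizing
    the k-weighted sum of squared ruling lengths (3D distance between
    aligned partners, pseudo pairs included) and squared sequence-alignment
    deviations (in residues, scaled by (3.8 A)^2) is selected, so the
    translation respects the register the strip's cost optimized.  The
    first and last state always match, and interior states may not consume
    a terminal vertex.  Every vertex left unmatched between two matched
    pairs is aligned to a pseudo alpha carbon placed by linear
    interpolation between the flanking matched pairs, which subdivides the
    stationary chain's adjacent segment uniformly (a fan of triangles from
    one vertex of A over r edges of B yields r - 1 pseudo points spaced at
    1/r of a residue).
    """
    pa = partners_a or {}
    pb = partners_b or {}
    m = path[-1][0] + 1
    n = path[-1][1] + 1
    length = len(path)
    s2 = RESIDUE_SCALE ** 2

    def pair_cost(ia: float, jb: float, point_a, point_b) -> float:
        c = k * float(np.sum((point_a - point_b) ** 2))
        w = 0.0
        if float(ia).is_integer():
            p = pa.get(int(ia))
            if p is not None:
                w += (jb - p) ** 2
        if float(jb).is_integer():
            p = pb.get(int(jb))
            if p is not None:
                w += (ia - p) ** 2
        return c + (1.0 - k) * 0.5 * s2 * w

    # candidate matched states: endpoints, plus interior states not on a
    # terminal row/column
    ok = [t == 0 or t == length - 1
          or (0 < path[t][0] < m - 1 and 0 < path[t][1] < n - 1)
          for t in range(length)]
    dist2 = [pair_cost(i, j, points_a[i], points_b[j]) for i, j in path]

    def gap_cost(s: int, t: int) -> float:
        """Cost of the pseudo pairs interpolated between matched states."""
        (i1, j1), (i2, j2) = path[s], path[t]
        c = 0.0
        for i in range(i1 + 1, i2):
            x = j1 + (j2 - j1) * (i - i1) / (i2 - i1)
            lo = int(x)
            p = points_b[lo] if lo >= n - 1 else \
                (1 - (x - lo)) * points_b[lo] + (x - lo) * points_b[lo + 1]
            c += pair_cost(i, x, points_a[i], p)
        for j in range(j1 + 1, j2):
            x = i1 + (i2 - i1) * (j - j1) / (j2 - j1)
            lo = int(x)
            p = points_a[lo] if lo >= m - 1 else \
                (1 - (x - lo)) * points_a[lo] + (x - lo) * points_a[lo + 1]
            c += pair_cost(x, j, p, points_b[j])
        return c

    # DP over path states for the strictly increasing subsequence through
    # the endpoints minimizing the total squared ruling length of the
    # induced gap-free alignment (matched + pseudo pairs)
    best_cost = [math.inf] * length
    prev = [-1] * length
    best_cost[0] = dist2[0]
    max_back = 64                   # fans longer than this do not occur
    for t in range(1, length):
        if not ok[t]:
            continue
        it, jt = path[t]
        s = t - 1
        scanned = 0
        while s >= 0 and scanned < max_back:
            if best_cost[s] < math.inf:
                si, sj = path[s]
                if si < it and sj < jt:
                    cost = best_cost[s] + dist2[t] + gap_cost(s, t)
                    if cost < best_cost[t]:
                        best_cost[t], prev[t] = cost, s
                scanned += 1
            s -= 1
    t = length - 1
    matched: List[Tuple[int, int]] = []
    while t >= 0:
        matched.append(path[t])
        t = prev[t]
    matched.reverse()
    la: List[float] = []
    lb: List[float] = []
    for (i1, j1), (i2, j2) in zip(matched, matched[1:]):
        pairs = [(float(i1), float(j1))]
        for i in range(i1 + 1, i2):
            pairs.append((float(i), j1 + (j2 - j1) * (i - i1) / (i2 - i1)))
        for j in range(j1 + 1, j2):
            pairs.append((i1 + (i2 - i1) * (j - j1) / (j2 - j1), float(j)))
        pairs.sort()
        for a, b in pairs:
            la.append(a)
            lb.append(b)
    la.append(float(matched[-1][0]))
    lb.append(float(matched[-1][1]))
    return np.array(la), np.array(lb)


def _interp(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Points at fractional vertex labels, linear along the polygon."""
    lo = np.clip(np.floor(labels).astype(int), 0, len(points) - 1)
    hi = np.clip(lo + 1, 0, len(points) - 1)
    f = (labels - lo)[:, None]
    return (1.0 - f) * points[lo] + f * points[hi]


@dataclasses.dataclass(frozen=True)
class CurveAlignment:
    """Two equal-cardinality aligned point lists (real + pseudo CAs).

    Labels are fractional vertex indices into the *full* chains (the
    ``offset`` of the window start is already added), so whole-number
    labels are real alpha carbons and fractions are pseudo points on the
    segment between their flanking alpha carbons.
    """

    points_a: np.ndarray
    points_b: np.ndarray
    labels_a: np.ndarray
    labels_b: np.ndarray

    def __post_init__(self):
        if len(self.points_a) != len(self.points_b):
            raise ValueError("aligned curves must have equal cardinality")

    def __len__(self) -> int:
        return len(self.points_a)

    @property
    def correspondence(self) -> ResidueCorrespondence:
        fwd = {int(round(a)): float(b)
               for a, b in zip(self.labels_a, self.labels_b)
               if abs(a - round(a)) < 1e-9}
        bwd = {int(round(b)): float(a)
               for a, b in zip(self.labels_a, self.labels_b)
               if abs(b - round(b)) < 1e-9}
        return ResidueCorrespondence(fwd, bwd)


def strip_to_curve_alignment(tri: Triangulation, points_a: np.ndarray,
                             points_b: np.ndarray,
                             offset: Tuple[int, int] = (0, 0),
                             partners_a: Optional[Dict[int, float]] = None,
                             partners_b: Optional[Dict[int, float]] = None) -> CurveAlignment:
    """Translate a triangle strip into a gap-free curve alignment.

    Whenever consecutive triangles fan from one stationary apex, the
    stationary chain receives pseudo alpha carbons subdividing its adjacent
    segment uniformly; every real alpha carbon of either window appears
    exactly once and both point lists have equal cardinality."""
    la, lb = _match_and_label(tri.path, np.asarray(points_a, float),
                              np.asarray(points_b, float),
                              partners_a, partners_b, tri.k)
    return CurveAlignment(_interp(np.asarray(points_a, float), la),
                          _interp(np.asarray(points_b, float), lb),
                          la + offset[0], lb + offset[1])


def write_curve_alignment_tsv(ca: CurveAlignment, path) -> None:
    """Tabular export: label_A, x y z of A, label_B, x y z of B per row."""
    lines = ["label_A\tx_A\ty_A\tz_A\tlabel_B\tx_B\ty_B\tz_B"]
    for la, pa, lb, pb in zip(ca.labels_a, ca.points_a,
                              ca.labels_b, ca.points_b):
        lines.append(f"{la:.4f}\t{pa[0]:.3f}\t{pa[1]:.3f}\t{pa[2]:.3f}\t"
                     f"{lb:.4f}\t{pb[0]:.3f}\t{pb[1]:.3f}\t{pb[2]:.3f}")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# terminal cutting

def _arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def cut_terminal(tri: Triangulation, points_a: np.ndarray,
                 points_b: np.ndarray) -> Tuple[int, int]:
    """Pick the strip's terminal state by cutting the longer chain where
    triangulation cost per Angstrom of traversed backbone is smallest.

    Chains of equal window length are not cut.  Ties (e.g. a surplus tail
    that fans onto the partner's terminal point with zero area) prefer the
    shortest kept extension."""
    dp = tri.cost_table
    m, n = dp.shape
    if m == n:
        return (m - 1, n - 1)
    if m > n:
        arc = _arclength(np.asarray(points_a, float))
        costs = dp[:, n - 1]
        lo = max(1, n - 1)                    # keep at least the shorter span
        ratios = costs[lo:] / np.maximum(arc[lo:], 1e-12)
        best = ratios.min()
        i = lo + int(np.nonzero(ratios <= best + 1e-9 * (1 + best))[0][0])
        return (i, n - 1)
    arc = _arclength(np.asarray(points_b, float))
    costs = dp[m - 1, :]
    lo = max(1, m - 1)
    ratios = costs[lo:] / np.maximum(arc[lo:], 1e-12)
    best = ratios.min()
    j = lo + int(np.nonzero(ratios <= best + 1e-9 * (1 + best))[0][0])
    return (m - 1, j)


# ---------------------------------------------------------------------------
# the symmetric driver

@dataclasses.dataclass(frozen=True)
class BCAlignResult:
    k: float
    curve_alignment: CurveAlignment
    superposition: Superposition
    rmsd: float
    rmsd_align_seq: float
    iterations: int
    converged: bool
    terminal_cuts: Dict[str, int]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "rmsd": self.rmsd,
            "rmsd_align_seq": self.rmsd_align_seq,
            "iterations": self.iterations,
            "converged": self.converged,
            "terminal_cuts": dict(self.terminal_cuts),
            "n_aligned_points": len(self.curve_alignment),
        }


def _pick_anchor(corr: ResidueCorrespondence,
                 window_a: Tuple[int, int],
                 window_b: Tuple[int, int]) -> Tuple[int, int]:
    """Aligned integer pair nearest the window midpoints, preferring one
    whose neighborhood is nearly consecutively aligned (>= 5 of the 6
    flanking residues aligned within one residue of consecutively)."""
    mid_a = 0.5 * (window_a[0] + window_a[1])
    mid_b = 0.5 * (window_b[0] + window_b[1])
    pairs = [(i, int(round(x))) for i, x in sorted(corr.forward.items())
             if abs(x - round(x)) < 1e-9
             and window_a[0] <= i <= window_a[1]
             and window_b[0] <= round(x) <= window_b[1]]
    if not pairs:
        raise ValueError("no aligned residue pair available as anchor")

    def centrality(p):
        return abs(p[0] - mid_a) + abs(p[1] - mid_b)

    def nearly_consecutive(p):
        i, j = p
        good = 0
        for d in (-3, -2, -1, 1, 2, 3):
            x = corr.forward.get(i + d)
            if x is not None and abs(x - (j + d)) <= 1.0:
                good += 1
        return good >= 5

    qualified = [p for p in pairs if nearly_consecutive(p)]
    return min(qualified or pairs, key=centrality)


def _local_partners(exact: Sequence[Tuple[int, int]], i0: int, j0: int,
                    downstream: bool) -> Tuple[Dict[int, float], Dict[int, float]]:
    pa: Dict[int, float] = {}
    pb: Dict[int, float] = {}
    for i, j in exact:
        if downstream and i >= i0 and j >= j0:
            pa[i - i0] = float(j - j0)
            pb[j - j0] = float(i - i0)
        elif not downstream and i <= i0 and j <= j0:
            pa[i0 - i] = float(j0 - j)
            pb[j0 - j] = float(i0 - i)
    return pa, pb


def _half_strip(pts_a: np.ndarray, pts_b: np.ndarray,
                partners: Tuple[Dict[int, float], Dict[int, float]],
                k: float, allow_cut: bool) -> Tuple[Triangulation, Tuple[int, int]]:
    pa, pb = partners
    if len(pts_a) == 1 and len(pts_b) == 1:   # anchor sits on both terminals
        return (Triangulation(((0, 0),), 0.0, np.zeros((1, 1)), k), (0, 0))
    tri = triangulate(pts_a, pts_b, pa, pb, k)
    if allow_cut:
        end = cut_terminal(tri, pts_a, pts_b)
    else:
        end = (len(pts_a) - 1, len(pts_b) - 1)
    if end != (len(pts_a) - 1, len(pts_b) - 1):
        tri = triangulate(pts_a, pts_b, pa, pb, k, end=end)
    return tri, end


def bcalign(curve_a: BackboneCurve, curve_b: BackboneCurve,
            seq_alignment: SequenceAlignment, k: float = 1.0, *,
            fixed_windows: bool = False,
            max_iterations: int = MAX_ITERATIONS) -> BCAlignResult:
    """Gap-free structural alignment and superposition of two backbone
    curves, balancing structural deviation against deviation from the
    input sequence alignment with weight ``k`` in (0, 1].
    """
    if not (0.0 < k <= 1.0):
        raise ValueError("k must lie in (0, 1]")
    exact = seq_alignment.exact_pairs
    if len(exact) < 3:
        raise ValueError("insufficient sequence anchor: need >= 3 exact "
                         "sequence-aligned pairs")
    a_pts = curve_a.points
    b_orig = curve_b.points
    m, n = len(a_pts), len(b_orig)

    idx_a = np.array([i for i, _ in exact])
    idx_b = np.array([j for _, j in exact])
    sup = superpose(a_pts[idx_a], b_orig[idx_b])
    b_cur = sup.apply(b_orig)

    window_a = (exact[0][0], exact[-1][0])
    window_b = (exact[0][1], exact[-1][1])
    corr = from_exact_pairs(exact)
    history = [corr]

    ca: Optional[CurveAlignment] = None
    converged = False
    iterations = 0
    cuts = {"n_a": 0, "c_a": 0, "n_b": 0, "c_b": 0}

    for iterations in range(1, max_iterations + 1):
        i0, j0 = _pick_anchor(corr, window_a, window_b)

        # downstream: anchor -> C-terminals
        if fixed_windows:
            da, db = a_pts[i0:window_a[1] + 1], b_cur[j0:window_b[1] + 1]
        else:
            da, db = a_pts[i0:], b_cur[j0:]
        tri_d, end_d = _half_strip(da, db, _local_partners(exact, i0, j0, True),
                                   k, allow_cut=not fixed_windows)
        # upstream: anchor -> N-terminals, traversed in reverse
        if fixed_windows:
            ua = a_pts[window_a[0]:i0 + 1][::-1]
            ub = b_cur[window_b[0]:j0 + 1][::-1]
        else:
            ua, ub = a_pts[:i0 + 1][::-1], b_cur[:j0 + 1][::-1]
        tri_u, end_u = _half_strip(ua, ub, _local_partners(exact, i0, j0, False),
                                   k, allow_cut=not fixed_windows)

        # stitch the two half strips into one absolute path
        up = [(i0 - i, j0 - j) for i, j in tri_u.path]
        up.reverse()
        down = [(i0 + i, j0 + j) for i, j in tri_d.path]
        path = tuple(up + down[1:])
        start_a, start_b = path[0]
        end_a, end_b = path[-1]

        local_path = tuple((i - start_a, j - start_b) for i, j in path)
        tri_full = Triangulation(local_path, tri_u.total_cost + tri_d.total_cost,
                                 np.zeros((0, 0)), k)
        # match registers in the current superposed frame, then fit the
        # absolute superposition from the original B coordinates
        win_pa = {i - start_a: float(j - start_b) for i, j in exact
                  if start_a <= i <= end_a and start_b <= j <= end_b}
        win_pb = {j - start_b: float(i - start_a) for i, j in exact
                  if start_a <= i <= end_a and start_b <= j <= end_b}
        ca = strip_to_curve_alignment(tri_full,
                                      a_pts[start_a:end_a + 1],
                                      b_cur[start_b:end_b + 1],
                                      offset=(start_a, start_b),
                                      partners_a=win_pa, partners_b=win_pb)
        b_points = _interp(b_orig[start_b:end_b + 1],
                           ca.labels_b - start_b)
        sup = superpose(ca.points_a, b_points)
        b_cur = sup.apply(b_orig)
        ca = CurveAlignment(ca.points_a, sup.apply(b_points),
                            ca.labels_a, ca.labels_b)

        window_a, window_b = (start_a, end_a), (start_b, end_b)
        cuts = {"n_a": start_a, "c_a": (m - 1) - end_a,
                "n_b": start_b, "c_b": (n - 1) - end_b}
        corr = ca.correspondence
        for prev in history:
            try:
                if (mal(corr, prev) <= MAL_TOL
                        and aad(corr, prev) <= AAD_TOL):
                    converged = True
                    break
            except ValueError:
                continue
        history.append(corr)
        if converged:
            break

    assert ca is not None
    return BCAlignResult(
        k=k, curve_alignment=ca, superposition=sup, rmsd=sup.rmsd,
        rmsd_align_seq=rmsd_align_seq(corr, seq_alignment),
        iterations=iterations, converged=converged, terminal_cuts=cuts)
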