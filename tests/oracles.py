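"""Independent reference computations used to check the package's
implementations on small inputs: exhaustive strip enumeration, a dense-time
minimum-segment-distance scan of the morph, a quadratic-space global
alignment scorer, and random-rotation superposition bounds."""

import itertools

import numpy as np

RESIDUE_SCALE = 3.8


def strip_cost_brute_force(points_a, points_b, partners_a, partners_b, k):
    """Minimum k-weighted strip cost by enumerating every monotone strip."""
    A, B = np.asarray(points_a), np.asarray(points_b)
    m, n = len(A), len(B)
    s2 = RESIDUE_SCALE ** 2
    best = np.inf
    total = (m - 1) + (n - 1)
    for apos in itertools.combinations(range(total), m - 1):
        aset = set(apos)
        i = j = 0
        cost = 0.0
        for step in range(total):
            if step in aset:
                v = np.cross(A[i + 1] - A[i], B[j] - A[i])
                g = float(v @ v)
                s = 0.0
                for u in (i, i + 1):
                    p = partners_a.get(u)
                    if p is not None:
                        s += 0.5 * s2 * (j - p) ** 2
                cost += k * g + (1 - k) * s
                i += 1
            else:
                v = np.cross(B[j + 1] - B[j], A[i] - B[j])
                g = float(v @ v)
                s = 0.0
                for u in (j, j + 1):
                    p = partners_b.get(u)
                    if p is not None:
                        s += 0.5 * s2 * (i - p) ** 2
                cost += k * g + (1 - k) * s
                j += 1
            if cost >= best:
                break
        best = min(best, cost)
    return best


def _seg_seg_dist_batch(a, b, c, d):
    """Min distance between segments a-b and c-d, batched over axis 0."""
    u, v, w0 = b - a, d - c, a - c
    A = np.sum(u * u, -1)
    B = np.sum(u * v, -1)
    C = np.sum(v * v, -1)
    D = np.sum(u * w0, -1)
    E = np.sum(v * w0, -1)
    den = np.maximum(A * C - B * B, 1e-12)
    s = np.clip((B * E - C * D) / den, 0.0, 1.0)
    t = np.clip((B * s + E) / np.maximum(C, 1e-12), 0.0, 1.0)
    s = np.clip((B * t - D) / np.maximum(A, 1e-12), 0.0, 1.0)
    p = a + s[..., None] * u
    q = c + t[..., None] * v
    return np.linalg.norm(p - q, axis=-1)


def _refined_min_dist(pa, pb, i, j, t_lo, t_hi, rounds=3, grid=2000):
    """True minimum over time of the distance between moving segments i and
    j, by repeated local grid refinement inside [t_lo, t_hi]."""
    best_t, best_d = t_lo, np.inf
    for _ in range(rounds):
        ts = np.linspace(t_lo, t_hi, grid)
        X = (1 - ts[:, None, None]) * pa[None] + ts[:, None, None] * pb[None]
        d = _seg_seg_dist_batch(X[:, i], X[:, i + 1], X[:, j], X[:, j + 1])
        q = int(np.argmin(d))
        best_t, best_d = float(ts[q]), float(d[q])
        span = (t_hi - t_lo) / grid * 4
        t_lo = max(0.0, best_t - span)
        t_hi = min(1.0, best_t + span)
    return best_t, best_d


def dense_time_events(points_a, points_b, n_steps=10_000, candidate=5e-2,
                      touch=1e-6):
    """Segment pairs that touch (distance -> 0) during the linear morph:
    a dense time grid locates minimum-distance dips, each dip is refined
    locally, and only dips whose true minimum vanishes count as events."""
    pa, pb = np.asarray(points_a), np.asarray(points_b)
    ts = np.linspace(0.0, 1.0, n_steps)
    X = (1 - ts[:, None, None]) * pa[None] + ts[:, None, None] * pb[None]
    n = X.shape[1]
    found = []
    for i in range(n - 1):
        for j in range(i + 2, n - 1):
            d = _seg_seg_dist_batch(X[:, i], X[:, i + 1], X[:, j], X[:, j + 1])
            if d.min() >= candidate:
                continue
            idx = np.nonzero(d < candidate)[0]
            groups = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
            for g in groups:
                # a group can hold several crossings (touch and re-touch):
                # refine every interior local minimum separately
                dg = d[g]
                if len(g) >= 3:
                    interior = 1 + np.nonzero((dg[1:-1] <= dg[:-2])
                                              & (dg[1:-1] <= dg[2:]))[0]
                    minima = list(interior)
                else:
                    minima = [int(np.argmin(dg))]
                if not minima:
                    minima = [int(np.argmin(dg))]
                for q in minima:
                    lo = ts[max(g[max(q - 2, 0)], 0)]
                    hi = ts[min(g[min(q + 2, len(g) - 1)], n_steps - 1)]
                    t_best, d_best = _refined_min_dist(pa, pb, i, j, lo, hi)
                    if d_best < touch:
                        found.append((i, j, t_best))
    return found


def nw_score_quadratic(seq_a, seq_b, matrix, gap_open, gap_extend):
    """Optimal global affine-gap alignment score by an independent
    three-matrix dynamic program (first gapped position costs gap_open,
    each further one gap_extend)."""
    m, n = len(seq_a), len(seq_b)
    neg = -np.inf
    M = np.full((m + 1, n + 1), neg)
    X = np.full((m + 1, n + 1), neg)   # gap in B (A consumed)
    Y = np.full((m + 1, n + 1), neg)   # gap in A
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, n + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = matrix[seq_a[i - 1], seq_b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
    return float(max(M[m, n], X[m, n], Y[m, n]))


def random_rotation_rmsd_bound(points_a, points_b, n_rot, rng):
    """Best RMSD over random proper rotations with optimal translation."""
    from scipy.spatial.transform import Rotation
    pa = points_a - points_a.mean(axis=0)
    pb = points_b - points_b.mean(axis=0)
    rots = Rotation.random(n_rot, rng=rng).as_matrix()
    moved = np.einsum("rij,nj->rni", rots, pb)
    diff = moved - pa[None]
    rmsd = np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1))
    return float(rmsd.min())
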