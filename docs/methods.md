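# Methods

This note records the models, parameter choices and numerical decisions
behind `bcalign`, and what the synthetic fixtures do and do not show.

## Backbone curves and connectivity

A structure is reduced to the ordered polygon of its alpha carbons
(author residue numbering; insertion codes ignored; alternate locations
resolved to highest occupancy, ties to first listed; nonstandard residues
kept with code `X`).  A chain is *connected* when every consecutive
alpha-carbon pair either steps forward by at most three residue numbers
(repeats and decreases qualify) or lies within 6 Å.  The rule tolerates up
to two missing residues or a short physical gap while rejecting broken
chains whose morphs would be meaningless.

## Sequence alignment

Global Needleman–Wunsch with affine gaps, defaults gap open 8 and extend
1 (the first gapped position costs 8, each further one 1); these penalties
favor compact alignments at domain terminals.  The substitution matrix
defaults to BLOSUM62 and is recorded in the output provenance, since
results depend on it.  Implementation: `Bio.Align.PairwiseAligner`;
co-optimal alignments are resolved deterministically by taking the first
alignment in its enumeration order.  Sequence identity is reported as
identical residues over both-aligned columns — a convention, recorded
because several exist.  Externally produced alignments (pairwise FASTA or
a two-column residue-pair table) can be injected in place of the internal
aligner, so the topology check can post-process any structural alignment
method.

## Metrics on the space of alignments

For alignments a₁: I₁↔J₁ and a₂: I₂↔J₂ with I\* = I₁∩I₂, J\* = J₁∩J₂:

* RMSDalign(a₁,a₂) = ( 1/(2·#I\*) Σ_{i∈I\*} (a₁(i)−a₂(i))²
  + 1/(2·#J\*) Σ_{j∈J\*} (a₁⁻¹(j)−a₂⁻¹(j))² )^½ — residue units;
* AAD — the same construction with absolute values (one-norm);
* MAL = #(I₁ Δ I₂) + #(J₁ Δ J₂) — residues aligned by exactly one side;
* RMSDalignseq(a) = RMSDalign(a, a_s) with a_s the exact matching pairs of
  the input sequence alignment.

Images may be fractional (pseudo alpha carbons), so a half-residue change
contributes 0.5; MAL counts whole residues only.  Both direction terms are
always required: if either common set is empty the metric is an error, not
a one-sided value.  Over 100 aligned residues, one whole-residue move plus
one half-residue move gives AAD = 0.015 — the convergence tolerance below.

## The alignment objective

Every monotone triangle strip between the two windows is scored as
k·Σ 4·Area² + (1−k)·Σ seq, with the geometric term carried per triangle as
|(base₁−base₀) × (apex−base₀)|² = 4·Area², which makes the dynamic program
additive per transition.  The sequence term attaches to the two strip
triangles whose base edge flanks an exactly sequence-aligned residue u on
its own chain: each contributes ½·(3.8 Å)²·(apex − partner(u))².  For a
1:1 consecutively aligned region the two charges sum to
(3.8 Å)²·(register shift)², i.e. the squared area of a rectangle of height
1 Å and length equal to the geometric misalignment; alignment gaps cost
more.  The 3.8 Å/residue scale enters squared exactly once per bound term.
These bound semantics are this package's normative definition of how the
apexes flanking a sequence-anchored residue constrain its alignment.

The DP runs over lattice states (i, j) with transitions advancing one
chain by one vertex; ties prefer advancing chain A.  On windows of ≤ 7
vertices the DP cost is verified against exhaustive enumeration of all
monotone strips.

## Strip → gap-free curve alignment

A strip's lattice states are its cross edges (candidate matched
alpha-carbon pairs).  The translation selects a strictly-diagonal
subsequence of states — the matched pairs — and aligns every unmatched
vertex to a pseudo alpha carbon interpolated linearly between the flanking
matched pairs, which subdivides the stationary chain's adjacent backbone
segment uniformly (a fan of one A-vertex over r B-edges yields r−1 pseudo
points spaced at 1/r residue).  Because a staircase strip is consistent
with several registers, the matched set is chosen by a second small DP
minimizing the same k-weighted trade-off: squared 3D ruling lengths (in
the current superposed frame) plus squared sequence-alignment deviations
on the (3.8 Å)² scale, pseudo pairs included.  This reproduces the
identity alignment for identical curves and respects the register the
strip's cost optimized.  The first and last states always match; interior
states may not consume a terminal vertex.

## Superposition

One least-squares rigid superposition (Kabsch via
`scipy.spatial.transform.Rotation.align_vectors`, proper rotation,
det = +1) of the equal-cardinality aligned point lists, real and pseudo
alpha carbons alike.  Fewer than 3 pairs or collinear point sets are
errors.  The reported RMSD is over all aligned points.

## Terminal cutting and the symmetric driver

The DP table holds the minimal cost of triangulating every sub-window with
the same start, so the strip can be extended to both C-terminals and the
longer chain cut where triangulation cost per Å of traversed backbone is
smallest (the N-terminal side is treated by reversing traversal).  Equal
window lengths are never cut.  Exact ties — e.g. a surplus tail that fans
onto the partner's terminal vertex with zero area — are resolved toward
the shortest kept extension, since chain beyond the partner's terminus can
only pair degenerately.

The driver: superpose on the exact sequence-aligned pairs; windows span
first-to-last exact pair; then repeat { pick as anchor the aligned integer
pair nearest the window midpoints whose neighborhood is nearly
consecutively aligned (≥ 5 of the 6 flanking residues aligned within one
residue of consecutively; fallback: nearest pair); triangulate the full
upstream (reversed) and downstream structures; cut terminals; stitch;
translate; superpose; update windows }.  Iteration stops when the current
alignment differs from **any** previous iteration's by MAL ≤ 1 and
AAD ≤ 0.015 residues (comparing against all previous iterates detects
period-2 cycling), or after 20 iterations with `converged = False`.
A `fixed_windows` option freezes the windows and skips cutting.
For k surveys the CLI uses 15 k values on [10⁻⁴, 1]: 13 logarithmically
spaced plus the reference values 0.01 and 0.3 (spacing within the interval
is a package choice).

## Morph self-intersections

With the gap-free alignment, vertex p moves as X_p(t) = (1−t)A_p + tB_p.
For every segment pair (i, j), |i−j| ≥ 2, the signed volume of the four
moving endpoints is a cubic in t (coefficients assembled exactly from
cross/dot products of the endpoints and velocities).  Roots in (0, 1) are
taken from the cubic solver; a root is an event when (a) the volume
derivative is non-negligible there (tolerance 10⁻⁹ on the normalized
volume — near-tangential double roots are discarded as non-transversal,
since sampling noise otherwise creates canceling event pairs) and (b) the
two coplanar segments truly intersect within both parameter ranges
(least-squares intersection, parameter tolerance 10⁻⁹).  The crossing sign
is the direction of the writhe jump; for a transversal crossing this is
exactly the negated sign of the volume's time derivative at the root.
Adjacent segment pairs share endpoints and are excluded.  Curve smoothing
is *not* applied before detection (it is exposed nowhere; detection works
on the raw alpha-carbon polygon).

The polygonal Gauss-sum writhe (Klenin–Langowski closed form per segment
pair) serves as a cross-check: across each event the writhe jumps by
2·sign.  Note the open curve's writhe also drifts continuously during the
morph, so the end-to-end writhe difference equals the sum of jumps *plus*
that drift; tests therefore verify the per-event jump (Richardson
extrapolation at ε = 10⁻⁸ removes the drift to below 10⁻⁶), not a bare
end-to-end difference.

## Untangling moves and essential events

*Type 1*: one event whose self-intersecting arc (the chain between the two
crossing segments, ≤ 15 segments) spans a surface — a triangle fan from
the crossing point over the arc at the crossing time — disjoint from the
remainder of the interpolating curve at sampled times within ±0.05 of the
event.  *Type 2*: an opposite-sign event pair whose sliding arc (the
shorter side, ≤ 15 segments; the slid-over stretch must also be local)
satisfies the same surface condition around both events.  Admissible moves
are selected to resolve the maximal number of events, ties broken by
minimal total added motion length (exact subset search up to 12 candidate
moves, greedy beyond).  The added length of a move is an explicit
upper-bound construction: twice the summed distances from the moved arc's
vertices to the crossing point (collapse toward the crossing, rotate,
reopen); lengths of chosen moves are summed into the untangling length,
with ≥ 140 Å flagged as a significant structural variation.  The
15-segment cap reflects that rearranging more can alter a fold outright.

*End-contractions* (off by default — physically meaningful only when the
domain terminal is a chain terminal): retract up to 7.5 residues from a
terminal, recount events on the remaining sub-curve, and count what
disappeared as resolved, with added length twice the arc length traveled
by the retracted vertices.  At most one contraction per terminal, at the
depth resolving the most events.

Events resolved by no admissible move are **essential**.  MeanOverlap is
the average over morph time (trapezoid rule, 64 uniform steps; refinement
to 256 changes fixtures by < 1 %) and over morph vertices of the summed
sphere-overlap depth max(0, 2r − d) against all non-adjacent vertices,
with clash radius r = 2.0 Å per alpha carbon by default (the radius is
configurable and recorded in output; pseudo alpha carbons are included as
vertices).

## Synthetic fixtures

All tests run without downloads on generated alpha-carbon polygons with
exact 3.8 Å chords (helix: rise 1.5 Å, radius 2.3 Å):

* **helix** — a rigidly moved ideal helix: zero events, RMSD 0.
* **loop_chirality_pair** — a 12-gon loop (radius ≈ 7.34 Å so chords are
  3.8 Å) whose exit strand passes 2 Å above the entry segment in one
  conformation and 2 Å below in the other: exactly one transversal event
  at t = 0.5, removable by a type 1 move; the `blocked` variant threads a
  static arc through the loop's axis, piercing the spanned surface.
* **threading_pair** — an open ring plus an outboard spacer and a terminal
  strand that ends above the ring's center in one conformation and below
  in the other: the morph drags the terminal through the ring wall at a
  chain distance beyond the 15-segment cap (essential), while a C-terminal
  contraction resolves it.
* **loop_displacement_pair** — identical backbones (straight stretch with
  a ~5-residue loop excursion) whose sequences contain one deletion and
  one insertion bracketing the loop, so the optimal sequence alignment
  shifts the loop window by one residue while the structural optimum is
  the identity.  This is the controlled realization of a displaced loop
  for the k trade-off: a purely spatial displacement would leave sequence
  and structure optima identical and show no trade-off.
* **random_walk** — fixed-step (3.8 Å) self-avoiding walks with minimum
  non-adjacent separation 4 Å, which keeps morph crossings transversal.

What passing on fixtures does **not** show: real domains have terminal
overhangs, missing residues, nonstandard numbering and thousands of
residues; the fixtures exercise the mechanisms (register trade-off, cut
rule, move admissibility) at small scale, not PDB-scale robustness or the
population statistics of large domain surveys.

## Problem sizes and numerics

Tests use windows of ≤ 8 vertices for exhaustive enumeration (all
C(m+n−2, m−1) strips), 500 random 10–20 vertex morphs against a 10⁴-step
dense-time minimum-distance oracle with local refinement, 10⁴ random
rotations per superposition bound, and 40-residue fixtures for the driver
— sizes at which the oracles are exact and the whole suite runs in a few
minutes.  Root finding uses `numpy.roots` on normalized cubics; degenerate
leading coefficients drop the degree.  All randomness is seeded; fixture
generation is bit-reproducible for a given spec and seed.

## Known limitations

* The alignment-bound semantics of the sequence cost and the
  strip-translation register choice are this package's own normative
  definitions of under-specified constructions; other choices would change
  k-intermediate alignments slightly.
* The added-length of moves is an upper bound and can look large for
  clusters of events needing similar untangling motions; overlapping moves
  are summed.
* MeanOverlap's absolute scale depends on the clash radius and on counting
  pseudo vertices; values are comparable within a configuration only.
* The iterative driver converges to a fixed point of the
  triangulate/superpose map seeded by the sequence alignment; for
  pathologically symmetric inputs (e.g. exactly identical curves with a
  globally shifted sequence register) distinct self-consistent optima
  exist and the seeded one is reported.
* Single chains only; no multimer handling, no flexible (hinge-aware)
  superposition, no knot/lasso classification.
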