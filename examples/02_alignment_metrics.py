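"""Metrics on the space of alignments.

Builds two correspondences over 100 aligned residues differing by one
whole-residue move and one half-residue (pseudo alpha carbon) move, and
prints RMSDalign, AAD and MAL.  AAD = 0.015 for this construction is the
convergence tolerance of the iterative aligner: iteration stops when the
alignment changes by at most one residue (MAL <= 1) and AAD <= 0.015.
"""

from bcalign import aad, from_exact_pairs, mal, rmsd_align
from bcalign.align_metrics import ResidueCorrespondence

a1 = from_exact_pairs((i, i) for i in range(100))
fwd = {i: float(i) for i in range(100)}
bwd = {i: float(i) for i in range(100)}
fwd[30], bwd[30] = 31.0, 31.0     # moved to the neighboring residue
fwd[70], bwd[70] = 70.5, 70.5     # moved to a pseudo alpha carbon
a2 = ResidueCorrespondence(fwd, bwd)

print(f"RMSDalign = {rmsd_align(a1, a2):.6f} residues")
print(f"AAD       = {aad(a1, a2):.6f} residues")
print(f"MAL       = {mal(a1, a2)} residues")
print("AAD is the mean alignment displacement; 0.015 over 100 residues is "
      "one whole-residue plus one half-residue change.")
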