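"""Backbone curve intake from PDB/mmCIF files.

A protein chain is reduced to its ordered alpha-carbon polygon ("backbone
curve").  All downstream alignment and topology operations work on this
polygon; side chains and non-CA atoms are deliberately ignored.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence, Tuple

import gemmi
import numpy as np

__all__ = ["BackboneCurve", "read_backbone", "is_connected", "write_ca_pdb"]

#: Connectivity rule: consecutive alpha carbons belong to a connected chain if
#: the residue-number step is at most this many residues ...
MAX_RESIDUE_STEP = 3
#: ... or their Euclidean distance is at most this many Angstrom.
MAX_CA_GAP = 6.0

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclasses.dataclass(frozen=True)
class BackboneCurve:
    """Ordered alpha-carbon polygon of one chain (or residue window).

    Parameters
    ----------
    points
        (n, 3) float array of CA coordinates in Angstrom, chain order.
    residue_numbers
        Author residue numbers, one per point.  Repeats and decreases are
        permitted (they occur in real PDB entries).
    residue_codes
        One-letter amino-acid codes; ``X`` for nonstandard residues.
    chain_id, source_id
        Provenance labels, e.g. ``"A"`` and ``"4qlfA00"``.
    """

    points: np.ndarray
    residue_numbers: Tuple[int, ...]
    residue_codes: str
    chain_id: str = ""
    source_id: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        n = len(pts)
        if n < 2:
            raise ValueError("curve too short: need at least 2 alpha carbons")
        if pts.shape != (n, 3):
            raise ValueError("points must be an (n, 3) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite coordinates in backbone curve")
        if len(self.residue_numbers) != n or len(self.residue_codes) != n:
            raise ValueError("points, residue_numbers and residue_codes must "
                             "have equal length")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise ValueError("consecutive alpha carbons coincide exactly")
        object.__setattr__(self, "residue_numbers",
                           tuple(int(r) for r in self.residue_numbers))

    def __len__(self) -> int:
        return len(self.points)

    @property
    def sequence(self) -> str:
        return self.residue_codes

    def window(self, first: int, last: int) -> "BackboneCurve":
        """Restrict to author residue numbers ``first..last`` inclusive."""
        keep = [k for k, r in enumerate(self.residue_numbers)
                if first <= r <= last]
        if len(keep) < 2:
            raise ValueError("curve too short: fewer than 2 alpha carbons in "
                             f"window {first}..{last}")
        return BackboneCurve(
            self.points[keep],
            tuple(self.residue_numbers[k] for k in keep),
            "".join(self.residue_codes[k] for k in keep),
            self.chain_id, self.source_id)


def read_backbone(structure_file, chain_id: str,
                  residue_window: Optional[Tuple[int, int]] = None,
                  source_id: str = "") -> BackboneCurve:
    """Read one chain's alpha-carbon curve from a PDB or mmCIF file.

    Residues lacking a CA atom are skipped.  Alternate locations are resolved
    to the highest-occupancy CA (ties: first listed).  Insertion codes are
    ignored for residue identity; the author residue number is kept.
    """
    path = Path(structure_file)
    try:
        structure = gemmi.read_structure(str(path))
    except Exception as exc:  # pragma: no cover - gemmi error text varies
        raise ValueError(f"could not read structure file {path}: {exc}") from exc
    if len(structure) == 0:
        raise ValueError(f"could not read structure file {path}: no models")
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise KeyError(f"chain not found: {chain_id!r} in {path.name}")

    points, numbers, codes = [], [], []
    for residue in chain:
        best = None
        for atom in residue:
            if atom.name != "CA" or atom.element == gemmi.Element("Ca"):
                continue
            if best is None or atom.occ > best.occ:
                best = atom
        if best is None:
            continue
        points.append([best.pos.x, best.pos.y, best.pos.z])
        numbers.append(residue.seqid.num)
        codes.append(_THREE_TO_ONE.get(residue.name.upper(), "X"))
    if len(points) < 2:
        raise ValueError(f"curve too short: chain {chain_id!r} of {path.name} "
                         f"has {len(points)} alpha carbons")
    curve = BackboneCurve(np.array(points, dtype=float), tuple(numbers),
                          "".join(codes), chain_id,
                          source_id or path.stem)
    if residue_window is not None:
        curve = curve.window(*residue_window)
    return curve


def is_connected(curve: BackboneCurve) -> bool:
    """Chain-connectivity rule used to accept a domain for analysis.

    Consecutive alpha carbons must either step forward by at most three
    residue numbers (repeats and decreases count as a step <= 3) or lie
    within 6 Angstrom of each other.
    """
    nums = np.asarray(curve.residue_numbers)
    steps = np.diff(nums)
    dists = np.linalg.norm(np.diff(curve.points, axis=0), axis=1)
    return bool(np.all((steps <= MAX_RESIDUE_STEP) | (dists <= MAX_CA_GAP)))


def write_ca_pdb(curve: BackboneCurve, path, *,
                 extra_curves: Sequence[BackboneCurve] = ()) -> None:
    """Write a minimal CA-only PDB file (fixture writer; round-trips exactly
    at PDB's fixed %8.3f coordinate precision)."""
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items()}
    lines = []
    serial = 1
    for cv in (curve, *extra_curves):
        cid = (cv.chain_id or "A")[0]
        for (x, y, z), num, code in zip(cv.points, cv.residue_numbers,
                                        cv.residue_codes):
            res = one_to_three.get(code, "UNK")
            lines.append(
                f"ATOM  {serial:5d}  CA  {res:>3s} {cid}{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
            serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
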