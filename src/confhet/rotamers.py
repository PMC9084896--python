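"""Chi dihedrals, rotamer-well assignment, and apo/holo rotamer comparison.

Side-chain chi angles are binned into the three staggered wells
p (gauche+, [0, 120)), t (trans, [120, 240)) and m (gauche-, [240, 360));
a residue's rotamer label concatenates one letter per chi angle.  Terminal
chi angles of two-fold symmetric groups (Asp/Glu carboxylates, Phe/Tyr
rings) are reported modulo 180 degrees and binned p = [0, 120),
t = [120, 180).

For a matched apo/holo residue the two sets of per-conformer labels are
compared set-wise and classified into five mutually exclusive categories:
``no_change`` (equal sets), ``distinct`` (no shared label),
``remodeled_holo_loss`` (holo strictly within apo),
``remodeled_holo_gain`` (apo strictly within holo) and ``remodeled_both``
(overlap with extra labels on both sides).
"""

from __future__ import annotations

from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._tables import CHI_ATOMS, SYMMETRIC_CHI
from .structure import Conformer, MultiConfResidue

#: Default well edges (degrees): [0,120) -> p, [120,240) -> t, [240,360) -> m.
WELL_EDGES = (120.0, 240.0)

INCOMPLETE = "INCOMPLETE"


class RotamerChangeCategory(str, Enum):
    NO_CHANGE = "no_change"
    DISTINCT = "distinct"
    REMODELED_HOLO_LOSS = "remodeled_holo_loss"
    REMODELED_HOLO_GAIN = "remodeled_holo_gain"
    REMODELED_BOTH = "remodeled_both"


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
             p4: np.ndarray) -> float:
    """Signed torsion angle p1-p2-p3-p4 mapped to [0, 360) degrees."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("collinear points: dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang % 360.0)


def _bin_chi(angle: float, symmetric: bool,
             edges: tuple[float, float] = WELL_EDGES) -> str:
    a = angle % 360.0
    if symmetric:
        a = a % 180.0
        return "p" if a < edges[0] else "t"
    if a < edges[0]:
        return "p"
    if a < edges[1]:
        return "t"
    return "m"


def chi_angles(conformer: Conformer, aa: str) -> list[Optional[float]]:
    """All defined chi angles of one conformer (None where atoms missing)."""
    out: list[Optional[float]] = []
    for quad in CHI_ATOMS.get(aa, []):
        atoms = [conformer.get_atom(n) for n in quad]
        if any(a is None for a in atoms):
            out.append(None)
        else:
            out.append(dihedral(*(a.xyz for a in atoms)))
    return out


def assign_rotamer(conformer: Conformer, aa: str,
                   edges: tuple[float, float] = WELL_EDGES) -> str:
    """Rotamer-well label of one conformer, e.g. ``'mt'`` for Leu.

    Returns ``'INCOMPLETE'`` when a required chi atom is missing and
    ``''`` for residues with no chi angles (Gly/Ala).
    """
    quads = CHI_ATOMS.get(aa, [])
    label = []
    for i, angle in enumerate(chi_angles(conformer, aa), start=1):
        if angle is None:
            return INCOMPLETE
        label.append(_bin_chi(angle, (aa, i) in SYMMETRIC_CHI, edges))
    return "".join(label)


def residue_rotamer_set(residue: MultiConfResidue) -> set[str]:
    """Set of rotamer labels over a residue's conformers (incomplete dropped)."""
    labels = {assign_rotamer(c, residue.aa) for c in residue.conformers}
    return {l for l in labels if l != INCOMPLETE}


def classify_pair_rotamers(set_apo: set[str],
                           set_holo: set[str]) -> RotamerChangeCategory:
    """Four-way (plus a never-observed fifth) rotamer-change category."""
    if not set_apo or not set_holo:
        raise ValueError("rotamer sets must be non-empty")
    if set_apo == set_holo:
        return RotamerChangeCategory.NO_CHANGE
    if not (set_apo & set_holo):
        return RotamerChangeCategory.DISTINCT
    if set_holo < set_apo:
        return RotamerChangeCategory.REMODELED_HOLO_LOSS
    if set_apo < set_holo:
        return RotamerChangeCategory.REMODELED_HOLO_GAIN
    return RotamerChangeCategory.REMODELED_BOTH


def rotamer_table(model) -> pd.DataFrame:
    """Per-conformer rotamer labels for every residue of a structure."""
    rows = []
    for res in model.residues:
        for conf in res.conformers:
            rows.append({
                "structure_id": model.id, "chain": res.chain,
                "seqnum": res.seqnum, "aa": res.aa,
                "altloc": conf.altloc,
                "label": assign_rotamer(conf, res.aa),
            })
    return pd.DataFrame(rows)
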