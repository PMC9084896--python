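"""Ligand descriptor normalization and occupancy/B-factor context.

Size-driven descriptors (rotatable bonds, hydrogen-bond donors/acceptors)
are normalised by molecular weight or heavy-atom count so that quartile
comparisons contrast chemistry rather than sheer size.  Ligand occupancy
is classified as full (one conformer at ~1), multiconformer-full
(several conformers summing to ~1) or partial; ligand B-factors are put
on a per-structure scale by dividing by the mean alpha-carbon B-factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .metrics import calpha_bfactor
from .structure import MultiConfResidue, StructureModel

FULL_OCCUPANCY_TOL = 0.99


@dataclass
class LigandDescriptors:
    ligand_id: str
    mw: float
    n_heavy: int
    logp: float
    n_rotatable: int
    hbd: int
    hba: int
    rot_per_mw: float
    hb_per_heavy: float
    occupancy: Optional[float] = None
    occupancy_class: Optional[str] = None
    b_norm: Optional[float] = None


def normalize_descriptors(raw: dict) -> LigandDescriptors:
    """Populate derived size-normalised descriptor ratios."""
    mw = float(raw["mw"])
    n_heavy = int(raw["n_heavy"])
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    if n_heavy <= 0:
        raise ValueError("heavy-atom count must be positive")
    hbd, hba = int(raw["hbd"]), int(raw["hba"])
    n_rot = int(raw["n_rotatable"])
    return LigandDescriptors(
        ligand_id=str(raw["ligand_id"]), mw=mw, n_heavy=n_heavy,
        logp=float(raw["logp"]), n_rotatable=n_rot, hbd=hbd, hba=hba,
        rot_per_mw=n_rot / mw, hb_per_heavy=(hbd + hba) / n_heavy)


def ligand_occupancy_class(ligand: MultiConfResidue,
                           tol: float = FULL_OCCUPANCY_TOL) -> str:
    """'full' | 'multiconf_full' | 'partial' by total conformer occupancy."""
    total = sum(c.occupancy for c in ligand.conformers)
    if total <= 0:
        raise ValueError(f"ligand {ligand.key} has zero occupancy")
    if total >= tol:
        return "full" if len(ligand.conformers) == 1 else "multiconf_full"
    return "partial"


def ligand_occupancy(ligand: MultiConfResidue) -> float:
    return float(sum(c.occupancy for c in ligand.conformers))


def ligand_b_norm(ligand: MultiConfResidue, model: StructureModel) -> float:
    """Occupancy-weighted ligand heavy-atom B over mean alpha-carbon B."""
    num, wsum = 0.0, 0.0
    for conf in ligand.conformers:
        heavy = [a for a in conf.atoms if not a.is_hydrogen]
        if not heavy:
            continue
        num += conf.occupancy * float(np.mean([a.b_iso for a in heavy]))
        wsum += conf.occupancy
    if wsum == 0:
        raise ValueError(f"ligand {ligand.key} has no heavy atoms")
    cas = [calpha_bfactor(r) for r in model.residues]
    cas = [b for b in cas if np.isfinite(b)]
    if not cas:
        raise ValueError("structure has no alpha carbons")
    return (num / wsum) / float(np.mean(cas))


def ligand_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Augment a raw descriptor table with the normalised ratios."""
    out = []
    for _, row in rows.iterrows():
        d = normalize_descriptors(row.to_dict())
        rec = row.to_dict()
        rec.update(rot_per_mw=d.rot_per_mw, hb_per_heavy=d.hb_per_heavy)
        out.append(rec)
    return pd.DataFrame(out)
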