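"""Apo/holo pair construction: role classification, matching, QC.

A *holo* structure carries at least one HETATM group with >= 10 heavy
atoms whose residue code is not a common crystallographic additive; all
other structures are *apo*.  Candidate pairs must share a space group and
sequence (allowing up to five residues trimmed from either terminus of
either sequence), differ by at most 0.1 A in resolution, 1 A in each cell
length and 1 degree in each cell angle; each holo keeps the apo with the
smallest resolution difference.  Surviving pairs are quality-controlled
on Kabsch-superposed alpha-carbon RMSD, clashscore, R-free gaps and
ligand occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from ._tables import DEFAULT_ADDITIVES
from .structure import MultiConfResidue, StructureModel

RESOLUTION_TOL = 0.1
CELL_LENGTH_TOL = 1.0
CELL_ANGLE_TOL = 1.0
MAX_TERMINAL_TRIM = 5
_EPS = 1e-9


@dataclass
class StructureMeta:
    """Row of the structure metadata/QC table."""

    id: str
    role: str                     # 'apo' | 'holo'
    space_group: str
    cell: tuple[float, float, float, float, float, float]
    resolution: float
    sequence: str
    ligand_id: Optional[str] = None
    ligand_occupancy: Optional[float] = None
    r_free_initial: Optional[float] = None
    r_free_final: Optional[float] = None
    clashscore: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in ("apo", "holo"):
            raise ValueError(f"{self.id}: role must be apo or holo")
        if self.role == "holo" and not self.ligand_id:
            raise ValueError(f"{self.id}: holo structure without ligand_id")


@dataclass
class PairRecord:
    holo_id: str
    apo_id: str
    delta_resolution: float
    qc_status: str = "pass"
    qc_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.delta_resolution = abs(self.delta_resolution)


@dataclass
class QCConfig:
    max_global_rmsd: float = 1.0
    max_binding_site_rmsd: float = 0.5
    max_clashscore: float = 15.0
    max_rfree_gap: float = 0.05
    max_rfree_increase: float = 0.025
    min_ligand_occupancy: float = 0.15


def ligand_heavy_count(res: MultiConfResidue) -> int:
    return len(res.heavy_atoms)


def classify_role(model: StructureModel,
                  additive_list: Optional[set[str]] = None,
                  min_heavy: int = 10) -> str:
    """'holo' iff a non-additive HETATM group has >= ``min_heavy`` heavy atoms."""
    additives = DEFAULT_ADDITIVES if additive_list is None else additive_list
    for lig in model.ligands:
        if lig.aa in additives:
            continue
        if ligand_heavy_count(lig) >= min_heavy:
            return "holo"
    return "apo"


def select_ligand(model: StructureModel,
                  additive_list: Optional[set[str]] = None,
                  min_heavy: int = 10) -> Optional[MultiConfResidue]:
    """The qualifying ligand, preferring the lowest-alphabetical chain."""
    additives = DEFAULT_ADDITIVES if additive_list is None else additive_list
    candidates = [l for l in model.ligands
                  if l.aa not in additives and ligand_heavy_count(l) >= min_heavy]
    if not candidates:
        return None
    return min(candidates, key=lambda l: (l.chain, l.seqnum))


def _sequences_match(seq_a: str, seq_b: str,
                     max_trim: int = MAX_TERMINAL_TRIM) -> bool:
    """Equal sequences, or equal after trimming up to ``max_trim`` residues
    from either terminus of either sequence (minimal trim accepted)."""
    if seq_a == seq_b:
        return True
    for la in range(max_trim + 1):
        for ra in range(max_trim + 1):
            a = seq_a[la:len(seq_a) - ra or None]
            for lb in range(max_trim + 1):
                for rb in range(max_trim + 1):
                    b = seq_b[lb:len(seq_b) - rb or None]
                    if a and a == b:
                        return True
    return False


def _cells_match(cell_a, cell_b) -> bool:
    for i in range(3):
        if abs(cell_a[i] - cell_b[i]) > CELL_LENGTH_TOL + _EPS:
            return False
    for i in range(3, 6):
        if abs(cell_a[i] - cell_b[i]) > CELL_ANGLE_TOL + _EPS:
            return False
    return True


def pair_eligible(holo: StructureMeta, apo: StructureMeta) -> bool:
    return (holo.space_group == apo.space_group
            and _sequences_match(holo.sequence, apo.sequence)
            and abs(holo.resolution - apo.resolution) <= RESOLUTION_TOL + _EPS
            and _cells_match(holo.cell, apo.cell))


def match_pairs(metas: Sequence[StructureMeta]) -> list[PairRecord]:
    """All matching (holo, apo) pairs, reduced to one apo per holo.

    The retained apo minimises the absolute resolution difference; ties go
    to the lexicographically smallest apo id.
    """
    holos = sorted((m for m in metas if m.role == "holo"), key=lambda m: m.id)
    apos = [m for m in metas if m.role == "apo"]
    records = []
    for holo in holos:
        eligible = [a for a in apos if pair_eligible(holo, a)]
        if not eligible:
            continue
        best = min(eligible,
                   key=lambda a: (abs(holo.resolution - a.resolution), a.id))
        records.append(PairRecord(holo_id=holo.id, apo_id=best.id,
                                  delta_resolution=holo.resolution - best.resolution))
    return records


def kabsch_superpose(coords_ref: np.ndarray, coords_mov: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (rotation, translation, RMSD).

    Returns the proper rotation matrix R and translation t such that
    ``coords_mov @ R.T + t`` best fits ``coords_ref``.
    """
    ref = np.asarray(coords_ref, dtype=float)
    mov = np.asarray(coords_mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate arrays must be matched N x 3")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("at least 3 points required for superposition")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    if (np.linalg.matrix_rank(ref_c, tol=1e-8) < 2
            or np.linalg.matrix_rank(mov_c, tol=1e-8) < 2):
        raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(ref_c, mov_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - rot.apply(mov.mean(axis=0))
    rmsd = float(rssd / np.sqrt(n))
    return R, t, rmsd


def calpha_coords(model: StructureModel,
                  keys: Optional[set] = None) -> tuple[list, np.ndarray]:
    out_keys, coords = [], []
    for res in model.residues:
        if keys is not None and res.key not in keys:
            continue
        ca = res.best_conformer().get_atom("CA")
        if ca is not None:
            out_keys.append(res.key)
            coords.append(ca.xyz)
    return out_keys, np.asarray(coords)


def paired_calpha_rmsd(apo: StructureModel, holo: StructureModel,
                       keys: Optional[set] = None) -> float:
    """Alpha-carbon RMSD after optimal superposition of residues shared by
    both models (paired by apo residue numbering)."""
    keys_a, ca_a = calpha_coords(apo, keys)
    keys_h, ca_h = calpha_coords(holo, keys)
    common = [k for k in keys_a if k in set(keys_h)]
    if len(common) < 3:
        raise ValueError("fewer than 3 shared alpha carbons")
    idx_a = {k: i for i, k in enumerate(keys_a)}
    idx_h = {k: i for i, k in enumerate(keys_h)}
    a = ca_a[[idx_a[k] for k in common]]
    h = ca_h[[idx_h[k] for k in common]]
    return kabsch_superpose(a, h)[2]


def qc_filter(pair: PairRecord, apo_meta: StructureMeta,
              holo_meta: StructureMeta,
              apo: Optional[StructureModel] = None,
              holo: Optional[StructureModel] = None,
              binding_site: Optional[set] = None,
              thresholds: Optional[QCConfig] = None) -> PairRecord:
    """Accumulate QC failure reasons on a matched pair.

    Checks: global and binding-site alpha-carbon RMSD, clashscore of either
    structure, apo/holo R-free gap, per-structure R-free increase across
    refinement, and minimum ligand occupancy.  The pair passes iff no
    reason accumulates.
    """
    cfg = thresholds or QCConfig()
    reasons: list[str] = []

    if apo is not None and holo is not None:
        if paired_calpha_rmsd(apo, holo) > cfg.max_global_rmsd:
            reasons.append("global_rmsd")
        if binding_site:
            if paired_calpha_rmsd(apo, holo, binding_site) > cfg.max_binding_site_rmsd:
                reasons.append("binding_site_rmsd")

    for meta in (apo_meta, holo_meta):
        if meta.clashscore is not None and meta.clashscore > cfg.max_clashscore:
            reasons.append(f"clashscore:{meta.id}")
        if (meta.r_free_initial is not None and meta.r_free_final is not None
                and meta.r_free_final - meta.r_free_initial > cfg.max_rfree_increase):
            reasons.append(f"rfree_increase:{meta.id}")

    if (apo_meta.r_free_final is not None and holo_meta.r_free_final is not None
            and abs(holo_meta.r_free_final - apo_meta.r_free_final) > cfg.max_rfree_gap):
        reasons.append("rfree_gap")

    if (holo_meta.ligand_occupancy is not None
            and holo_meta.ligand_occupancy < cfg.min_ligand_occupancy):
        reasons.append("ligand_occupancy")

    return PairRecord(holo_id=pair.holo_id, apo_id=pair.apo_id,
                      delta_resolution=pair.delta_resolution,
                      qc_status="pass" if not reasons else "fail",
                      qc_reasons=reasons)


# ---------------------------------------------------------------------------
# Metadata table I/O

_META_COLUMNS = ["id", "role", "space_group", "a", "b", "c", "alpha", "beta",
                 "gamma", "resolution", "sequence"]


def read_meta_table(path: str) -> list[StructureMeta]:
    df = pd.read_csv(path)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    metas = []
    for _, row in df.iterrows():
        def opt(col):
            return (float(row[col])
                    if col in df.columns and pd.notna(row[col]) else None)
        metas.append(StructureMeta(
            id=str(row["id"]), role=str(row["role"]),
            space_group=str(row["space_group"]),
            cell=tuple(float(row[c]) for c in ("a", "b", "c", "alpha", "beta", "gamma")),
            resolution=float(row["resolution"]), sequence=str(row["sequence"]),
            ligand_id=(str(row["ligand_id"])
                       if "ligand_id" in df.columns and pd.notna(row.get("ligand_id"))
                       else None),
            ligand_occupancy=opt("ligand_occupancy"),
            r_free_initial=opt("r_free_initial"),
            r_free_final=opt("r_free_final"),
            clashscore=opt("clashscore")))
    return metas


def pairs_to_frame(records: Sequence[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "holo_id": r.holo_id, "apo_id": r.apo_id,
        "delta_resolution": r.delta_resolution,
        "qc_status": r.qc_status, "qc_reasons": ";".join(r.qc_reasons),
    } for r in records])
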