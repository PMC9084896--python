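"""Spatial partitioning of residues and solvent accessibility.

Residues are classified relative to a bound ligand — *binding site*
(any heavy atom within 5 A of any ligand heavy atom) and *distant*
(more than 10 A from every ligand heavy atom) — and by solvent exposure,
using an in-repo Shrake-Rupley solvent-accessible surface area (SASA)
with the relative-accessibility convention: a residue with
RASA = SASA / MaxASA >= 20% counts as solvent exposed.

SASA is evaluated on the highest-occupancy conformer of each residue with
hydrogens excluded, sampling each atom's solvent-extended sphere with a
deterministic Fibonacci point set and occluding points that fall inside a
neighbour's extended sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._tables import MAX_ASA, VDW_RADII
from .structure import MultiConfResidue, StructureModel

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960
EXPOSURE_THRESHOLD = 0.20
BINDING_SITE_CUTOFF = 5.0
DISTANT_CUTOFF = 10.0


@dataclass
class EnvironmentClass:
    is_binding_site: bool
    is_distant: bool
    rasa: float
    is_exposed: bool


def _heavy_coords(residue: MultiConfResidue) -> np.ndarray:
    atoms = residue.heavy_atoms
    if not atoms:
        return np.empty((0, 3))
    return np.asarray([a.xyz for a in atoms])


def min_ligand_distances(model: StructureModel,
                         ligand: MultiConfResidue) -> pd.Series:
    """Minimum heavy-atom distance from each residue to the ligand."""
    lig = _heavy_coords(ligand)
    if lig.size == 0:
        raise ValueError("ligand has no heavy atoms")
    tree = cKDTree(lig)
    out = {}
    for res in model.residues:
        coords = _heavy_coords(res)
        if coords.size == 0:
            continue
        out[res.key] = float(tree.query(coords)[0].min())
    return pd.Series(out)


def binding_site_residues(model: StructureModel, ligand: MultiConfResidue,
                          cutoff: float = BINDING_SITE_CUTOFF) -> set:
    """Residues with any heavy atom within ``cutoff`` of a ligand heavy atom."""
    d = min_ligand_distances(model, ligand)
    return set(d.index[d <= cutoff])


def distant_residues(model: StructureModel, ligand: MultiConfResidue,
                     cutoff: float = DISTANT_CUTOFF) -> set:
    """Residues whose closest heavy atom is more than ``cutoff`` from the ligand."""
    d = min_ligand_distances(model, ligand)
    return set(d.index[d > cutoff])


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(coords: np.ndarray, elements: list[str],
                       probe: float = PROBE_RADIUS,
                       n_points: int = N_SPHERE_POINTS,
                       subset: np.ndarray | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley style.

    ``subset`` optionally restricts which atoms get an area (all atoms
    still occlude); excluded atoms report 0.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    try:
        radii = np.asarray([VDW_RADII[e.upper()] for e in elements])
    except KeyError as exc:
        raise ValueError(f"unknown element {exc.args[0]!r}: no vdW radius") from exc
    ext = radii + probe
    sphere = fibonacci_sphere(n_points)
    areas = np.zeros(n)
    tree = cKDTree(coords)
    max_ext = ext.max()
    targets = range(n) if subset is None else np.asarray(subset, dtype=int)
    for i in targets:
        nbrs = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                if j != i]
        if not nbrs:
            areas[i] = 4.0 * np.pi * ext[i] ** 2
            continue
        nbrs = np.asarray(nbrs)
        # closest occluders first so buried atoms terminate early
        order = np.argsort(np.sum((coords[nbrs] - coords[i]) ** 2, axis=1))
        nbrs = nbrs[order]
        pts = coords[i] + ext[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for start in range(0, len(nbrs), 16):
            chunk = nbrs[start:start + 16]
            diff = pts[accessible, None, :] - coords[chunk][None, :, :]
            blocked = np.any(
                np.einsum("pjk,pjk->pj", diff, diff) <= ext[chunk] ** 2,
                axis=1)
            idx = np.flatnonzero(accessible)
            accessible[idx[blocked]] = False
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
    return areas


def residue_sasa(model: StructureModel, probe: float = PROBE_RADIUS,
                 n_points: int = N_SPHERE_POINTS,
                 include_hydrogens: bool = False) -> pd.Series:
    """Per-residue SASA on the highest-occupancy conformer of each residue.

    Ligand/HETATM atoms act as occluders but their own areas are not
    computed (only protein residues are classified by exposure).
    """
    coords, elements, owner = [], [], []
    for group, is_protein in ((model.residues, True), (model.ligands, False)):
        for res in group:
            conf = res.best_conformer()
            for a in conf.atoms:
                if a.is_hydrogen and not include_hydrogens:
                    continue
                coords.append(a.xyz)
                elements.append(a.element)
                owner.append(res.key if is_protein else None)
    if not coords:
        return pd.Series(dtype=float)
    subset = np.flatnonzero([o is not None for o in owner])
    areas = shrake_rupley_sasa(np.asarray(coords), elements, probe, n_points,
                               subset=subset)
    df = pd.DataFrame({"owner": [owner[i] for i in subset],
                       "area": areas[subset]})
    totals = df.groupby("owner", sort=False)["area"].sum()
    return pd.Series({k: totals[k] for k in totals.index})


def classify_exposure(sasa: float, aa: str,
                      threshold: float = EXPOSURE_THRESHOLD
                      ) -> tuple[float, bool]:
    """Relative accessibility and the exposed/buried call (RASA >= threshold)."""
    if aa not in MAX_ASA:
        raise ValueError(f"no MaxASA tabulated for residue type {aa!r}")
    rasa = sasa / MAX_ASA[aa]
    return float(rasa), bool(rasa >= threshold)


def environment_table(model: StructureModel, ligand: MultiConfResidue,
                      binding_cutoff: float = BINDING_SITE_CUTOFF,
                      distant_cutoff: float = DISTANT_CUTOFF,
                      exposure_threshold: float = EXPOSURE_THRESHOLD,
                      n_points: int = N_SPHERE_POINTS) -> pd.DataFrame:
    """Full environment classification for every residue of a structure."""
    dist = min_ligand_distances(model, ligand)
    sasa = residue_sasa(model, n_points=n_points)
    rows = []
    for res in model.residues:
        if res.key not in dist.index:
            continue
        d = dist[res.key]
        s = float(sasa.get(res.key, 0.0))
        rasa, exposed = classify_exposure(s, res.aa, exposure_threshold)
        rows.append({
            "structure_id": model.id, "chain": res.chain,
            "seqnum": res.seqnum, "icode": res.icode, "aa": res.aa,
            "min_ligand_distance": d,
            "is_binding_site": d <= binding_cutoff,
            "is_distant": d > distant_cutoff,
            "sasa": s, "rasa": rasa, "is_exposed": exposed,
        })
    return pd.DataFrame(rows)
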