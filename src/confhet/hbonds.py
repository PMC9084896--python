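"""Geometric hydrogen-bond detection with occupancy weighting.

A hydrogen bond is recorded when the hydrogen-to-acceptor distance is
below 3.2 A and the donor-H...acceptor angle is at least 90 degrees,
with donor/acceptor chemistry taken from a per-residue-type table
(backbone N-H donor and carbonyl O acceptor; side-chain N/O/S groups).
Only side-chain/side-chain and side-chain/main-chain bonds are kept.

Multiconformer structures are handled by splitting the model into one
single-conformer structure per altloc label, detecting bonds in each
split, and recombining: every unique bond (identified by its donor and
acceptor atoms regardless of altloc) contributes the maximum over splits
of min(donor occupancy, acceptor occupancy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._tables import (BACKBONE_ACCEPTORS, BACKBONE_DONOR, SIDECHAIN_ACCEPTORS,
                      SIDECHAIN_DONORS)
from .structure import MultiConfResidue, StructureModel, split_by_altloc

H_A_CUTOFF = 3.2
MIN_DHA_ANGLE = 90.0
#: Maximum covalent D-H distance used to pair hydrogens with donor atoms.
DH_COVALENT_CUTOFF = 1.35


@dataclass(frozen=True)
class HBond:
    donor: tuple        # (residue key, atom name, altloc)
    hydrogen: tuple
    acceptor: tuple
    h_a_distance: float
    dha_angle: float
    weight: float
    bond_class: str     # 'sidechain-sidechain' | 'sidechain-mainchain'


def _is_donor(res: MultiConfResidue, name: str) -> bool:
    if name == BACKBONE_DONOR and res.aa != "PRO":
        return True
    return name in SIDECHAIN_DONORS.get(res.aa, ())


def _is_acceptor(res: MultiConfResidue, name: str) -> bool:
    return name in BACKBONE_ACCEPTORS or name in SIDECHAIN_ACCEPTORS.get(res.aa, ())


def detect_hbonds(model: StructureModel, h_a_cutoff: float = H_A_CUTOFF,
                  min_dha: float = MIN_DHA_ANGLE) -> list[HBond]:
    """All side-chain-involving hydrogen bonds of a single-conformer model.

    Requires explicit hydrogens; raises otherwise.  Intra-residue pairs are
    excluded, as are main-chain/main-chain bonds.
    """
    residues = list(model.residues)
    entries = []   # (res, atom)
    hydrogens = []
    for res in residues:
        if len(res.conformers) != 1:
            raise ValueError("detect_hbonds expects a single-conformer model; "
                             "use split_by_altloc first")
        for atom in res.conformers[0].atoms:
            if atom.is_hydrogen:
                hydrogens.append((res, atom))
            else:
                entries.append((res, atom))
    if not hydrogens:
        raise ValueError("no hydrogens in model: hydrogen placement is "
                         "required before hydrogen-bond detection")

    donors = []  # (res, donor atom, hydrogen atom)
    for res, h in hydrogens:
        best = None
        for res2, heavy in entries:
            if res2 is not res:
                continue
            d = float(np.linalg.norm(h.xyz - heavy.xyz))
            if d < DH_COVALENT_CUTOFF and (best is None or d < best[0]):
                best = (d, heavy)
        if best is not None and _is_donor(res, best[1].name):
            donors.append((res, best[1], h))

    acceptors = [(res, a) for res, a in entries if _is_acceptor(res, a.name)]
    if not acceptors or not donors:
        return []
    acc_coords = np.asarray([a.xyz for _, a in acceptors])
    tree = cKDTree(acc_coords)

    bonds = []
    for res, d_atom, h_atom in donors:
        for j in tree.query_ball_point(h_atom.xyz, h_a_cutoff):
            a_res, a_atom = acceptors[j]
            if a_res is res:
                continue
            dist = float(np.linalg.norm(h_atom.xyz - a_atom.xyz))
            if dist >= h_a_cutoff:
                continue
            v1 = d_atom.xyz - h_atom.xyz
            v2 = a_atom.xyz - h_atom.xyz
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < min_dha:
                continue
            d_main = d_atom.is_mainchain
            a_main = a_atom.is_mainchain
            if d_main and a_main:
                continue
            bond_class = ("sidechain-sidechain" if not d_main and not a_main
                          else "sidechain-mainchain")
            bonds.append(HBond(
                donor=(res.key, d_atom.name, d_atom.altloc),
                hydrogen=(res.key, h_atom.name, h_atom.altloc),
                acceptor=(a_res.key, a_atom.name, a_atom.altloc),
                h_a_distance=dist, dha_angle=angle,
                weight=min(d_atom.occupancy, a_atom.occupancy),
                bond_class=bond_class))
    return bonds


def collect_weighted_hbonds(model: StructureModel,
                            h_a_cutoff: float = H_A_CUTOFF,
                            min_dha: float = MIN_DHA_ANGLE,
                            dedup: bool = True) -> pd.DataFrame:
    """Occupancy-weighted unique hydrogen bonds across altloc splits.

    With ``dedup`` (default) a bond seen in several splits contributes its
    maximum weight once; otherwise per-split weights are summed.
    """
    records: dict[tuple, dict] = {}
    for split in split_by_altloc(model):
        for b in detect_hbonds(split, h_a_cutoff, min_dha):
            key = (b.donor[0], b.donor[1], b.acceptor[0], b.acceptor[1])
            if key not in records:
                records[key] = {
                    "donor_res": b.donor[0], "donor_atom": b.donor[1],
                    "acceptor_res": b.acceptor[0], "acceptor_atom": b.acceptor[1],
                    "h_a_distance": b.h_a_distance, "dha_angle": b.dha_angle,
                    "bond_class": b.bond_class, "weight": b.weight,
                }
            elif dedup:
                records[key]["weight"] = max(records[key]["weight"], b.weight)
            else:
                records[key]["weight"] += b.weight
    return pd.DataFrame(list(records.values()))


def weighted_hbond_count(model: StructureModel, region: set,
                         h_a_cutoff: float = H_A_CUTOFF,
                         min_dha: float = MIN_DHA_ANGLE,
                         dedup: bool = True) -> float:
    """Occupancy-weighted hydrogen bonds per residue of ``region``.

    ``region`` is a set of residue keys; a bond counts when at least one
    endpoint residue lies in the region.  The total weight is divided by
    the region size.
    """
    if not region:
        raise ValueError("empty region")
    table = collect_weighted_hbonds(model, h_a_cutoff, min_dha, dedup)
    if table.empty:
        return 0.0
    in_region = table.apply(
        lambda r: r["donor_res"] in region or r["acceptor_res"] in region,
        axis=1)
    return float(table.loc[in_region, "weight"].sum()) / len(region)
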