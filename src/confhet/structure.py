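"""Data model and I/O for multiconformer PDB structures.

A multiconformer crystallographic model describes each disordered residue
as a small set of alternative conformations ("altlocs"), each carrying a
fractional occupancy and per-atom isotropic B-factors.  This module maps
the fixed-column PDB representation of such models onto an explicit
conformer-grouped data model: every residue owns one or more
:class:`Conformer` objects, atoms without an altloc label are shared by
all conformers of their residue, and crystal metadata (space group, unit
cell, resolution) travels with the structure.

Parsing and serialisation are delegated to :mod:`gemmi`; this module only
performs the grouping into conformers and back.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Standard amino-acid three-letter codes (protein residues).
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Atom names belonging to the protein main chain (backbone).
MAINCHAIN_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA",
                   "HA2", "HA3"}


class PDBFormatError(ValueError):
    """Raised for malformed PDB records or unserialisable models."""


@dataclass
class AtomRecord:
    """One atom site: name, element, altloc, occupancy, B-factor, position."""

    name: str
    element: str
    altloc: str  # '' means blank (shared by all conformers of the residue)
    occupancy: float
    b_iso: float
    xyz: np.ndarray
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not (0.0 <= self.occupancy <= 1.0 + 1e-6):
            raise ValueError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}")
        if self.b_iso < 0:
            raise ValueError(f"negative B-factor for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_mainchain(self) -> bool:
        return self.name in MAINCHAIN_ATOMS


@dataclass
class Conformer:
    """One alternative conformation of a residue.

    ``atoms`` holds every atom belonging to this conformation, including
    blank-altloc atoms shared with the other conformers of the residue
    (those keep ``altloc == ''`` so serialisation can emit them once).
    """

    altloc: str
    occupancy: float
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def own_atoms(self) -> list[AtomRecord]:
        """Atoms exclusive to this conformation (altloc-labelled)."""
        if self.altloc == "":
            return self.atoms
        return [a for a in self.atoms if a.altloc == self.altloc]

    @property
    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def get_atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class MultiConfResidue:
    """A residue with one or more alternative conformations."""

    chain: str
    seqnum: int
    icode: str
    aa: str
    conformers: list[Conformer]

    def __post_init__(self) -> None:
        labels = [c.altloc for c in self.conformers]
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate altloc labels in residue {self.key}")
        total = sum(c.occupancy for c in self.conformers)
        if len(self.conformers) > 1 and total > 1.0 + 1e-6:
            raise ValueError(
                f"conformer occupancies of {self.key} sum to {total:.3f} > 1")

    @property
    def key(self) -> tuple[str, int, str]:
        """Stable residue identifier (chain, seqnum, icode)."""
        return (self.chain, self.seqnum, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain}{self.seqnum}{self.icode}".strip()

    @property
    def is_amino_acid(self) -> bool:
        return self.aa in AMINO_ACIDS

    @property
    def shared_atoms(self) -> list[AtomRecord]:
        """Blank-altloc atoms, listed once."""
        return [a for a in self.conformers[0].atoms if a.altloc == ""]

    @property
    def heavy_atoms(self) -> list[AtomRecord]:
        """Union of heavy atoms over all conformers, each site once."""
        out = list(a for a in self.shared_atoms if not a.is_hydrogen)
        for c in self.conformers:
            out.extend(a for a in c.own_atoms
                       if a.altloc != "" and not a.is_hydrogen)
        return out

    def sidechain_altlocs(self) -> set[str]:
        """Distinct non-blank altloc labels on side-chain atoms."""
        labels = set()
        for c in self.conformers:
            for a in c.own_atoms:
                if a.altloc != "" and not a.is_mainchain:
                    labels.add(a.altloc)
        return labels

    def best_conformer(self) -> Conformer:
        """Highest-occupancy conformer; ties broken by smallest altloc."""
        return min(self.conformers, key=lambda c: (-c.occupancy, c.altloc))

    def get_conformer(self, altloc: str) -> Optional[Conformer]:
        for c in self.conformers:
            if c.altloc == altloc:
                return c
        return None


@dataclass
class StructureModel:
    """Chains of residues plus ligands and crystal metadata."""

    id: str
    residues: list[MultiConfResidue]
    ligands: list[MultiConfResidue]
    space_group: str = ""
    cell: tuple[float, float, float, float, float, float] = (0.0,) * 6
    resolution: float = 0.0
    r_free: Optional[float] = None

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"{self.id}: resolution must be positive")
        a, b, c, al, be, ga = self.cell
        if min(a, b, c) <= 0:
            raise ValueError(f"{self.id}: cell lengths must be positive")
        for ang in (al, be, ga):
            if not (0 < ang < 180):
                raise ValueError(f"{self.id}: cell angle {ang} outside (0, 180)")

    @property
    def has_crystal_metadata(self) -> bool:
        return bool(self.space_group) and min(self.cell[:3]) > 0

    def get_residue(self, key: tuple[str, int, str]) -> Optional[MultiConfResidue]:
        for r in self.residues:
            if r.key == key:
                return r
        return None

    def altloc_labels(self) -> list[str]:
        labels: set[str] = set()
        for res in list(self.residues) + list(self.ligands):
            for c in res.conformers:
                if c.altloc:
                    labels.add(c.altloc)
        return sorted(labels)

    def iter_atoms(self) -> Iterator[tuple[MultiConfResidue, AtomRecord]]:
        for res in list(self.residues) + list(self.ligands):
            for a in res.shared_atoms:
                yield res, a
            for c in res.conformers:
                for a in c.own_atoms:
                    if a.altloc != "":
                        yield res, a

    def sequence(self) -> str:
        """One-letter sequence of amino-acid residues in file order."""
        return "".join(_THREE_TO_ONE.get(r.aa, "X") for r in self.residues)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


# ---------------------------------------------------------------------------
# Reading

def _group_residue(res: gemmi.Residue, chain_id: str, is_hetero: bool
                   ) -> MultiConfResidue:
    shared: list[AtomRecord] = []
    by_altloc: dict[str, list[AtomRecord]] = {}
    for atom in res:
        altloc = atom.altloc if atom.altloc != "\0" else ""
        rec = AtomRecord(
            name=atom.name,
            element=atom.element.name,
            altloc=altloc,
            occupancy=min(atom.occ, 1.0),
            b_iso=atom.b_iso,
            xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
            is_hetero=is_hetero,
        )
        if altloc == "":
            shared.append(rec)
        else:
            by_altloc.setdefault(altloc, []).append(rec)

    if not by_altloc:
        occ = shared[0].occupancy if shared else 1.0
        confs = [Conformer(altloc="", occupancy=occ, atoms=shared)]
    else:
        confs = []
        for label in sorted(by_altloc):
            own = by_altloc[label]
            confs.append(Conformer(
                altloc=label,
                occupancy=own[0].occupancy,
                # blank-altloc atoms are shared by every conformer
                atoms=shared + own,
            ))
    return MultiConfResidue(
        chain=chain_id,
        seqnum=res.seqid.num,
        icode=res.seqid.icode.strip(),
        aa=res.name,
        conformers=confs,
    )


def read_pdb(path: str, resolution: Optional[float] = None,
             structure_id: Optional[str] = None) -> StructureModel:
    """Read a PDB file into a conformer-grouped :class:`StructureModel`.

    Altloc groups are assembled into :class:`Conformer` objects; blank-altloc
    atoms are shared by every conformer of their residue.  CRYST1 supplies
    space group and cell; resolution is taken from REMARK 2 unless
    ``resolution`` is given explicitly.  Only the first MODEL of a
    multi-model file is read (a warning is logged).
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no coordinate records")
    if len(st) > 1:
        logger.warning("%s: %d MODEL records, using MODEL 1 only", path, len(st))

    residues: list[MultiConfResidue] = []
    ligands: list[MultiConfResidue] = []
    model = st[0]
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H" and res.name != "HOH"
            if res.name == "HOH":
                continue
            mcr = _group_residue(res, chain.name, is_het)
            (ligands if is_het else residues).append(mcr)

    sg = st.spacegroup_hm or ""
    cell = (st.cell.a, st.cell.b, st.cell.c,
            st.cell.alpha, st.cell.beta, st.cell.gamma)
    if sg.strip() in ("", "P 1") and st.cell.a == 1.0:
        # gemmi's placeholder cell for files without CRYST1
        sg = ""
        cell = (0.0,) * 6
        logger.warning("%s: no CRYST1 record; crystal metadata absent", path)
    res_a = resolution if resolution is not None else (
        st.resolution if st.resolution > 0 else 0.0)
    return StructureModel(
        id=structure_id or st.name or str(path),
        residues=residues,
        ligands=ligands,
        space_group=sg,
        cell=cell,
        resolution=res_a,
    )


# ---------------------------------------------------------------------------
# Writing

def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.id
    if model.has_crystal_metadata:
        st.cell = gemmi.UnitCell(*model.cell)
        st.spacegroup_hm = model.space_group
    if model.resolution > 0:
        st.resolution = model.resolution
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in list(model.residues) + list(model.ligands):
        ch = chains.get(res.chain)
        if ch is None:
            ch = gemmi.Chain(res.chain)
            chains[res.chain] = ch
        gres = gemmi.Residue()
        gres.name = res.aa
        gres.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
        gres.het_flag = "H" if any(
            a.is_hetero for a in res.conformers[0].atoms) else "A"
        emitted_shared = False
        for conf in res.conformers:
            for atom in conf.atoms:
                if atom.altloc == "" and emitted_shared:
                    continue
                if len(atom.name) > 4:
                    raise PDBFormatError(
                        f"atom name {atom.name!r} longer than 4 characters")
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.altloc = atom.altloc if atom.altloc else "\0"
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_iso
                ga.pos = gemmi.Position(*atom.xyz)
                gres.add_atom(ga)
            emitted_shared = True
        ch.add_residue(gres)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_pdb(model: StructureModel, path: str) -> None:
    """Serialise a model as fixed-column PDB (CRYST1, REMARK 2, ATOM/HETATM)."""
    st = _to_gemmi(model)
    st.write_pdb(str(path))


def write_pdb_string(model: StructureModel) -> str:
    return _to_gemmi(model).make_pdb_string()


# ---------------------------------------------------------------------------
# Altloc splitting

def split_by_altloc(model: StructureModel) -> list[StructureModel]:
    """Split a multiconformer model into single-conformer models.

    One model per distinct altloc label: model ``L`` contains, for every
    residue, the atoms labelled ``L`` plus all blank-altloc atoms.  A
    residue lacking label ``L`` contributes its highest-occupancy conformer
    (tie broken by smallest altloc).  A model with no altlocs yields one
    copy of itself.
    """
    labels = model.altloc_labels()
    if not labels:
        return [model]

    out = []
    for label in labels:
        residues = []
        ligands = []
        for src, dest in ((model.residues, residues), (model.ligands, ligands)):
            for res in src:
                conf = res.get_conformer(label) or res.best_conformer()
                new_conf = Conformer(altloc=conf.altloc,
                                     occupancy=conf.occupancy,
                                     atoms=list(conf.atoms))
                dest.append(MultiConfResidue(
                    chain=res.chain, seqnum=res.seqnum, icode=res.icode,
                    aa=res.aa, conformers=[new_conf]))
        out.append(StructureModel(
            id=f"{model.id}_alt{label}",
            residues=residues, ligands=ligands,
            space_group=model.space_group, cell=model.cell,
            resolution=model.resolution, r_free=model.r_free))
    return out
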