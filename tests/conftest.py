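"""Shared fixtures: hand-written PDB snippets and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from confhet.structure import AtomRecord, Conformer, MultiConfResidue
from confhet.synthetic import CohortSpec, build_pair

# A minimal two-conformer serine with full crystal metadata, written by hand
# against the fixed-column format definition.
MINIMAL_ALTLOC_PDB = """\
REMARK   2 RESOLUTION.    1.60 ANGSTROMS.
CRYST1   40.000   50.000   60.000  90.00  90.00  90.00 P 21 21 21
ATOM      1  N   SER A   1       0.000   1.000   0.000  1.00 10.00           N
ATOM      2  CA  SER A   1       1.458   1.000   0.000  1.00 10.00           C
ATOM      3  C   SER A   1       2.000   2.400   0.000  1.00 10.00           C
ATOM      4  O   SER A   1       1.500   3.300   0.700  1.00 10.00           O
ATOM      5  CB ASER A   1       2.000   0.300   1.250  0.60 12.00           C
ATOM      6  OG ASER A   1       3.400   0.300   1.250  0.60 14.00           O
ATOM      7  CB BSER A   1       2.000   0.300  -1.250  0.40 13.00           C
ATOM      8  OG BSER A   1       3.400   0.300  -1.250  0.40 15.00           O
END
"""

NO_ALTLOC_PDB = """\
REMARK   2 RESOLUTION.    1.80 ANGSTROMS.
CRYST1   40.000   50.000   60.000  90.00  90.00  90.00 P 1
ATOM      1  N   ALA A   1       0.000   1.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   1.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.000   2.400   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.500   3.300   0.700  1.00 10.00           O
ATOM      5  CB  ALA A   1       2.000   0.300   1.250  1.00 12.00           C
ATOM      6  N   GLY A   2       3.300   2.500   0.000  1.00 11.00           N
ATOM      7  CA  GLY A   2       4.100   3.700   0.000  1.00 11.00           C
ATOM      8  C   GLY A   2       5.600   3.500   0.000  1.00 11.00           C
ATOM      9  O   GLY A   2       6.200   2.500   0.500  1.00 11.00           O
END
"""


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(MINIMAL_ALTLOC_PDB)
    return p


@pytest.fixture
def plain_pdb(tmp_path):
    p = tmp_path / "plain.pdb"
    p.write_text(NO_ALTLOC_PDB)
    return p


def make_residue(aa="SER", chain="A", seqnum=1, conformers=None):
    """Hand-assemble a residue from (altloc, occupancy, {atom: (xyz, b)})."""
    confs = []
    for altloc, occ, atoms in conformers:
        recs = [AtomRecord(name=name, element=elem, altloc=altloc if name_alt
                           else "", occupancy=occ if name_alt else 1.0,
                           b_iso=b, xyz=np.asarray(xyz, dtype=float))
                for name, (elem, xyz, b, name_alt) in atoms.items()]
        confs.append(Conformer(altloc=altloc, occupancy=occ, atoms=recs))
    return MultiConfResidue(chain=chain, seqnum=seqnum, icode="", aa=aa,
                            conformers=confs)


@pytest.fixture(scope="session")
def synthetic_pair():
    """One deterministic apo/holo pair with planted effects, in memory."""
    spec = CohortSpec()
    rng = np.random.default_rng(7)
    return build_pair(spec, 0, 0.05, -0.02, rng)
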