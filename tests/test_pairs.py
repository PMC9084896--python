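"""Role classification, pair matching, Kabsch superposition, QC filters."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from confhet.pairs import (PairRecord, QCConfig, StructureMeta, classify_role,
                           kabsch_superpose, match_pairs, pair_eligible,
                           qc_filter, select_ligand, _sequences_match)
from confhet.structure import AtomRecord, Conformer, MultiConfResidue, StructureModel


def _hetero_group(code, n_heavy, chain="L"):
    atoms = [AtomRecord(name=f"C{i+1}", element="C", altloc="",
                        occupancy=1.0, b_iso=20.0,
                        xyz=np.array([float(i), 0.0, 0.0]), is_hetero=True)
             for i in range(n_heavy)]
    return MultiConfResidue(chain=chain, seqnum=500, icode="", aa=code,
                            conformers=[Conformer("", 1.0, atoms)])


def _structure(ligands):
    return StructureModel(id="s", residues=[], ligands=ligands,
                          space_group="P 1", cell=(10, 10, 10, 90, 90, 90),
                          resolution=1.5)


def test_classify_role_rules():
    assert classify_role(_structure([_hetero_group("LIG", 19)])) == "holo"
    assert classify_role(_structure([_hetero_group("LIG", 9)])) == "apo"
    # additive codes are excluded regardless of size
    assert classify_role(_structure([_hetero_group("GOL", 12)]),
                         additive_list={"GOL"}) == "apo"
    assert classify_role(_structure([])) == "apo"


def test_select_ligand_prefers_lowest_chain():
    lig_b = _hetero_group("LIG", 12, chain="B")
    lig_a = _hetero_group("LIG", 12, chain="A")
    assert select_ligand(_structure([lig_b, lig_a])) is lig_a


def _meta(mid, role="apo", sg="P 1", cell=(50, 60, 70, 90, 90, 90),
          res=1.5, seq="SVLSVLSVL", **kw):
    if role == "holo":
        kw.setdefault("ligand_id", "LIG")
    return StructureMeta(id=mid, role=role, space_group=sg, cell=cell,
                         resolution=res, sequence=seq, **kw)


def _oracle_pairs(metas):
    """Independent re-application of the matching rules by brute force."""
    out = []
    for h in metas:
        if h.role != "holo":
            continue
        cands = []
        for a in metas:
            if a.role != "apo":
                continue
            ok = (h.space_group == a.space_group
                  and _sequences_match(h.sequence, a.sequence)
                  and abs(h.resolution - a.resolution) <= 0.1 + 1e-9
                  and all(abs(h.cell[i] - a.cell[i]) <= 1.0 + 1e-9
                          for i in range(3))
                  and all(abs(h.cell[i] - a.cell[i]) <= 1.0 + 1e-9
                          for i in range(3, 6)))
            if ok:
                cands.append(a)
        if cands:
            best = min(cands, key=lambda a: (abs(h.resolution - a.resolution),
                                             a.id))
            out.append((h.id, best.id))
    return out


def test_match_pairs_on_synthetic_metadata():
    metas = [
        _meta("holo1", "holo", res=1.50),
        _meta("apo_close", res=1.52),
        _meta("apo_far", res=1.58),
        _meta("apo_wrong_sg", sg="P 21", res=1.50),
        _meta("apo_big_dres", res=1.65),
        _meta("apo_trimmed", res=1.55, seq="SVLSVLS"),     # 2 trimmed: ok
    ]
    records = match_pairs(metas)
    assert [(r.holo_id, r.apo_id) for r in records] == _oracle_pairs(metas)
    assert len(records) == 1
    assert records[0].apo_id == "apo_close"     # smallest delta wins
    assert records[0].delta_resolution == pytest.approx(0.02)


def test_match_pairs_resolution_boundary():
    holo = _meta("h", "holo", res=1.50)
    assert not pair_eligible(holo, _meta("a", res=1.65))          # 0.15 out
    assert pair_eligible(holo, _meta("a", res=1.60))              # 0.10 in


def test_match_pairs_cell_rules():
    holo = _meta("h", "holo")
    assert not pair_eligible(holo, _meta("a", cell=(51.5, 60, 70, 90, 90, 90)))
    assert not pair_eligible(holo, _meta("a", cell=(50, 60, 70, 91.5, 90, 90)))
    assert pair_eligible(holo, _meta("a", cell=(50.9, 60, 70, 90.9, 90, 90)))


def test_sequence_trimming_semantics():
    assert _sequences_match("AAAAASVL", "SVL")          # 5 leading trimmed
    assert not _sequences_match("AAAAAASVL", "SVL")     # 6 needed: too many
    assert _sequences_match("SVLXX", "YSVL")            # both termini


def test_match_pairs_empty_input():
    assert match_pairs([]) == []


# ---------------------------------------------------------------------------
# Kabsch superposition

def _brute_force_rmsd(ref, mov, n_restarts=50, seed=0):
    """Numerical oracle: random-restart + local optimization over rotation
    vectors, independent of the closed-form superposition algebra."""
    from scipy.optimize import minimize
    rng = np.random.default_rng(seed)
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)

    def cost(rotvec):
        rot = Rotation.from_rotvec(rotvec)
        return np.mean(np.sum((rot.apply(mov_c) - ref_c) ** 2, axis=1))

    best = np.inf
    for _ in range(n_restarts):
        start = rng.normal(size=3) * np.pi
        res = minimize(cost, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        best = min(best, res.fun)
    return np.sqrt(best)


def test_kabsch_identity_and_translation():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(10, 3))
    _, _, rmsd = kabsch_superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    _, _, rmsd = kabsch_superpose(pts, pts + np.array([5.0, 0.0, 0.0]))
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_kabsch_rigid_transform_invariance():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(12, 3))
    rot = Rotation.random(rng=rng)
    moved = rot.apply(pts) + np.array([1.0, -2.0, 3.0])
    _, _, rmsd = kabsch_superpose(pts, moved)
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_kabsch_single_displaced_atom_vs_oracle():
    rng = np.random.default_rng(5)
    ref = rng.normal(size=(10, 3)) * 4.0
    mov = ref.copy()
    mov[0] += np.array([1.0, 0.0, 0.0])
    _, _, rmsd = kabsch_superpose(ref, mov)
    naive = np.sqrt(1.0 / 10.0)
    assert rmsd <= naive + 1e-12
    oracle = _brute_force_rmsd(ref, mov)
    assert rmsd <= oracle + 1e-6     # optimal fit beats any sampled rotation
    assert rmsd == pytest.approx(oracle, abs=1e-4)


def test_kabsch_rotation_is_proper():
    rng = np.random.default_rng(6)
    ref = rng.normal(size=(8, 3))
    mov = rng.normal(size=(8, 3))
    R, _, _ = kabsch_superpose(ref, mov)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_degenerate_inputs():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError):
        kabsch_superpose(line, line + 1.0)
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# QC filter

def test_qc_filter_pass_and_reasons():
    pair = PairRecord("h", "a", 0.02)
    apo = _meta("a", res=1.5, clashscore=5.0, r_free_initial=0.20,
                r_free_final=0.21)
    holo = _meta("h", "holo", res=1.52, clashscore=5.0, r_free_initial=0.20,
                 r_free_final=0.22, ligand_occupancy=0.9)
    out = qc_filter(pair, apo, holo)
    assert out.qc_status == "pass" and out.qc_reasons == []

    bad_holo = _meta("h", "holo", res=1.52, clashscore=20.0,
                     r_free_initial=0.20, r_free_final=0.26,
                     ligand_occupancy=0.10)
    bad_apo = _meta("a", res=1.5, clashscore=5.0, r_free_initial=0.20,
                    r_free_final=0.35)
    out = qc_filter(pair, bad_apo, bad_holo)
    assert out.qc_status == "fail"
    assert "clashscore:h" in out.qc_reasons
    assert "ligand_occupancy" in out.qc_reasons
    assert "rfree_gap" in out.qc_reasons
    assert "rfree_increase:h" in out.qc_reasons
    assert "rfree_increase:a" in out.qc_reasons


def test_qc_filter_rmsd_reason(synthetic_pair):
    apo, holo, _ = synthetic_pair
    pair = PairRecord(holo.id, apo.id, 0.0)
    meta_a = _meta("a")
    meta_h = _meta("h", "holo")
    out = qc_filter(pair, meta_a, meta_h, apo=apo, holo=holo)
    assert "global_rmsd" not in out.qc_reasons

    # displace every alpha carbon of a deep copy by 2 A
    import copy
    shifted = copy.deepcopy(apo)
    for res in shifted.residues:
        for conf in res.conformers:
            ca = conf.get_atom("CA")
            ca.xyz = ca.xyz + np.array([0.0, 2.0 * (res.seqnum % 2), 0.0])
    out = qc_filter(pair, meta_a, meta_h, apo=shifted, holo=holo)
    assert "global_rmsd" in out.qc_reasons
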