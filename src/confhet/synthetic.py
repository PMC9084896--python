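"""Synthetic multiconformer apo/holo pairs with fully known ground truth.

The generator emits matched apo/holo PDB pairs built from ideal-geometry
poly-Ser/Val/Leu chains in which every quantity the analysis pipeline
measures is planted analytically:

* Side chains are built by internal-coordinate placement so each
  conformer's chi1 equals its specification exactly; the Ca-Cb-gamma
  angle is the ideal tetrahedral value acos(-1/3), which makes any two
  chi1 wells 120 degrees apart subtend cos(theta) = -1/3.  For conformers
  occupying distinct wells the angular order parameter then has the
  closed form  s2_ang = (4 * sum q_i^2 - 1) / 3.

* B-factors are chosen so that the resolution normalization factor
  s2_ortho * B_CA / (c * resolution) is >= 1 and clips to exactly 1,
  hence s2_calc equals s2_ang and planted order-parameter deltas are
  exact.

* A 12-carbon ring ligand (code LIG) is placed near the first four
  residues of the holo chain only, defining the binding site; designated
  distant residues are enclosed in a shell of occluder pseudo-atoms
  (HETATM code CAG, an entry of the additive list) to plant the buried
  exposure class.

* Binding-site rigidification and distal flexibilization are planted as
  occupancy shifts between two chi1 wells; per-pair binding-site means
  are drawn antithetically around the cohort median so the planted
  cohort median is exact at finite n, and the distal means follow the
  generative residual slope plus noise.

Occupancies and B-factors are pre-quantized to the 0.01 precision of PDB
fixed-column fields, and all truth values are computed from the quantized
parameters, so pipeline recovery is exact to numerical precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .environment import fibonacci_sphere
from .metrics import CH_BOND_LENGTH, HARMONIC_K
from .stats import PairSummary
from .structure import (AtomRecord, Conformer, MultiConfResidue,
                        StructureModel, write_pdb)

TETRAHEDRAL = math.degrees(math.acos(-1.0 / 3.0))  # 109.4712...
CHAIN_SPACING = 3.8
SPACE_GROUP = "P 21 21 21"
CELL = (80.0, 80.0, 80.0, 90.0, 90.0, 90.0)

#: chi1 well centres (degrees) for wells p, t, m.
WELL_ANGLES = {"p": 60.0, "t": 180.0, "m": 300.0}

AA_CYCLE = ("SER", "VAL", "LEU")
_GAMMA = {"SER": ("OG", "O", 1.42), "VAL": ("CG1", "C", 1.52),
          "LEU": ("CG", "C", 1.52)}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of atom d bonded to c.

    Produces d with |cd| = bond, angle(b, c, d) = angle_deg and dihedral
    (a, b, c, d) = torsion_deg.
    """
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(theta),
                        bond * math.sin(theta) * math.cos(phi),
                        -bond * math.sin(theta) * math.sin(phi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class ResidueSpec:
    """Generative parameters of one residue."""

    aa: str
    chi1: tuple[float, ...]            # one angle per conformer, degrees
    occupancies: tuple[float, ...]     # quantized to 0.01, sum <= 1
    b_sidechain: float                 # A^2, shared by side-chain atoms
    b_calpha: float                    # A^2

    def __post_init__(self) -> None:
        if self.aa not in _GAMMA:
            raise ValueError(f"unsupported residue type {self.aa!r}")
        if len(self.chi1) != len(self.occupancies):
            raise ValueError("chi1 and occupancies length mismatch")
        if sum(self.occupancies) > 1.0 + 1e-6:
            raise ValueError("occupancies sum above 1")

    def s2_ang_true(self) -> float:
        """Closed-form angular order parameter (conformers in distinct
        120-degree-separated wells): (4 sum q^2 - 1) / 3 after occupancy
        renormalization."""
        q = np.asarray(self.occupancies, dtype=float)
        q = q / q.sum()
        return float((4.0 * np.sum(q * q) - 1.0) / 3.0)


def quantize(x: float, step: float = 0.01) -> float:
    return round(round(x / step) * step, 6)


def s2_for_two_wells(q1: float) -> float:
    """s2_ang of a two-conformer residue with occupancies (q1, 1 - q1)."""
    return 1.0 - (8.0 / 3.0) * q1 * (1.0 - q1)


def occupancy_for_s2(s2: float) -> float:
    """Major-well occupancy achieving a two-conformer s2_ang target."""
    if not (1.0 / 3.0 - 1e-9 <= s2 <= 1.0 + 1e-9):
        raise ValueError(f"two-well s2_ang target {s2:.4f} outside [1/3, 1]")
    disc = max(0.0, 1.0 - 1.5 * (1.0 - s2))
    return 0.5 * (1.0 + math.sqrt(disc))


def build_residue(spec: ResidueSpec, index: int, chain: str = "A"
                  ) -> MultiConfResidue:
    """Construct one residue at chain position ``index`` from its spec.

    Backbone atoms are blank-altloc and shared; each conformer carries its
    own side chain (Cb copy, gamma atoms, Cb hydrogens) built so the
    realized chi1 matches the spec exactly.
    """
    x0 = index * CHAIN_SPACING
    z_side = 1.0 if index % 2 == 0 else -1.0
    # slight zigzag keeps the alpha-carbon trace non-collinear
    ca = np.array([x0, 0.25 * z_side, 0.0])
    n = ca + 1.458 * _unit(np.array([-1.0, 1.1, 0.0]))
    c = ca + 1.525 * _unit(np.array([1.0, 1.1, 0.0]))
    o = c + 1.231 * _unit(np.array([0.4, 1.0, 0.3]))
    # tetrahedral Cb out of the backbone plane
    u_n = _unit(n - ca)
    u_c = _unit(c - ca)
    perp = _unit(np.cross(u_n, u_c)) * z_side
    bis = -_unit(u_n + u_c)
    cb = ca + 1.53 * _unit(bis * math.cos(math.radians(54.75))
                           + perp * math.sin(math.radians(54.75)))

    b_bb = spec.b_calpha

    def atom(name, element, xyz, occ, b, altloc=""):
        return AtomRecord(name=name, element=element, altloc=altloc,
                          occupancy=occ, b_iso=b, xyz=np.asarray(xyz))

    shared = [atom("N", "N", n, 1.0, b_bb),
              atom("CA", "C", ca, 1.0, b_bb),
              atom("C", "C", c, 1.0, b_bb),
              atom("O", "O", o, 1.0, b_bb)]

    multi = len(spec.chi1) > 1
    gamma_name, gamma_elem, gamma_bond = _GAMMA[spec.aa]
    conformers = []
    for ci, (chi, occ) in enumerate(zip(spec.chi1, spec.occupancies)):
        label = chr(ord("A") + ci) if multi else ""
        bsc = spec.b_sidechain
        own = [atom("CB", "C", cb, occ, bsc, label)]
        g1 = place_atom(n, ca, cb, gamma_bond, TETRAHEDRAL, chi)
        own.append(atom(gamma_name, gamma_elem, g1, occ, bsc, label))
        if spec.aa == "VAL":
            g2 = place_atom(n, ca, cb, 1.52, TETRAHEDRAL, chi + 120.0)
            own.append(atom("CG2", "C", g2, occ, bsc, label))
            hb = place_atom(n, ca, cb, CH_BOND_LENGTH, TETRAHEDRAL, chi - 120.0)
            own.append(atom("HB", "H", hb, occ, bsc, label))
        else:
            for hname, offset in (("HB2", 120.0), ("HB3", -120.0)):
                h = place_atom(n, ca, cb, CH_BOND_LENGTH, TETRAHEDRAL,
                               chi + offset)
                own.append(atom(hname, "H", h, occ, bsc, label))
        if spec.aa == "LEU":
            chi2 = 175.0
            cd1 = place_atom(ca, cb, g1, 1.52, TETRAHEDRAL, chi2)
            cd2 = place_atom(ca, cb, g1, 1.52, TETRAHEDRAL, chi2 + 120.0)
            own.append(atom("CD1", "C", cd1, occ, bsc, label))
            own.append(atom("CD2", "C", cd2, occ, bsc, label))
        if spec.aa == "SER":
            hg = place_atom(ca, cb, g1, 0.96, TETRAHEDRAL, 180.0)
            own.append(atom("HG", "H", hg, occ, bsc, label))
        conformers.append(Conformer(altloc=label, occupancy=occ,
                                    atoms=shared + own))
    return MultiConfResidue(chain=chain, seqnum=index + 1, icode="",
                            aa=spec.aa, conformers=conformers)


def _ring_ligand(center: np.ndarray, n_atoms: int = 12, radius: float = 2.2,
                 b: float = 20.0, occupancy: float = 1.0,
                 seqnum: int = 900) -> MultiConfResidue:
    atoms = []
    for i in range(n_atoms):
        ang = 2.0 * math.pi * i / n_atoms
        xyz = center + np.array([radius * math.cos(ang),
                                 radius * math.sin(ang), 0.0])
        atoms.append(AtomRecord(name=f"C{i + 1}", element="C", altloc="",
                                occupancy=occupancy, b_iso=b, xyz=xyz,
                                is_hetero=True))
    conf = Conformer(altloc="", occupancy=occupancy, atoms=atoms)
    return MultiConfResidue(chain="L", seqnum=seqnum, icode="", aa="LIG",
                            conformers=[conf])


def _occluder_shell(center: np.ndarray, seqnum: int,
                    b: float = 15.0) -> MultiConfResidue:
    """Double Fibonacci shell of carbon pseudo-atoms burying a residue."""
    pts = np.vstack([center + 4.6 * fibonacci_sphere(60),
                     center + 6.8 * fibonacci_sphere(150)])
    atoms = [AtomRecord(name=f"C{i + 1}", element="C", altloc="",
                        occupancy=1.0, b_iso=b, xyz=p, is_hetero=True)
             for i, p in enumerate(pts)]
    return MultiConfResidue(chain="X", seqnum=seqnum, icode="", aa="CAG",
                            conformers=[Conformer("", 1.0, atoms)])


@dataclass
class CohortSpec:
    """Study conditions of a synthetic apo/holo cohort."""

    n_pairs: int = 200
    n_residues: int = 26
    binding_site: tuple[int, ...] = (0, 1, 2, 3)        # chain indices
    caged: tuple[int, ...] = (8, 10, 12, 14, 16)        # buried distal
    #: residues actually buried by the shells (the shells also occlude the
    #: neighbours of their centres); the planted distal effect covers the
    #: whole block so the pipeline's buried set equals the planted set.
    distal_buried: tuple[int, ...] = tuple(range(6, 19))
    median_bs_delta: float = 0.03
    residual_slope: float = -0.44
    sigma_x: float = 0.10      # spread of per-pair binding-site means
    #: residual noise around the generative slope; with sigma_x = 0.1 and
    #: slope -0.44 this reproduces the observed scatter (r^2 ~ 0.46)
    sigma_r: float = 0.048
    sigma_res: float = 0.005   # per-residue scatter within a pair
    preorganized_fraction: float = 0.11
    resolutions: tuple[float, ...] = (1.2, 1.4, 1.6, 1.8, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if min(self.sigma_x, self.sigma_r, self.sigma_res) < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass
class SyntheticTruth:
    """Planted parameters and their analytic consequences for one pair."""

    pair_id: str
    x_bs: float                 # realized mean binding-site delta s2
    residual: float             # realized distal-buried mean minus x_bs
    residues: pd.DataFrame      # per-residue truth rows


# per-residue rotamer-change patterns: (apo wells, holo wells, category)
_CATEGORY_PATTERNS = {
    "distinct": (("p", "t"), ("m",), 0.97),
    "remodeled_holo_loss": (("p", "t"), ("p",), 0.97),
    "remodeled_holo_gain": (("p",), ("p", "t"), 0.97),
}


def _sidechain_b_and_bca(rng: np.random.Generator, resolution: float
                         ) -> tuple[float, float]:
    """Side-chain B and an alpha-carbon B making the normalization clip at 1."""
    b_sc = quantize(rng.uniform(8.0, 14.0))
    s2o = 1.0 - HARMONIC_K * (2.0 * b_sc) / CH_BOND_LENGTH ** 2
    b_ca = math.ceil((10.0 * resolution / s2o + 0.01) * 100.0) / 100.0
    return b_sc, b_ca


def _antithetic_normal(rng: np.random.Generator, n: int, center: float,
                       sigma: float) -> np.ndarray:
    """Normal draws mirrored around ``center`` so the sample median is exact
    for even n (the generator pads odd n with one draw at the center)."""
    half = rng.normal(0.0, sigma, size=n // 2)
    vals = np.concatenate([center + half, center - half])
    if n % 2 == 1:
        vals = np.append(vals, center)
    rng.shuffle(vals)
    return vals


def _centered(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    e = rng.normal(0.0, sigma, size=n)
    return e - e.mean()


def build_pair(spec: CohortSpec, pair_index: int, x_bs: float, residual: float,
               rng: np.random.Generator
               ) -> tuple[StructureModel, StructureModel, SyntheticTruth]:
    """One apo/holo pair with planted binding-site and distal effects.

    ``x_bs`` is the target mean binding-site delta-s2 and ``residual`` the
    target (distal-buried mean - binding-site mean); realized values after
    occupancy quantization are reported in the returned truth.
    """
    pair_id = f"pair{pair_index:04d}"
    resolution = float(rng.choice(spec.resolutions))
    n_res = spec.n_residues
    bs = list(spec.binding_site)
    caged = [i for i in spec.caged if i < n_res]
    buried = [i for i in spec.distal_buried if i < n_res]

    # per-residue categories in the binding site
    preorganized = rng.random() < spec.preorganized_fraction
    categories = {i: "no_change" for i in range(n_res)}
    if not preorganized:
        # exactly one remodeled residue per non-preorganized site keeps the
        # cohort-wide changed fraction near the observed ~1-in-5
        changed = int(rng.choice(bs))
        weights = np.array([0.155, 0.026, 0.038])
        names = ["distinct", "remodeled_holo_loss", "remodeled_holo_gain"]
        categories[changed] = names[rng.choice(3, p=weights / weights.sum())]

    # fixed deltas of category-changed residues (quantized occupancies)
    fixed_delta = {}
    for i in bs:
        cat = categories[i]
        if cat == "no_change":
            continue
        _, _, q_major = _CATEGORY_PATTERNS[cat]
        s2_two = s2_for_two_wells(q_major)
        fixed_delta[i] = (1.0 - s2_two) if cat != "remodeled_holo_gain" \
            else (s2_two - 1.0)

    # remaining binding-site residues absorb the pair-level target
    free_bs = [i for i in bs if i not in fixed_delta]
    target_sum = len(bs) * x_bs - sum(fixed_delta.values())
    if free_bs:
        eps = _centered(rng, len(free_bs), spec.sigma_res)
        free_deltas = {i: target_sum / len(free_bs) + e
                       for i, e in zip(free_bs, eps)}
    elif abs(target_sum) > 0.25:
        raise ValueError("infeasible binding-site effect: no free residues")
    else:
        free_deltas = {}

    distal_mean = x_bs + residual
    eps_d = _centered(rng, len(buried), spec.sigma_res)
    distal_deltas = {i: distal_mean + e for i, e in zip(buried, eps_d)}

    def two_well_specs(aa, s2_apo, s2_holo, b_sc, b_ca):
        """Quantized apo/holo residue specs for a no-change two-well residue."""
        qa = quantize(occupancy_for_s2(s2_apo))
        qh = quantize(occupancy_for_s2(s2_holo))
        qa = min(max(qa, 0.51), 0.99)
        qh = min(max(qh, 0.51), 0.99)
        apo = ResidueSpec(aa, (WELL_ANGLES["p"], WELL_ANGLES["t"]),
                          (qa, round(1.0 - qa, 6)), b_sc, b_ca)
        holo = ResidueSpec(aa, (WELL_ANGLES["p"], WELL_ANGLES["t"]),
                           (qh, round(1.0 - qh, 6)), b_sc, b_ca)
        return apo, holo

    apo_residues, holo_residues, truth_rows = [], [], []
    for i in range(n_res):
        aa = AA_CYCLE[i % len(AA_CYCLE)]
        b_sc, b_ca = _sidechain_b_and_bca(rng, resolution)
        cat = categories[i]
        if i in bs and cat != "no_change":
            apo_wells, holo_wells, q_major = _CATEGORY_PATTERNS[cat]
            qm = quantize(q_major)

            def spec_for(wells):
                if len(wells) == 1:
                    return ResidueSpec(aa, (WELL_ANGLES[wells[0]],), (1.0,),
                                       b_sc, b_ca)
                return ResidueSpec(
                    aa, tuple(WELL_ANGLES[w] for w in wells),
                    (qm, round(1.0 - qm, 6)), b_sc, b_ca)

            spec_a, spec_h = spec_for(apo_wells), spec_for(holo_wells)
        else:
            delta = free_deltas.get(i, distal_deltas.get(i, 0.0))
            lo, hi = 1.0 / 3.0 + 0.01, 0.995
            lo_a, hi_a = lo + max(0.0, -delta), hi - max(0.0, delta)
            if lo_a > hi_a:
                raise ValueError(
                    f"infeasible planted effect at residue {i}: shift "
                    f"{delta:.3f} exceeds the two-well s2_ang range")
            # centre the shift inside the feasible window
            s2_apo = float(np.clip(0.67 - delta / 2.0
                                   + rng.uniform(-0.05, 0.05), lo_a, hi_a))
            s2_holo = s2_apo + delta
            spec_a, spec_h = two_well_specs(aa, s2_apo, s2_holo, b_sc, b_ca)
            if delta == 0.0:
                spec_h = spec_a  # exact zero delta for unaffected residues

        apo_residues.append(build_residue(spec_a, i))
        holo_residues.append(build_residue(spec_h, i))
        region = ("binding_site" if i in bs
                  else "distant_buried" if i in buried else "bulk")
        truth_rows.append({
            "pair_id": pair_id, "chain": "A", "seqnum": i + 1, "aa": aa,
            "region": region, "category": cat if i in bs else "no_change",
            "s2_ang_apo": spec_a.s2_ang_true(),
            "s2_ang_holo": spec_h.s2_ang_true(),
            "delta_s2": spec_h.s2_ang_true() - spec_a.s2_ang_true(),
            "n_conf_apo": len(spec_a.chi1), "n_conf_holo": len(spec_h.chi1),
            "buried": i in buried,
        })

    truth = pd.DataFrame(truth_rows)
    bs_mask = truth["region"] == "binding_site"
    db_mask = truth["region"] == "distant_buried"
    x_real = float(truth.loc[bs_mask, "delta_s2"].mean())
    resid_real = float(truth.loc[db_mask, "delta_s2"].mean()) - x_real

    lig_center = np.array([(len(bs) - 1) * CHAIN_SPACING / 2.0, 5.0, 0.0])
    ligand = _ring_ligand(lig_center, occupancy=1.0, b=20.0)
    shells = []
    for k, i in enumerate(caged):
        res = holo_residues[i]
        heavy = np.asarray([a.xyz for a in res.heavy_atoms])
        shells.append(_occluder_shell(heavy.mean(axis=0), seqnum=950 + k))

    common = dict(space_group=SPACE_GROUP, cell=CELL, resolution=resolution)
    apo = StructureModel(id=f"{pair_id}_apo", residues=apo_residues,
                         ligands=list(shells), **common)
    holo = StructureModel(id=f"{pair_id}_holo", residues=holo_residues,
                          ligands=[ligand] + list(shells), **common)
    return apo, holo, SyntheticTruth(pair_id=pair_id, x_bs=x_real,
                                     residual=resid_real, residues=truth)


def draw_pair_effects(spec: CohortSpec, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair binding-site means and residuals under the generative model.

    The residual noise is projected orthogonal to the binding-site means,
    so the planted slope is exact in the realized cohort (not only in
    expectation), matching the exact-median antithetic draw of the means.
    """
    x = _antithetic_normal(rng, spec.n_pairs, spec.median_bs_delta,
                           spec.sigma_x)
    eta = rng.normal(0.0, spec.sigma_r, size=spec.n_pairs)
    if spec.n_pairs >= 3 and np.ptp(x) > 1e-12 and spec.sigma_r > 0:
        xc = x - x.mean()
        eta = eta - (eta @ xc) / (xc @ xc) * xc
    resid = spec.residual_slope * x + eta
    return x, resid


def build_cohort(spec: CohortSpec, out_dir: str | Path
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a full synthetic cohort: PDB pairs, metadata and truth tables.

    Returns (metadata table, per-residue truth table); deterministic under
    ``spec.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    xs, resids = draw_pair_effects(spec, rng)
    meta_rows, truth_frames, pair_rows = [], [], []
    sequence = "".join({"SER": "S", "VAL": "V", "LEU": "L"}[
        AA_CYCLE[i % len(AA_CYCLE)]] for i in range(spec.n_residues))
    for p in range(spec.n_pairs):
        apo, holo, truth = build_pair(spec, p, float(xs[p]), float(resids[p]),
                                      rng)
        write_pdb(apo, out / f"{apo.id}.pdb")
        write_pdb(holo, out / f"{holo.id}.pdb")
        for model, role in ((apo, "apo"), (holo, "holo")):
            meta_rows.append({
                "id": model.id, "role": role, "space_group": SPACE_GROUP,
                "a": CELL[0], "b": CELL[1], "c": CELL[2], "alpha": CELL[3],
                "beta": CELL[4], "gamma": CELL[5],
                "resolution": model.resolution, "sequence": sequence,
                "ligand_id": "LIG" if role == "holo" else "",
                "ligand_occupancy": 1.0 if role == "holo" else "",
                "r_free_initial": 0.20, "r_free_final": 0.21,
                "clashscore": 5.0,
            })
        truth_frames.append(truth.residues)
        pair_rows.append({"pair_id": truth.pair_id, "x_bs": truth.x_bs,
                          "residual": truth.residual,
                          "resolution": holo.resolution})
    meta = pd.DataFrame(meta_rows)
    truth_res = pd.concat(truth_frames, ignore_index=True)
    pairs = pd.DataFrame(pair_rows)
    meta.to_csv(out / "metadata.csv", index=False)
    truth_res.to_csv(out / "truth_residues.csv", index=False)
    pairs.to_csv(out / "truth_pairs.csv", index=False)
    return meta, truth_res


def simulate_pair_summaries(n_pairs: int, median_bs_delta: float,
                            residual_slope: float, sigma_x: float = 0.10,
                            sigma_r: float = 0.048,
                            seed: Optional[int] = None) -> list[PairSummary]:
    """Summary-level draw from the generative model (no structures built)."""
    spec = CohortSpec(n_pairs=n_pairs, median_bs_delta=median_bs_delta,
                      residual_slope=residual_slope, sigma_x=sigma_x,
                      sigma_r=sigma_r, seed=seed or 0)
    rng = np.random.default_rng(seed)
    xs, resids = draw_pair_effects(spec, rng)
    return [PairSummary(pair_id=f"sim{i:04d}", mean_delta_s2_bs=float(x),
                        mean_delta_s2_distant_buried=float(x + r))
            for i, (x, r) in enumerate(zip(xs, resids))]


def make_calibration_series(n_residues: int = 200, true_c: float = 10.0,
                            noise_sd: float = 0.01,
                            res_low: float = 2.0, res_high: float = 1.2,
                            seed: Optional[int] = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Matched multi-resolution harmonic order-parameter series.

    Each residue has a resolution-independent normalized value S_i; the
    raw harmonic component observed at resolution ``res`` is
    S_i * true_c * res / B_CA (inverting the normalization), so the
    correct constant recovers S_i in both series up to additive noise.
    Returns (series_low, series_high) as (n, 3) arrays of
    (s2_ortho_raw, b_calpha, resolution).
    """
    rng = np.random.default_rng(seed)
    s_true = rng.uniform(0.40, 0.98, size=n_residues)
    # high-resolution reference: B-factors reliable, values on the true scale
    raw_high = np.clip(s_true + rng.normal(0.0, noise_sd, size=n_residues),
                       0.0, 1.0)
    b_ca_high = rng.uniform(8.0, 20.0, size=n_residues)
    series_high = np.column_stack([raw_high, b_ca_high,
                                   np.full(n_residues, res_high)])
    # low-resolution series: raw values depressed by inflated B-factors,
    # recoverable through the normalization at the true constant
    u = rng.uniform(0.50, 0.95, size=n_residues)   # raw values observed
    b_ca_low = true_c * res_low * s_true / u
    raw_low = np.clip(u + rng.normal(0.0, noise_sd, size=n_residues),
                      0.0, 1.0)
    series_low = np.column_stack([raw_low, b_ca_low,
                                  np.full(n_residues, res_low)])
    return series_low, series_high
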