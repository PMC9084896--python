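"""Per-residue conformational-heterogeneity metrics.

The central quantity is a crystallographic side-chain order parameter
S2 in [0, 1] (1 = fully rigid) factored into two components:

* ``s2_ang`` — an angular (anharmonic) component computed from the
  occupancy-weighted orientations of the chi1-defining Cbeta->gamma bond
  vectors of the alternative conformers, via the second-rank orientational
  tensor  S2 = (3/2) sum_ab M_ab^2 - 1/2  with  M_ab = sum_i q_i u_ia u_ib.
  For two conformers this reduces to 1 - 3 q1 q2 sin^2(theta).

* ``s2_ortho`` — a harmonic component from the isotropic B-factors of the
  Cbeta carbon and its attached hydrogen(s), modelling small-amplitude
  wobble of the bond:  S2 = 1 - k (B_heavy + B_H) / r^2  with
  k = 3/(16 pi^2) and r the C-H bond length.

Because absolute B-factors inflate as resolution degrades, ``s2_ortho``
is rescaled by the residue's alpha-carbon B-factor relative to the
resolution:  s2_ortho_norm = s2_ortho * B_CA / (c * resolution), with the
constant c calibrated on same-protein structures spanning a resolution
range (default c = 10).  The combined order parameter is

    s2_calc = s2_ortho_norm * s2_ang

All S2 values are clipped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._tables import GAMMA_ATOM, NO_S2_RESIDUES
from .structure import MultiConfResidue, StructureModel

#: Harmonic small-wobble prefactor 3/(16 pi^2).
HARMONIC_K = 3.0 / (16.0 * math.pi ** 2)

#: C-H bond length used in the harmonic model (Angstrom).
CH_BOND_LENGTH = 1.09

#: Riding-hydrogen B-factor convention when explicit H is absent.
RIDING_H_FACTOR = 1.2


@dataclass
class NormalizationConfig:
    """Resolution normalization of the harmonic component.

    ``c`` is the denominator constant in B_CA / (c * resolution);
    ``mode`` selects a per-residue or structure-mean alpha-carbon
    B-factor; ``clip`` bounds the result to [0, 1].
    """

    c: float = 10.0
    mode: str = "per_residue_calpha"  # or "structure_mean_calpha"
    clip: bool = True

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("normalization constant c must be positive")
        if self.mode not in ("per_residue_calpha", "structure_mean_calpha"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")


@dataclass
class ResidueMetrics:
    """Heterogeneity metrics for one residue (NaN = not computable)."""

    chain: str
    seqnum: int
    icode: str
    aa: str
    n_conformers: int
    s2_ang: float = float("nan")
    s2_ortho: float = float("nan")
    s2_ortho_norm: float = float("nan")
    s2_calc: float = float("nan")
    rmsf: float = float("nan")
    mean_b_sidechain: float = float("nan")
    mean_b_calpha: float = float("nan")
    computable: bool = False


def s2_angular(bond_vectors: Sequence[np.ndarray],
               occupancies: Sequence[float]) -> float:
    """Angular order parameter of a set of bond orientations.

    Occupancies are renormalised to sum to one.  Returns 1 for a single
    orientation; the minimum 0.25 occurs for a fully isotropic planar
    degenerate case.
    """
    vecs = np.asarray(bond_vectors, dtype=float)
    if vecs.ndim != 2 or vecs.shape[0] < 1 or vecs.shape[1] != 3:
        raise ValueError("bond_vectors must be a non-empty list of 3-vectors")
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length bond vector")
    u = vecs / norms[:, None]
    q = np.asarray(occupancies, dtype=float)
    if q.shape[0] != u.shape[0]:
        raise ValueError("occupancies and vectors length mismatch")
    if q.sum() <= 0:
        raise ValueError("occupancies sum to zero")
    q = q / q.sum()
    m = np.einsum("i,ia,ib->ab", q, u, u)
    return float(1.5 * np.sum(m * m) - 0.5)


def s2_ortho(b_heavy: float, b_hydrogen: float,
             r: float = CH_BOND_LENGTH, k: float = HARMONIC_K) -> float:
    """Harmonic order parameter from heavy-atom and hydrogen B-factors."""
    if r <= 0:
        raise ValueError("bond length must be positive")
    if b_heavy < 0 or b_hydrogen < 0:
        raise ValueError("B-factors must be non-negative")
    return float(np.clip(1.0 - k * (b_heavy + b_hydrogen) / (r * r), 0.0, 1.0))


def normalize_s2_ortho(s2o: float, b_calpha: float, resolution: float,
                       cfg: Optional[NormalizationConfig] = None) -> float:
    """Rescale the harmonic component by B_CA / (c * resolution)."""
    cfg = cfg or NormalizationConfig()
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if b_calpha < 0:
        raise ValueError("b_calpha must be non-negative")
    value = s2o * b_calpha / (cfg.c * resolution)
    if cfg.clip:
        value = float(np.clip(value, 0.0, 1.0))
    return float(value)


def calibrate_normalization(series_low: np.ndarray, series_high: np.ndarray,
                            c_grid: Sequence[float],
                            normalize_reference: bool = False
                            ) -> tuple[float, pd.DataFrame]:
    """Select the normalization constant from matched multi-resolution data.

    ``series_low`` and ``series_high`` are (n, 3) arrays of
    (s2_ortho_raw, b_calpha, resolution) for the same residues observed in
    a lower- and a higher-resolution structure of the same protein.  For
    every candidate c the lower-resolution series is normalised (with
    clipping) and the higher-resolution reference values are regressed on
    it; candidates are ranked lexicographically by (|slope - 1|, RMSE),
    ties broken by smallest c.

    By default the high-resolution series serves as the reference scale
    and is used raw: its B-factors are taken as reliable, so a correct
    constant maps the low-resolution values onto it with unit slope.
    (Normalising both series with the same candidate, available via
    ``normalize_reference=True``, leaves the OLS slope invariant to c and
    cannot identify the constant; it is kept only for diagnostics.)

    Returns the winning c and the per-candidate score table.
    """
    lo = np.asarray(series_low, dtype=float)
    hi = np.asarray(series_high, dtype=float)
    if lo.shape != hi.shape or lo.ndim != 2 or lo.shape[1] != 3 or lo.shape[0] < 3:
        raise ValueError("series must be matched (n, 3) arrays with n >= 3")
    rows = []
    for c in c_grid:
        x_raw = lo[:, 0] * lo[:, 1] / (c * lo[:, 2])
        y = hi[:, 0]
        if normalize_reference:
            y = np.clip(hi[:, 0] * hi[:, 1] / (c * hi[:, 2]), 0.0, 1.0)
        # saturated values carry no scale information: drop clipped points
        keep = x_raw < 1.0
        x, y = np.clip(x_raw[keep], 0.0, 1.0), np.asarray(y)[keep]
        if keep.sum() < 3 or np.ptp(x) < 1e-12:
            # candidate saturates the clip: not a usable normalization
            rows.append({"c": float(c), "slope": float("nan"),
                         "rmse": float("inf")})
            continue
        fit = sps.linregress(x, y)
        resid = y - (fit.intercept + fit.slope * x)
        rows.append({"c": float(c), "slope": float(fit.slope),
                     "rmse": float(np.sqrt(np.mean(resid ** 2)))})
    table = pd.DataFrame(rows)
    if table["slope"].isna().all():
        raise ValueError("degenerate series: zero variance after "
                         "normalization for every candidate c")
    order = table.assign(score=np.abs(table["slope"] - 1.0)).sort_values(
        ["score", "rmse", "c"], kind="mergesort")
    return float(order.iloc[0]["c"]), table


def _chi1_vectors(residue: MultiConfResidue
                  ) -> tuple[list[np.ndarray], list[float]]:
    """Cbeta->gamma bond vector and occupancy per conformer."""
    gamma_name = GAMMA_ATOM.get(residue.aa)
    vecs, occs = [], []
    for conf in residue.conformers:
        cb = conf.get_atom("CB")
        gamma = conf.get_atom(gamma_name) if gamma_name else None
        if cb is None or gamma is None:
            continue
        vecs.append(gamma.xyz - cb.xyz)
        occs.append(conf.occupancy)
    return vecs, occs


def _cbeta_hydrogen_b(residue: MultiConfResidue) -> tuple[float, float]:
    """Occupancy-weighted (B_Cbeta, B_H) over conformers.

    Hydrogens attached to Cbeta are used when present; otherwise the
    riding-hydrogen convention B_H = 1.2 * B_Cbeta applies.
    """
    num_cb, num_h, wsum = 0.0, 0.0, 0.0
    for conf in residue.conformers:
        cb = conf.get_atom("CB")
        if cb is None:
            continue
        hb = [a for a in conf.atoms
              if a.is_hydrogen and np.linalg.norm(a.xyz - cb.xyz) < 1.3]
        b_h = float(np.mean([a.b_iso for a in hb])) if hb \
            else RIDING_H_FACTOR * cb.b_iso
        q = conf.occupancy
        num_cb += q * cb.b_iso
        num_h += q * b_h
        wsum += q
    if wsum == 0:
        raise ValueError(f"residue {residue.key} has no Cbeta")
    return num_cb / wsum, num_h / wsum


def residue_bfactor(residue: MultiConfResidue, scope: str = "sidechain") -> float:
    """Occupancy-weighted mean heavy-atom B-factor over the given scope."""
    if scope not in ("sidechain", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    num, wsum = 0.0, 0.0
    for conf in residue.conformers:
        atoms = [a for a in conf.atoms if not a.is_hydrogen]
        if scope == "sidechain":
            atoms = [a for a in atoms if not a.is_mainchain]
        if not atoms:
            continue
        q = conf.occupancy
        num += q * float(np.mean([a.b_iso for a in atoms]))
        wsum += q
    if wsum == 0:
        return float("nan")
    return num / wsum


def calpha_bfactor(residue: MultiConfResidue) -> float:
    """Occupancy-weighted alpha-carbon B-factor."""
    num, wsum = 0.0, 0.0
    for conf in residue.conformers:
        ca = conf.get_atom("CA")
        if ca is None:
            continue
        num += conf.occupancy * ca.b_iso
        wsum += conf.occupancy
    return num / wsum if wsum > 0 else float("nan")


def side_chain_rmsf(residue: MultiConfResidue) -> float:
    """Occupancy-weighted RMSF of side-chain heavy-atom conformer centroids."""
    centroids, occs = [], []
    for conf in residue.conformers:
        sc = [a for a in conf.atoms
              if not a.is_hydrogen and not a.is_mainchain]
        if not sc:
            continue
        centroids.append(np.mean([a.xyz for a in sc], axis=0))
        occs.append(conf.occupancy)
    if not centroids:
        return float("nan")
    c = np.asarray(centroids)
    q = np.asarray(occs) / np.sum(occs)
    cbar = np.einsum("i,ij->j", q, c)
    d2 = np.sum((c - cbar) ** 2, axis=1)
    return float(np.sqrt(np.dot(q, d2)))


def conformer_count(residue: MultiConfResidue) -> int:
    """Number of distinct side-chain alternative conformations (>= 1).

    A residue counts as multiconformer if at least one side-chain atom
    carries an altloc label; backbone-only altlocs do not count.
    """
    labels = residue.sidechain_altlocs()
    return max(1, len(labels))


def s2_calc(residue: MultiConfResidue, resolution: float,
            cfg: Optional[NormalizationConfig] = None,
            structure_mean_b_calpha: Optional[float] = None) -> ResidueMetrics:
    """All order-parameter components for one residue.

    Gly and Pro are excluded (no rotatable chi1 in this framework) and are
    returned with ``computable=False``.  Ala has no gamma atom; its single
    Cbeta orientation gives ``s2_ang = 1`` by convention.
    """
    cfg = cfg or NormalizationConfig()
    out = ResidueMetrics(
        chain=residue.chain, seqnum=residue.seqnum, icode=residue.icode,
        aa=residue.aa, n_conformers=conformer_count(residue),
        rmsf=side_chain_rmsf(residue),
        mean_b_sidechain=residue_bfactor(residue, "sidechain"),
        mean_b_calpha=calpha_bfactor(residue),
    )
    if residue.aa in NO_S2_RESIDUES:
        return out
    if residue.aa == "ALA":
        ang = 1.0
    else:
        vecs, occs = _chi1_vectors(residue)
        if not vecs:
            return out  # missing chi1 atoms: flagged, not raised
        ang = s2_angular(vecs, occs)
    try:
        b_cb, b_h = _cbeta_hydrogen_b(residue)
    except ValueError:
        return out
    ortho = s2_ortho(b_cb, b_h)
    b_ca = (structure_mean_b_calpha
            if cfg.mode == "structure_mean_calpha"
            and structure_mean_b_calpha is not None
            else out.mean_b_calpha)
    if not np.isfinite(b_ca):
        return out
    out.s2_ang = float(np.clip(ang, 0.0, 1.0))
    out.s2_ortho = ortho
    out.s2_ortho_norm = normalize_s2_ortho(ortho, b_ca, resolution, cfg)
    out.s2_calc = float(np.clip(out.s2_ortho_norm * out.s2_ang, 0.0, 1.0))
    out.computable = True
    return out


def structure_metrics(model: StructureModel,
                      cfg: Optional[NormalizationConfig] = None
                      ) -> pd.DataFrame:
    """Per-residue metrics table for one structure."""
    cfg = cfg or NormalizationConfig()
    model.validate()
    mean_bca = float(np.nanmean(
        [calpha_bfactor(r) for r in model.residues])) if model.residues else float("nan")
    rows = []
    for res in model.residues:
        m = s2_calc(res, model.resolution, cfg,
                    structure_mean_b_calpha=mean_bca)
        rows.append({
            "structure_id": model.id, "chain": m.chain, "seqnum": m.seqnum,
            "icode": m.icode, "aa": m.aa, "n_conformers": m.n_conformers,
            "s2_ang": m.s2_ang, "s2_ortho": m.s2_ortho,
            "s2_ortho_norm": m.s2_ortho_norm, "s2_calc": m.s2_calc,
            "rmsf": m.rmsf, "mean_b_sidechain": m.mean_b_sidechain,
            "mean_b_calpha": m.mean_b_calpha, "computable": m.computable,
        })
    return pd.DataFrame(rows)
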