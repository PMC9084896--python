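"""End-to-end orchestration: per-pair analysis and cohort aggregation."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import environment as env
from . import hbonds, ligands, metrics, pairs, rotamers, stats
from .structure import StructureModel, read_pdb

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds of the analysis, all in the units noted."""

    binding_site_cutoff: float = 5.0     # A
    distant_cutoff: float = 10.0         # A
    exposure_threshold: float = 0.20     # RASA fraction
    hbond_distance_cutoff: float = 3.2   # A, H...acceptor
    hbond_min_angle: float = 90.0        # degrees, D-H...A
    min_ligand_heavy: int = 10
    min_ligand_occupancy: float = 0.15
    bonferroni_m: int = 10
    sasa_points: int = 960
    normalization: metrics.NormalizationConfig = field(
        default_factory=metrics.NormalizationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("binding_site_cutoff", "distant_cutoff",
                     "hbond_distance_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("exposure_threshold", "min_ligand_occupancy"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must be in (0, 1)")


def run_pair(apo: StructureModel | str, holo: StructureModel | str,
             config: Optional[PipelineConfig] = None,
             out_dir: Optional[str | Path] = None) -> dict:
    """Analyse one matched apo/holo pair.

    Returns a dict of tables: residue metrics for both structures, the
    holo environment table, per-residue deltas with rotamer categories,
    and a small hydrogen-bond/ligand summary.  Refuses an apo structure
    that itself contains a qualifying ligand.
    """
    cfg = config or PipelineConfig()
    if isinstance(apo, (str, Path)):
        apo = read_pdb(apo)
    if isinstance(holo, (str, Path)):
        holo = read_pdb(holo)
    if pairs.classify_role(apo, min_heavy=cfg.min_ligand_heavy) == "holo":
        raise ValueError(f"{apo.id}: apo structure contains a qualifying "
                         "ligand; roles are inverted or misassigned")
    ligand = pairs.select_ligand(holo, min_heavy=cfg.min_ligand_heavy)
    if ligand is None:
        raise ValueError(f"{holo.id}: no qualifying ligand found in holo")

    m_apo = metrics.structure_metrics(apo, cfg.normalization)
    m_holo = metrics.structure_metrics(holo, cfg.normalization)
    env_table = env.environment_table(
        holo, ligand, cfg.binding_site_cutoff, cfg.distant_cutoff,
        cfg.exposure_threshold, n_points=cfg.sasa_points)

    cats = []
    keys = ["chain", "seqnum", "icode"]
    for res_h in holo.residues:
        res_a = apo.get_residue(res_h.key)
        if res_a is None:
            continue
        set_a = rotamers.residue_rotamer_set(res_a)
        set_h = rotamers.residue_rotamer_set(res_h)
        if not set_a or not set_h:
            continue
        cats.append({"chain": res_h.chain, "seqnum": res_h.seqnum,
                     "icode": res_h.icode,
                     "rotamer_category":
                         rotamers.classify_pair_rotamers(set_a, set_h).value})
    cat_table = pd.DataFrame(cats)

    pair_id = f"{holo.id}__{apo.id}"
    deltas = stats.pair_residue_deltas(m_apo, m_holo, env_table,
                                       cat_table if cats else None,
                                       pair_id=pair_id)

    bs_keys = set(env_table.loc[env_table["is_binding_site"],
                                keys].itertuples(index=False, name=None))
    summary = {
        "pair_id": pair_id,
        "ligand_id": ligand.aa,
        "ligand_occupancy": ligands.ligand_occupancy(ligand),
        "ligand_occupancy_class": ligands.ligand_occupancy_class(ligand),
        "ligand_b_norm": ligands.ligand_b_norm(ligand, holo),
        "n_binding_site": len(bs_keys),
    }
    if bs_keys:
        for name, model in (("holo", holo), ("apo", apo)):
            try:
                summary[f"hbonds_per_bs_residue_{name}"] = \
                    hbonds.weighted_hbond_count(
                        model, bs_keys, cfg.hbond_distance_cutoff,
                        cfg.hbond_min_angle)
            except ValueError:
                summary[f"hbonds_per_bs_residue_{name}"] = float("nan")

    out = {"metrics_apo": m_apo, "metrics_holo": m_holo,
           "environment": env_table, "deltas": deltas,
           "rotamer_categories": cat_table, "summary": summary}
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        for name in ("metrics_apo", "metrics_holo", "environment", "deltas",
                     "rotamer_categories"):
            out[name].to_csv(d / f"{pair_id}_{name}.csv", index=False)
        (d / f"{pair_id}_summary.json").write_text(
            json.dumps(summary, indent=2))
    return out


def run_cohort(delta_tables: Sequence[pd.DataFrame],
               config: Optional[PipelineConfig] = None,
               control_draws: int = 100) -> dict:
    """Aggregate per-pair delta tables into cohort statistics.

    Computes the per-pair binding-site means and residuals, the residual
    regression, paired tests, the matched-control comparison, and category
    summaries.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    if not delta_tables:
        raise ValueError("no per-pair delta tables supplied")
    summaries, control_means, bs_means = [], [], []
    for table in delta_tables:
        if table.empty:
            continue
        s = stats.summarize_pair(table)
        summaries.append(s)
        bs_means.append(s.mean_delta_s2_bs)
        try:
            control_means.append(
                stats.matched_control_delta(table, rng, control_draws)[0])
        except ValueError:
            control_means.append(float("nan"))
    slope, r2, p_slope = stats.residual_regression(summaries)
    all_deltas = pd.concat(delta_tables, ignore_index=True)
    w_stat, w_p = stats.paired_test(
        [b for b in bs_means if np.isfinite(b)])
    out = {
        "n_pairs": len(summaries),
        "median_bs_delta_s2": float(np.nanmedian(bs_means)),
        "median_control_delta_s2": float(np.nanmedian(control_means)),
        "residual_slope": slope,
        "residual_r2": r2,
        "residual_slope_p": p_slope,
        "bs_delta_wilcoxon_stat": w_stat,
        "bs_delta_wilcoxon_p": w_p,
        "categories": stats.summarize_categories(all_deltas),
        "pair_summaries": summaries,
    }
    return out


def match_and_qc(meta_path: str, qc: Optional[pairs.QCConfig] = None
                 ) -> pd.DataFrame:
    """Match apo/holo pairs from a metadata table and apply table-level QC."""
    metas = pairs.read_meta_table(meta_path)
    by_id = {m.id: m for m in metas}
    records = pairs.match_pairs(metas)
    out = [pairs.qc_filter(r, by_id[r.apo_id], by_id[r.holo_id],
                           thresholds=qc) for r in records]
    return pairs.pairs_to_frame(out)
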