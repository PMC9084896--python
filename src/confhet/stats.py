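"""Pair-level and cohort-level comparative statistics.

All differences follow the holo-minus-apo sign convention.  The central
cohort quantities are, per pair, the mean order-parameter change in
binding-site residues and the *residual* — the mean change in distant
buried residues minus the mean change in the binding site — which is
regressed on the binding-site change across the cohort.  Supporting
procedures: matched controls drawn by residue type and exposure class,
bootstrap comparison of regression slopes between two cohorts, paired
Wilcoxon and Mann-Whitney tests, Bonferroni-corrected quartile contrasts
of ligand descriptors, and hierarchical clustering of the residue-by-pair
delta matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

DELTA_COLUMNS = ["pair_id", "chain", "seqnum", "icode", "aa",
                 "delta_s2", "delta_b", "delta_rmsf", "delta_nconf",
                 "rotamer_category", "environment"]


def classify_environment(is_binding_site: bool, is_distant: bool,
                         is_exposed: bool) -> str:
    if is_binding_site:
        return "binding_site"
    if is_distant:
        return "distant_buried" if not is_exposed else "distant_exposed"
    return "other"


def pair_residue_deltas(apo_metrics: pd.DataFrame, holo_metrics: pd.DataFrame,
                        environment: pd.DataFrame,
                        rotamer_categories: Optional[pd.DataFrame] = None,
                        pair_id: str = "") -> pd.DataFrame:
    """Holo-minus-apo per-residue deltas for one matched pair.

    Residues are aligned on (chain, seqnum, icode); rows appear only where
    the metric is computable on both sides.  ``environment`` is the holo
    environment table; ``rotamer_categories`` optionally adds a
    per-residue category column.
    """
    keys = ["chain", "seqnum", "icode"]
    merged = holo_metrics.merge(apo_metrics, on=keys, suffixes=("_holo", "_apo"))
    merged = merged[merged["computable_holo"] & merged["computable_apo"]]
    env = environment.set_index(keys)
    rows = []
    for _, r in merged.iterrows():
        k = (r["chain"], r["seqnum"], r["icode"])
        if k not in env.index:
            continue
        e = env.loc[k]
        rec = {
            "pair_id": pair_id, "chain": r["chain"], "seqnum": r["seqnum"],
            "icode": r["icode"], "aa": r["aa_holo"],
            "delta_s2": r["s2_calc_holo"] - r["s2_calc_apo"],
            "delta_b": r["mean_b_sidechain_holo"] - r["mean_b_sidechain_apo"],
            "delta_rmsf": r["rmsf_holo"] - r["rmsf_apo"],
            "delta_nconf": int(r["n_conformers_holo"] - r["n_conformers_apo"]),
            "environment": classify_environment(
                bool(e["is_binding_site"]), bool(e["is_distant"]),
                bool(e["is_exposed"])),
            "is_exposed": bool(e["is_exposed"]),
        }
        rows.append(rec)
    out = pd.DataFrame(rows)
    if rotamer_categories is not None and not out.empty:
        out = out.merge(rotamer_categories[keys + ["rotamer_category"]],
                        on=keys, how="left")
    return out


@dataclass
class PairSummary:
    pair_id: str
    mean_delta_s2_bs: float
    mean_delta_s2_distant_buried: float

    @property
    def residual(self) -> float:
        return self.mean_delta_s2_distant_buried - self.mean_delta_s2_bs


def summarize_pair(deltas: pd.DataFrame, pair_id: str = "") -> PairSummary:
    bs = deltas.loc[deltas["environment"] == "binding_site", "delta_s2"]
    db = deltas.loc[deltas["environment"] == "distant_buried", "delta_s2"]
    return PairSummary(
        pair_id=pair_id or (deltas["pair_id"].iloc[0] if len(deltas) else ""),
        mean_delta_s2_bs=float(bs.mean()) if len(bs) else float("nan"),
        mean_delta_s2_distant_buried=float(db.mean()) if len(db) else float("nan"))


def matched_control_delta(deltas: pd.DataFrame, rng: np.random.Generator,
                          n_draws: int = 100) -> tuple[float, np.ndarray]:
    """Mean delta-S2 of matched control residues.

    For every binding-site residue one non-binding-site residue of the
    same amino-acid type and the same exposure class is sampled without
    replacement; binding-site residues with no eligible match are skipped.
    Returns the mean over ``n_draws`` repetitions and the raw draws.
    """
    bs = deltas[deltas["environment"] == "binding_site"]
    if bs.empty:
        raise ValueError("no binding-site residues in delta table")
    pool = deltas[deltas["environment"] != "binding_site"]
    draws = np.empty(n_draws)
    for d in range(n_draws):
        sampled = []
        used: set[int] = set()
        for _, r in bs.iterrows():
            match = pool[(pool["aa"] == r["aa"])
                         & (pool["is_exposed"] == r["is_exposed"])
                         & (~pool.index.isin(used))]
            if match.empty:
                continue
            pick = match.index[rng.integers(len(match))]
            used.add(pick)
            sampled.append(pool.loc[pick, "delta_s2"])
        draws[d] = float(np.mean(sampled)) if sampled else float("nan")
    return float(np.nanmean(draws)), draws


def residual_regression(summaries: Sequence[PairSummary]
                        ) -> tuple[float, float, float]:
    """OLS of the residual on the binding-site delta: (slope, r^2, p).

    The p-value is the two-sided t-test on the slope.
    """
    x = np.array([s.mean_delta_s2_bs for s in summaries])
    y = np.array([s.residual for s in summaries])
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 pairs with finite values")
    if np.ptp(x) < 1e-12:
        raise ValueError("zero variance in binding-site deltas")
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.rvalue ** 2), float(fit.pvalue)


def bootstrap_slope_compare(cohort_a: Sequence[PairSummary],
                            cohort_b: Sequence[PairSummary],
                            n_boot: int = 1000,
                            seed: Optional[int] = None
                            ) -> tuple[tuple[float, float],
                                       tuple[float, float], float, float]:
    """Bootstrap comparison of residual-regression slopes of two cohorts.

    Pairs are resampled with replacement within each cohort; the z
    statistic compares the bootstrap slope means against the combined
    bootstrap spread, with a two-sided normal p-value.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    slopes = []
    for cohort in (cohort_a, cohort_b):
        cohort = list(cohort)
        if len(cohort) < 3:
            raise ValueError("each cohort needs at least 3 pairs")
        vals = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(len(cohort), size=len(cohort))
            try:
                vals[b] = residual_regression([cohort[i] for i in idx])[0]
            except ValueError:
                vals[b] = np.nan
        slopes.append(vals[np.isfinite(vals)])
    mean_a, mean_b = slopes[0].mean(), slopes[1].mean()
    sd_a, sd_b = slopes[0].std(ddof=1), slopes[1].std(ddof=1)
    z = (mean_a - mean_b) / np.sqrt(sd_a ** 2 + sd_b ** 2)
    p = 2.0 * sps.norm.sf(abs(z))
    return (float(mean_a), float(mean_b)), (float(sd_a), float(sd_b)), \
        float(z), float(p)


def paired_test(deltas: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns (statistic, p); p is NaN when every delta is zero.
    """
    arr = np.asarray(deltas, dtype=float)
    if np.all(arr == 0):
        return 0.0, float("nan")
    stat, p = sps.wilcoxon(arr)
    return float(stat), float(p)


def group_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between independent groups."""
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(u), float(p)


def quartile_compare(values: pd.Series, key: pd.Series, alpha: float = 0.05,
                     m_tests: int = 10) -> dict:
    """Lowest- vs highest-quartile contrast of ``values`` stratified by ``key``.

    Mann-Whitney U with Bonferroni-corrected significance at alpha/m_tests.
    """
    if len(values) < 8:
        raise ValueError("need at least 8 observations for quartiles")
    key = pd.Series(np.asarray(key, dtype=float))
    values = pd.Series(np.asarray(values, dtype=float))
    if np.ptp(key) < 1e-12:
        raise ValueError("descriptor key has no variation")
    lo_thr = key.quantile(0.25)
    hi_thr = key.quantile(0.75)
    low = values[key <= lo_thr]
    high = values[key >= hi_thr]
    u, p = group_test(low, high)
    corrected = alpha / m_tests
    return {"n_low": int(len(low)), "n_high": int(len(high)),
            "median_low": float(low.median()), "median_high": float(high.median()),
            "u": u, "p": p, "alpha_corrected": corrected,
            "significant": bool(p < corrected)}


def summarize_categories(deltas: pd.DataFrame) -> dict:
    """Cohort fractions of conformer-count changes and rotamer categories."""
    if deltas.empty:
        raise ValueError("empty delta table")
    out: dict = {}
    n = len(deltas)
    out["frac_gain_conformer"] = float((deltas["delta_nconf"] > 0).mean())
    out["frac_lose_conformer"] = float((deltas["delta_nconf"] < 0).mean())
    out["frac_same_conformer"] = float((deltas["delta_nconf"] == 0).mean())
    if "rotamer_category" in deltas.columns:
        cats = deltas["rotamer_category"].dropna()
        out["rotamer_fractions"] = (cats.value_counts(normalize=True)
                                    .to_dict() if len(cats) else {})
        bs = deltas[deltas["environment"] == "binding_site"].dropna(
            subset=["rotamer_category"])
        out["rotamer_fractions_binding_site"] = (
            bs["rotamer_category"].value_counts(normalize=True).to_dict()
            if len(bs) else {})
        if "pair_id" in deltas.columns and len(bs):
            per_pair = bs.groupby("pair_id")["rotamer_category"].apply(
                lambda s: bool((s == "no_change").all()))
            out["frac_preorganized_binding_sites"] = float(per_pair.mean())
    return out


def cluster_delta_matrix(matrix: pd.DataFrame
                         ) -> tuple[list[int], list[int], dict]:
    """Hierarchical co-clustering of a residue-by-pair delta matrix.

    Average-linkage agglomerative clustering with Euclidean distances on
    rows and columns; returns leaf orders for clustermap rendering and
    the two linkage matrices.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if not np.all(np.isfinite(arr)):
        raise ValueError("matrix contains non-finite entries; impute or drop "
                         "incomplete residues before clustering")
    orders, linkages = [], []
    for data in (arr, arr.T):
        if data.shape[0] < 2:
            orders.append(list(range(data.shape[0])))
            linkages.append(None)
            continue
        link = hierarchy.linkage(pdist(data), method="average")
        orders.append(list(hierarchy.leaves_list(link)))
        linkages.append(link)
    return orders[0], orders[1], {"rows": linkages[0], "cols": linkages[1]}
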