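"""Cohort statistics: deltas, controls, regression, bootstrap, tests."""

import numpy as np
import pandas as pd
import pytest

from confhet.stats import (PairSummary, bootstrap_slope_compare,
                           cluster_delta_matrix, group_test,
                           matched_control_delta, paired_test,
                           pair_residue_deltas, quartile_compare,
                           residual_regression, summarize_categories,
                           summarize_pair)


def _metrics_frame(n=6, s2=0.7, computable=True):
    return pd.DataFrame({
        "structure_id": "s", "chain": "A", "seqnum": range(1, n + 1),
        "icode": "", "aa": ["SER", "VAL", "LEU"] * (n // 3),
        "n_conformers": 2, "s2_ang": s2, "s2_ortho": 0.8,
        "s2_ortho_norm": 1.0, "s2_calc": s2, "rmsf": 0.3,
        "mean_b_sidechain": 12.0, "mean_b_calpha": 15.0,
        "computable": computable,
    })


def _env_frame(n=6, n_bs=2):
    return pd.DataFrame({
        "structure_id": "s", "chain": "A", "seqnum": range(1, n + 1),
        "icode": "", "aa": ["SER", "VAL", "LEU"] * (n // 3),
        "min_ligand_distance": [3.0] * n_bs + [12.0] * (n - n_bs),
        "is_binding_site": [True] * n_bs + [False] * (n - n_bs),
        "is_distant": [False] * n_bs + [True] * (n - n_bs),
        "sasa": 50.0, "rasa": 0.1, "is_exposed": False,
    })


def test_pair_residue_deltas_zero_for_identical():
    m = _metrics_frame()
    deltas = pair_residue_deltas(m, m.copy(), _env_frame(), pair_id="p")
    assert len(deltas) == 6
    assert (deltas["delta_s2"] == 0).all()
    assert (deltas["delta_nconf"] == 0).all()
    assert set(deltas["environment"]) == {"binding_site", "distant_buried"}


def test_pair_residue_deltas_sign_convention_and_dropping():
    apo = _metrics_frame()
    holo = _metrics_frame()
    holo.loc[0, "s2_calc"] = 0.9                     # holo more rigid
    holo = holo[holo["seqnum"] != 6]                 # trimmed residue
    deltas = pair_residue_deltas(apo, holo, _env_frame(), pair_id="p")
    assert deltas.loc[deltas["seqnum"] == 1, "delta_s2"].iloc[0] == \
        pytest.approx(0.2)                           # holo minus apo
    assert 6 not in set(deltas["seqnum"])


def _delta_table(n_bs=3, n_pool=9, bs_delta=0.0, pool_delta=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    aas = ["SER", "VAL", "LEU"]
    for i in range(n_bs):
        rows.append({"pair_id": "p", "chain": "A", "seqnum": i + 1,
                     "icode": "", "aa": aas[i % 3],
                     "delta_s2": bs_delta + rng.normal(0, 0.01),
                     "delta_b": 0.0, "delta_rmsf": 0.0, "delta_nconf": 0,
                     "environment": "binding_site", "is_exposed": True,
                     "rotamer_category": "no_change"})
    for i in range(n_pool):
        rows.append({"pair_id": "p", "chain": "A", "seqnum": 100 + i,
                     "icode": "", "aa": aas[i % 3],
                     "delta_s2": pool_delta + rng.normal(0, 0.01),
                     "delta_b": 0.0, "delta_rmsf": 0.0, "delta_nconf": 0,
                     "environment": "distant_exposed", "is_exposed": True,
                     "rotamer_category": "no_change"})
    return pd.DataFrame(rows)


def test_matched_control_never_samples_binding_site():
    table = _delta_table(bs_delta=0.5, pool_delta=0.0)
    rng = np.random.default_rng(1)
    mean, draws = matched_control_delta(table, rng, n_draws=50)
    # control values come from the zero-effect pool, not the shifted site
    assert abs(mean) < 0.1
    assert np.isfinite(draws).all()


def test_matched_control_deterministic_under_seed():
    table = _delta_table()
    m1, d1 = matched_control_delta(table, np.random.default_rng(42), 20)
    m2, d2 = matched_control_delta(table, np.random.default_rng(42), 20)
    assert m1 == m2 and np.array_equal(d1, d2)


def test_matched_control_requires_binding_site():
    table = _delta_table()
    table["environment"] = "distant_exposed"
    with pytest.raises(ValueError):
        matched_control_delta(table, np.random.default_rng(0))


def _summaries(x, resid):
    return [PairSummary(f"p{i}", float(a), float(a + b))
            for i, (a, b) in enumerate(zip(x, resid))]


def test_residual_regression_exact_line():
    x = np.linspace(-0.2, 0.3, 20)
    slope, r2, p = residual_regression(_summaries(x, -0.5 * x))
    assert slope == pytest.approx(-0.5, abs=1e-12)
    assert r2 == pytest.approx(1.0, abs=1e-12)
    assert p < 1e-20


def test_residual_regression_recovers_planted_slope():
    rng = np.random.default_rng(0)
    x = rng.normal(0.03, 0.1, size=200)
    resid = -0.44 * x + rng.normal(0, 0.048, size=200)
    slope, r2, p = residual_regression(_summaries(x, resid))
    se = 0.048 / (x.std() * np.sqrt(len(x)))
    assert abs(slope - (-0.44)) < 1.96 * se * 1.5
    assert p < 1e-6


def test_residual_regression_constant_x_raises():
    with pytest.raises(ValueError):
        residual_regression(_summaries(np.full(10, 0.1), np.zeros(10)))


def test_residual_recomputable_from_components():
    s = PairSummary("p", 0.05, 0.02)
    assert s.residual == pytest.approx(0.02 - 0.05, abs=1e-12)
    table = _delta_table(bs_delta=0.1)
    table.loc[table["environment"] == "distant_exposed", "environment"] = \
        "distant_buried"
    summ = summarize_pair(table)
    assert summ.residual == pytest.approx(
        summ.mean_delta_s2_distant_buried - summ.mean_delta_s2_bs, abs=1e-12)


def test_bootstrap_identical_cohorts_small_z():
    from confhet.synthetic import simulate_pair_summaries
    cohort = simulate_pair_summaries(100, 0.03, -0.44, seed=2)
    _, _, z, p = bootstrap_slope_compare(cohort, cohort, n_boot=200, seed=3)
    assert abs(z) < 0.5 and p > 0.5


def test_bootstrap_deterministic_under_seed():
    from confhet.synthetic import simulate_pair_summaries
    a = simulate_pair_summaries(50, 0.03, -0.44, seed=4)
    b = simulate_pair_summaries(50, 0.0, -0.28, seed=5)
    r1 = bootstrap_slope_compare(a, b, n_boot=100, seed=6)
    r2 = bootstrap_slope_compare(a, b, n_boot=100, seed=6)
    assert r1 == r2


def test_paired_test_power_and_degenerate():
    stat, p = paired_test([1.0] * 12)
    assert p < 0.01
    _, p0 = paired_test(np.zeros(10))
    assert np.isnan(p0)


def test_group_test_identical_groups_midrank_u():
    x = np.arange(10, dtype=float)
    u, p = group_test(x, x)
    assert u == pytest.approx(len(x) * len(x) / 2.0)


def test_quartile_compare_planted_shift():
    rng = np.random.default_rng(7)
    key = np.concatenate([rng.uniform(0, 1, 120), rng.uniform(2, 3, 120)])
    values = np.concatenate([rng.normal(-0.05, 0.02, 120),
                             rng.normal(0.0, 0.02, 120)])
    out = quartile_compare(pd.Series(values), pd.Series(key))
    assert out["alpha_corrected"] == pytest.approx(0.005)
    assert out["significant"]


def test_quartile_compare_group_sizes():
    values = pd.Series(np.arange(8, dtype=float))
    key = pd.Series(np.arange(8, dtype=float))
    out = quartile_compare(values, key)
    assert out["n_low"] == 2 and out["n_high"] == 2
    with pytest.raises(ValueError):
        quartile_compare(values, pd.Series(np.ones(8)))


def test_summarize_categories_exact_fractions():
    table = _delta_table(n_bs=4, n_pool=4)
    table.loc[table.index[:2], "delta_nconf"] = -1
    table.loc[table.index[2], "delta_nconf"] = 1
    table.loc[table.index[0], "rotamer_category"] = "distinct"
    out = summarize_categories(table)
    assert out["frac_lose_conformer"] == pytest.approx(0.25)
    assert out["frac_gain_conformer"] == pytest.approx(0.125)
    assert out["rotamer_fractions_binding_site"]["distinct"] == \
        pytest.approx(0.25)
    assert out["frac_preorganized_binding_sites"] == 0.0


def test_summarize_all_no_change():
    table = _delta_table(n_bs=4, n_pool=4)
    out = summarize_categories(table)
    assert out["frac_same_conformer"] == 1.0
    assert out["frac_preorganized_binding_sites"] == 1.0


def test_cluster_block_matrix_contiguity():
    rng = np.random.default_rng(8)
    block = np.vstack([np.full((5, 6), 0.2), np.full((5, 6), -0.2)])
    block += rng.normal(0, 0.01, block.shape)
    perm = rng.permutation(10)
    mat = pd.DataFrame(block[perm])
    row_order, col_order, links = cluster_delta_matrix(mat)
    labels = (perm < 5)[row_order]
    # each original block's rows are contiguous after reordering
    changes = np.sum(labels[:-1] != labels[1:])
    assert changes == 1


def test_cluster_single_row_and_nan():
    row_order, col_order, _ = cluster_delta_matrix(pd.DataFrame([[1.0, 2.0]]))
    assert row_order == [0]
    with pytest.raises(ValueError, match="impute"):
        cluster_delta_matrix(pd.DataFrame([[1.0, np.nan], [0.0, 1.0]]))


def test_cluster_permutation_consistency():
    """Permuting input rows permutes the output: same merge heights, and
    the leaf order is a permutation of the rows."""
    rng = np.random.default_rng(9)
    mat = rng.normal(size=(8, 5))
    r1, _, l1 = cluster_delta_matrix(pd.DataFrame(mat))
    perm = rng.permutation(8)
    r2, _, l2 = cluster_delta_matrix(pd.DataFrame(mat[perm]))
    assert sorted(r1) == list(range(8)) and sorted(r2) == list(range(8))
    assert np.allclose(np.sort(l1["rows"][:, 2]), np.sort(l2["rows"][:, 2]))
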