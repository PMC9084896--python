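"""Order parameters, RMSF, B-factor aggregation and normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from confhet.metrics import (HARMONIC_K, NormalizationConfig,
                             calibrate_normalization, calpha_bfactor,
                             conformer_count, normalize_s2_ortho,
                             residue_bfactor, s2_angular, s2_calc, s2_ortho,
                             side_chain_rmsf)
from confhet.synthetic import (ResidueSpec, build_residue,
                               make_calibration_series)

from conftest import make_residue


def two_site_closed_form(q1, q2, theta_deg):
    """Independent oracle: S2 = 1 - 3 q1 q2 sin^2(theta) (occupancies
    normalised)."""
    s = q1 + q2
    q1, q2 = q1 / s, q2 / s
    return 1.0 - 3.0 * q1 * q2 * math.sin(math.radians(theta_deg)) ** 2


def vectors_at_angle(theta_deg):
    t = math.radians(theta_deg)
    return [np.array([0.0, 0.0, 1.0]),
            np.array([math.sin(t), 0.0, math.cos(t)])]


@pytest.mark.parametrize("q1,q2,theta,expected", [
    (1.0, None, None, 1.0),                       # single conformer
    (0.5, 0.5, 90.0, 0.25),
    (0.5, 0.5, math.degrees(math.acos(-1.0 / 3.0)), 1.0 / 3.0),
    (0.7, 0.3, 90.0, 0.37),
])
def test_s2_angular_closed_form_cases(q1, q2, theta, expected):
    if q2 is None:
        assert s2_angular([np.array([0.0, 0.0, 1.0])], [q1]) == pytest.approx(1.0)
    else:
        got = s2_angular(vectors_at_angle(theta), [q1, q2])
        assert got == pytest.approx(expected, abs=1e-12)


@settings(max_examples=200, deadline=None)
@given(q1=st.floats(0.05, 0.95), theta=st.floats(1.0, 179.0),
       seed=st.integers(0, 2 ** 16))
def test_s2_angular_tensor_matches_closed_form_and_rotation_invariance(
        q1, theta, seed):
    vecs = vectors_at_angle(theta)
    occs = [q1, 1.0 - q1]
    expected = two_site_closed_form(q1, 1.0 - q1, theta)
    assert s2_angular(vecs, occs) == pytest.approx(expected, abs=1e-12)
    rot = Rotation.random(rng=np.random.default_rng(seed))
    rotated = [rot.apply(v) for v in vecs]
    assert s2_angular(rotated, occs) == pytest.approx(expected, abs=1e-9)
    # occupancy-preserving permutation
    assert s2_angular(vecs[::-1], occs[::-1]) == pytest.approx(expected,
                                                               abs=1e-12)


def test_s2_angular_rejects_zero_vector():
    with pytest.raises(ValueError):
        s2_angular([np.zeros(3)], [1.0])


def test_s2_ortho_values_and_clip():
    assert s2_ortho(0.0, 0.0) == 1.0
    expected = 1.0 - HARMONIC_K * 20.0 / 1.09 ** 2
    assert s2_ortho(10.0, 10.0) == pytest.approx(expected)
    assert expected == pytest.approx(0.680, abs=5e-4)
    assert s2_ortho(60.0, 60.0) == 0.0       # clipped at the floor
    with pytest.raises(ValueError):
        s2_ortho(10.0, 10.0, r=0.0)


def test_s2_ortho_monotone_decreasing_in_b():
    values = [s2_ortho(b, b) for b in np.linspace(0, 30, 20)]
    assert all(a >= b for a, b in zip(values, values[1:]))


def test_normalize_s2_ortho():
    assert normalize_s2_ortho(0.8, 16.0, 1.6) == pytest.approx(0.8)
    assert normalize_s2_ortho(0.8, 8.0, 1.6) == pytest.approx(0.4)
    assert normalize_s2_ortho(0.8, 40.0, 2.0) == 1.0   # clipped ceiling
    with pytest.raises(ValueError):
        normalize_s2_ortho(0.8, 16.0, 0.0)


def test_s2_calc_planted_product():
    """s2_calc on a generator-built residue equals the analytic product of
    the planted angular and (clipped) harmonic-normalized components."""
    spec = ResidueSpec("SER", (60.0, 180.0), (0.7, 0.3), 10.0, 40.0)
    res = build_residue(spec, 0)
    m = s2_calc(res, resolution=1.6)
    s2o = s2_ortho(10.0, 10.0)
    norm = normalize_s2_ortho(s2o, 40.0, 1.6)
    expected = norm * spec.s2_ang_true()
    assert m.computable
    assert m.s2_ang == pytest.approx(spec.s2_ang_true(), abs=1e-9)
    assert m.s2_calc == pytest.approx(expected, abs=1e-9)
    assert m.s2_calc == pytest.approx(m.s2_ortho_norm * m.s2_ang, abs=1e-12)


def test_s2_calc_gly_not_computable():
    gly = make_residue("GLY", conformers=[
        ("", 1.0, {"N": ("N", (0, 1, 0), 10.0, False),
                   "CA": ("C", (1.4, 1, 0), 10.0, False)})])
    m = s2_calc(gly, resolution=1.6)
    assert not m.computable
    assert math.isnan(m.s2_calc)


def _two_centroid_residue(q1, q2):
    return make_residue("SER", conformers=[
        ("A", q1, {"CA": ("C", (0, 0, 0), 10.0, False),
                   "CB": ("C", (1, 0, 0), 10.0, True),
                   "OG": ("O", (1, 0, 1), 10.0, True)}),
        ("B", q2, {"CA": ("C", (0, 0, 0), 10.0, False),
                   "CB": ("C", (1, 1, 0), 10.0, True),
                   "OG": ("O", (1, 1, 1), 10.0, True)}),
    ])


@pytest.mark.parametrize("q1,q2,expected", [
    (0.5, 0.5, 0.5),
    (0.8, 0.2, 0.4),
])
def test_rmsf_hand_cases(q1, q2, expected):
    """Two conformers with side-chain centroids 1 A apart."""
    res = _two_centroid_residue(q1, q2)
    assert side_chain_rmsf(res) == pytest.approx(expected, abs=1e-12)


def test_rmsf_single_conformer_zero(synthetic_pair):
    res = make_residue("SER", conformers=[
        ("", 1.0, {"CB": ("C", (1, 0, 0), 10.0, False),
                   "OG": ("O", (1, 0, 1), 10.0, False)})])
    assert side_chain_rmsf(res) == 0.0


def test_residue_bfactor_weighted_mean():
    res = make_residue("SER", conformers=[
        ("A", 0.6, {"CB": ("C", (1, 0, 0), 10.0, True)}),
        ("B", 0.4, {"CB": ("C", (1, 1, 0), 20.0, True)}),
    ])
    assert residue_bfactor(res, "sidechain") == pytest.approx(14.0)


def test_residue_bfactor_scope_differs_when_backbone_differs():
    res = make_residue("SER", conformers=[
        ("", 1.0, {"CA": ("C", (0, 0, 0), 30.0, False),
                   "CB": ("C", (1, 0, 0), 10.0, False)})])
    assert residue_bfactor(res, "sidechain") == pytest.approx(10.0)
    assert residue_bfactor(res, "all") == pytest.approx(20.0)
    assert calpha_bfactor(res) == pytest.approx(30.0)


def test_conformer_count_rules():
    no_alt = make_residue("SER", conformers=[
        ("", 1.0, {"CB": ("C", (1, 0, 0), 10.0, False)})])
    assert conformer_count(no_alt) == 1
    # altloc on a single gamma atom -> 2 side-chain conformers
    gamma_only = make_residue("SER", conformers=[
        ("A", 0.5, {"CA": ("C", (0, 0, 0), 10.0, False),
                    "OG": ("O", (1, 0, 1), 10.0, True)}),
        ("B", 0.5, {"CA": ("C", (0, 0, 0), 10.0, False),
                    "OG": ("O", (1, 0, -1), 10.0, True)}),
    ])
    assert conformer_count(gamma_only) == 2
    # backbone-only altlocs do not make the side chain multiconformer
    backbone_only = make_residue("SER", conformers=[
        ("A", 0.5, {"CA": ("C", (0, 0, 0), 10.0, True)}),
        ("B", 0.5, {"CA": ("C", (0, 0.1, 0), 10.0, True)}),
    ])
    assert conformer_count(backbone_only) == 1


def test_calibration_recovers_true_constant():
    low, high = make_calibration_series(n_residues=200, true_c=10.0,
                                        noise_sd=0.01, seed=5)
    grid = [4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0]
    best, table = calibrate_normalization(low, high, grid)
    assert abs(best - 10.0) <= 2.0
    assert len(table) == len(grid)


def test_calibration_degenerate_series_raises():
    n = 10
    lo = np.column_stack([np.full(n, 0.5), np.full(n, 1e6), np.full(n, 2.0)])
    hi = np.column_stack([np.full(n, 0.5), np.full(n, 1e6), np.full(n, 1.2)])
    with pytest.raises(ValueError):
        calibrate_normalization(lo, hi, [10.0])
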