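import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ceeagree import (
    PairedTrialData,
    SimConfig,
    ValidationError,
    agreement_curve,
    ccc_threshold,
    concordance,
    difference_from_summaries,
    equivalence_test,
    fisher_z,
    fisher_z_inv,
    inb_difference,
    miscoverage,
    simulate_paired_trial,
)
from ceeagree.agreement import UndefinedThresholdError, _ccc_point

from conftest import make_data, random_paired_data


def swap_sources(data):
    frame = data.frame.rename(
        columns={
            "cost_1": "cost_2",
            "cost_2": "cost_1",
            "outcome_1": "outcome_2",
            "outcome_2": "outcome_1",
        }
    )
    return PairedTrialData(frame=frame, adverse_outcome=data.adverse_outcome)


# ---------------------------------------------------------------- difference

def test_identical_sources_exact_agreement(identical_sources_data):
    diff = inb_difference(identical_sources_data, 30_000.0)
    assert diff.exact_agreement
    assert diff.omega == 0.0
    assert diff.z == 0.0
    assert diff.p_two_sided == 1.0


def test_omega_equals_beta_difference():
    rng = np.random.default_rng(3)
    data = random_paired_data(rng)
    diff = inb_difference(data, 45_000.0)
    assert diff.omega == pytest.approx(diff.beta_2 - diff.beta_1, rel=1e-9, abs=1e-9)
    if diff.se_omega > 0:
        assert diff.z * diff.se_omega == pytest.approx(diff.omega, rel=1e-9)


@pytest.mark.parametrize(
    "beta_1, beta_2, se, expected_omega, expected_p",
    [
        # published INB comparisons at λ=£30,000: MD and two-sided p
        (-372.0, 268.0, 1129.0, 640.0, 0.571),
        (486.0, -372.0, 1021.0, -858.0, 0.401),
        (511.0, 268.0, 454.0, -243.0, 0.593),
        (-372.0, 511.0, 1021.0, 883.0, 0.387),
    ],
)
def test_summary_level_difference_matches_published(beta_1, beta_2, se, expected_omega, expected_p):
    res = difference_from_summaries(beta_1, beta_2, se)
    assert res.omega == pytest.approx(expected_omega, abs=1.0)
    assert res.p_two_sided == pytest.approx(expected_p, abs=0.002)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_se_omega_decomposition_oracle(seed):
    """se_ω from paired differences = √(σ²_β1 + σ²_β2 − 2côv) to 1e−9."""
    rng = np.random.default_rng(seed)
    data = random_paired_data(rng)
    lam = float(rng.uniform(0, 80_000))
    diff = inb_difference(data, lam)
    var1 = var2 = cov = 0.0
    for arm in ("control", "intervention"):
        c1, y1 = data.arm_arrays(1, arm)
        c2, y2 = data.arm_arrays(2, arm)
        e1 = 1 - y1 if data.adverse_outcome else y1
        e2 = 1 - y2 if data.adverse_outcome else y2
        nb1 = lam * e1 - c1
        nb2 = lam * e2 - c2
        n = nb1.size
        var1 += nb1.var(ddof=1) / n
        var2 += nb2.var(ddof=1) / n
        cov += np.cov(nb1, nb2, ddof=1)[0, 1] / n
    assert diff.se_omega**2 == pytest.approx(var1 + var2 - 2 * cov, rel=1e-9, abs=1e-9)


def test_antisymmetry_under_source_swap():
    rng = np.random.default_rng(17)
    data = random_paired_data(rng, n_min=20, n_max=30)
    lam = 25_000.0
    a = inb_difference(data, lam)
    b = inb_difference(swap_sources(data), lam)
    assert b.omega == pytest.approx(-a.omega, rel=1e-9, abs=1e-9)
    assert b.z == pytest.approx(-a.z, rel=1e-9, abs=1e-9)
    assert b.p_two_sided == pytest.approx(a.p_two_sided, rel=1e-9)
    # miscoverage with roles swapped is identical replicate-for-replicate
    m_ab = miscoverage(data, 2, 1, lam, 300, 0.05, seed=9)
    m_ba = miscoverage(swap_sources(data), 1, 2, lam, 300, 0.05, seed=9)
    assert m_ab.miscoverage == m_ba.miscoverage
    # concordance is symmetric in the sources
    c_a = concordance(data, lam, 200, seed=4)
    c_b_ = concordance(swap_sources(data), lam, 200, seed=4)
    assert c_b_.rho_c == pytest.approx(c_a.rho_c, rel=1e-9)


# ---------------------------------------------------------------- equivalence

def test_tost_at_margin_equal_to_critical_value():
    diff = difference_from_summaries(0.0, 0.0 + 0.0, 1.0)
    # omega 0, se 1, delta = z_{0.975}: both one-sided p's are 0.025
    assert equivalence_test(diff, 1.959964) == pytest.approx(0.025, abs=1e-4)


def test_tost_boundary_and_limits():
    diff = difference_from_summaries(0.0, 5.0, 2.0)
    assert equivalence_test(diff, 5.0) == pytest.approx(0.5)  # omega == delta
    assert equivalence_test(diff, 1e9) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValidationError):
        equivalence_test(diff, -1.0)


def test_tost_exact_agreement_convention(identical_sources_data):
    diff = inb_difference(identical_sources_data, 10_000.0)
    assert equivalence_test(diff, 1.0) == 0.0


# ---------------------------------------------------------------- miscoverage

def test_miscoverage_gross_disagreement():
    cfg = SimConfig(n_control=200, n_intervention=200,
                    source2_cost_shift=300_000.0, shift_arm="intervention", seed=2)
    data = simulate_paired_trial(cfg)
    res = miscoverage(data, 1, 2, 30_000.0, 200, 0.05, seed=6)
    assert res.miscoverage == pytest.approx(1.0)


def test_miscoverage_granularity_and_determinism():
    rng = np.random.default_rng(23)
    data = random_paired_data(rng)
    res = miscoverage(data, 1, 2, 20_000.0, 10, 0.05, seed=1)
    assert res.miscoverage * 10 == pytest.approx(round(res.miscoverage * 10))
    res2 = miscoverage(data, 1, 2, 20_000.0, 10, 0.05, seed=1)
    assert res.miscoverage == res2.miscoverage


def test_miscoverage_self_comparison_flagged():
    rng = np.random.default_rng(29)
    data = random_paired_data(rng, n_min=30, n_max=30)
    res = miscoverage(data, 1, 1, 10_000.0, 50, 0.05, seed=2)
    assert res.calibration


# ---------------------------------------------------------------- concordance

def test_concordance_identity(identical_sources_data):
    res = concordance(identical_sources_data, 30_000.0, 100, seed=3)
    assert res.rho_c == 1.0
    assert res.degenerate
    assert res.ci_low == res.ci_high == 1.0
    assert res.p_one_sided == 0.0


def test_concordance_independent_sources_near_zero():
    """Sources built from unrelated patients: ρ̂_c ≈ 0."""
    cfg = SimConfig(n_control=2000, n_intervention=2000, seed=31,
                    source_cost_sd_1=0.0, source_cost_sd_2=0.0,
                    misclass_1=0.0, misclass_2=0.0)
    a = simulate_paired_trial(cfg, seed=100)
    b = simulate_paired_trial(cfg, seed=200)
    frame = a.frame.copy()
    frame[["cost_2", "outcome_2"]] = b.frame[["cost_1", "outcome_1"]].to_numpy()
    data = PairedTrialData(frame=frame, adverse_outcome=True)
    res = concordance(data, 30_000.0, 100, seed=8, rho_c0_fixed=0.4)
    assert abs(res.rho_c) < 0.1


def _brute_force_rho_c(data, lam):
    """Independent evaluation of the adapted concordance quotient.

    Exact-fraction arithmetic over explicit sums; shares no code with the
    implementation under test.
    """
    stats = {}
    for arm in ("control", "intervention"):
        sub = data.frame[data.frame["arm"] == arm]
        nb1 = [Fraction(lam) * (1 - Fraction(y)) - Fraction(c)
               for c, y in zip(sub["cost_1"], sub["outcome_1"])]
        nb2 = [Fraction(lam) * (1 - Fraction(y)) - Fraction(c)
               for c, y in zip(sub["cost_2"], sub["outcome_2"])]
        n = len(nb1)
        m1 = sum(nb1) / n
        m2 = sum(nb2) / n
        v1 = sum((x - m1) ** 2 for x in nb1) / (n - 1)
        v2 = sum((x - m2) ** 2 for x in nb2) / (n - 1)
        c12 = sum((x - m1) * (y - m2) for x, y in zip(nb1, nb2)) / (n - 1)
        stats[arm] = (n, m1, m2, v1, v2, c12)
    n_i, m1i, m2i, v1i, v2i, ci = stats["intervention"]
    n_c, m1c, m2c, v1c, v2c, cc = stats["control"]
    b1 = m1i - m1c
    b2 = m2i - m2c
    var1 = v1i / n_i + v1c / n_c
    var2 = v2i / n_i + v2c / n_c
    cov = ci / n_i + cc / n_c
    return 2 * cov / ((b2 - b1) ** 2 + var1 + var2)


def test_concordance_micro_example_matches_brute_force():
    """3+3-patient dataset with integer costs: ρ̂_c equals the exact quotient."""
    data = make_data(
        control=[(100, 0, 120, 0), (260, 1, 240, 1), (180, 0, 150, 0)],
        intervention=[(90, 1, 110, 1), (200, 0, 230, 0), (150, 1, 130, 0)],
        adverse=True,
    )
    lam = 300
    expected = float(_brute_force_rho_c(data, lam))
    rho_c, rho, c_b, _, _ = _ccc_point(data, float(lam))
    assert rho_c == pytest.approx(expected, rel=1e-12)
    assert rho_c == pytest.approx(rho * c_b, rel=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_concordance_invariants(seed):
    """ρ_c = ρ·C_b; |ρ_c| ≤ |ρ|; ρ_c bounded; CI brackets the estimate."""
    rng = np.random.default_rng(seed)
    data = random_paired_data(rng, n_min=10, n_max=40)
    res = concordance(data, 15_000.0, 100, seed=seed % 1000, rho_c0_fixed=0.0)
    assert res.rho_c == pytest.approx(res.rho * res.c_b, rel=1e-9, abs=1e-12)
    assert abs(res.rho_c) <= abs(res.rho) + 1e-12
    assert -1.0 <= res.rho_c <= 1.0
    assert res.ci_low <= res.rho_c + 1e-9
    assert res.rho_c - 1e-9 <= res.ci_high


def test_concordance_rho_c_below_rho_when_means_differ():
    cfg = SimConfig(n_control=500, n_intervention=500,
                    source2_cost_shift=5_000.0, shift_arm="intervention", seed=13)
    data = simulate_paired_trial(cfg)
    res = concordance(data, 30_000.0, 100, seed=5)
    assert res.rho_c < res.rho
    assert res.c_b < 1.0


def test_concordance_requires_enough_bootstrap():
    rng = np.random.default_rng(37)
    data = random_paired_data(rng)
    with pytest.raises(ValidationError):
        concordance(data, 1_000.0, 1, seed=0)


# ---------------------------------------------------------------- closed forms

def test_fisher_z_values_and_roundtrip():
    assert fisher_z(0.0) == 0.0
    assert fisher_z(0.882) == pytest.approx(1.3847, abs=2e-4)
    for r in (-0.99, -0.5, 0.0, 0.3, 0.975):
        assert fisher_z_inv(fisher_z(r)) == pytest.approx(r, rel=1e-12, abs=1e-12)
    with pytest.raises(ValidationError):
        fisher_z(1.0)


def test_ccc_threshold_values():
    assert ccc_threshold(1.0, 1.0, 0.05) == pytest.approx(0.974679, abs=1e-5)
    assert ccc_threshold(0.8, 0.9, 0.0) == pytest.approx(0.72)  # x=0 → C_b·ρ = ρ_c
    with pytest.raises(UndefinedThresholdError):
        ccc_threshold(0.2, 1.0, 0.05)


# ---------------------------------------------------------------- curve

def test_agreement_curve_identity_propagates(identical_sources_data):
    curve = agreement_curve(
        identical_sources_data,
        lambda_grid=[0.0, 30_000.0, 100_000.0],
        n_boot=50,
        seed=12,
    ).frame
    assert np.allclose(curve["omega"], 0.0)
    assert np.allclose(curve["rho_c"], 1.0)
    assert np.allclose(curve["p_two_sided"], 1.0)


def test_agreement_curve_rows_match_standalone_ops():
    rng = np.random.default_rng(41)
    data = random_paired_data(rng, n_min=25, n_max=35)
    curve = agreement_curve(
        data, lambda_grid=[0.0, 20_000.0], referent=1, n_boot=80,
        alpha=0.05, rho_c0_fixed=0.4, seed=99,
    ).frame
    for _, row in curve.iterrows():
        lam = row["lambda"]
        diff = inb_difference(data, lam)
        assert row["omega"] == pytest.approx(diff.omega, rel=1e-12, abs=1e-12)
        misc = miscoverage(data, 1, 2, lam, 80, 0.05, int(row["misc_seed"]))
        assert row["miscoverage"] == misc.miscoverage
        conc = concordance(data, lam, 80, int(row["ccc_seed"]), rho_c0_fixed=0.4)
        assert row["rho_c"] == pytest.approx(conc.rho_c, rel=1e-12)
        assert row["ci_low"] == pytest.approx(conc.ci_low, rel=1e-12)


def test_agreement_curve_lambda_zero_is_costs_only():
    rng = np.random.default_rng(43)
    data = random_paired_data(rng)
    curve = agreement_curve(data, lambda_grid=[0.0], n_boot=50, seed=3,
                            rho_c0_fixed=0.4).frame
    row = curve.iloc[0]
    # at λ=0 the INB is −cost, so ω is minus the difference in ΔC
    from ceeagree import incremental_cost

    expected = -(incremental_cost(data, 2) - incremental_cost(data, 1))
    assert row["omega"] == pytest.approx(expected, rel=1e-9, abs=1e-9)


def test_agreement_curve_rejects_bad_grid(toy_data):
    with pytest.raises(ValidationError):
        agreement_curve(toy_data, lambda_grid=[], n_boot=10, seed=0)
    with pytest.raises(ValidationError):
        agreement_curve(toy_data, lambda_grid=[10.0, 5.0], n_boot=10, seed=0)
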