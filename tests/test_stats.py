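"""Scalar ANOVA / ICC core: oracle comparisons and invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import stats as sps

import relimap as rm
from relimap.stats import InvalidDesignError, SingularDesignError

from conftest import random_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def anova_oracle(values):
    """Brute-force sums of squares by explicit loops (no vectorisation)."""
    vals = np.asarray(values, dtype=float)
    n, k = vals.shape
    grand = sum(vals[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(vals[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(vals[i, j] for i in range(n)) / n for j in range(k)]
    ss_subject = k * sum((r - grand) ** 2 for r in row)
    ss_measure = n * sum((c - grand) ** 2 for c in col)
    ss_total = sum((vals[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_error = sum(
        (vals[i, j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    return {
        "msbs": ss_subject / (n - 1),
        "msbm": ss_measure / (k - 1),
        "mse": ss_error / ((n - 1) * (k - 1)),
        "msw": (ss_measure + ss_error) / (n * (k - 1)),
        "ss": (ss_subject, ss_measure, ss_error, ss_total),
    }


def pingouin_icc(values, kind):
    """Independent ICC + CI oracle (pingouin implements McGraw & Wong)."""
    import pingouin as pg

    vals = np.asarray(values, dtype=float)
    n, k = vals.shape
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": vals.ravel(),
        }
    )
    res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    row = res[res["Type"] == {"icc_1": "ICC(1,1)", "icc_2": "ICC(A,1)", "icc_3": "ICC(C,1)"}[kind]]
    return float(row["ICC"].iloc[0]), tuple(row["CI95"].iloc[0])


# ---------------------------------------------------------------------------
# ANOVA decompositions
# ---------------------------------------------------------------------------


def test_twoway_matches_bruteforce_on_worked_example(worked_matrix):
    a = rm.decompose_twoway(worked_matrix)
    oracle = anova_oracle(worked_matrix.values)
    assert a.ms_between_subject == pytest.approx(oracle["msbs"], rel=1e-12)
    assert a.ms_between_measure == pytest.approx(oracle["msbm"], rel=1e-12)
    assert a.ms_error == pytest.approx(oracle["mse"], rel=1e-12)
    # frozen values recomputed from the printed vectors with the loop oracle
    assert a.ms_between_subject == pytest.approx(157.6, abs=1e-9)
    assert a.ms_between_measure == pytest.approx(384.4, abs=1e-9)
    assert a.ms_error == pytest.approx(39.4, abs=1e-9)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_twoway_matches_bruteforce_on_random_matrices(seed):
    m = random_matrix(np.random.default_rng(seed), n=5 + seed, k=2 + seed % 3)
    a = rm.decompose_twoway(m)
    oracle = anova_oracle(m.values)
    for got, want in zip(
        (a.ms_between_subject, a.ms_between_measure, a.ms_error),
        (oracle["msbs"], oracle["msbm"], oracle["mse"]),
    ):
        assert got == pytest.approx(want, rel=1e-10)
    assert a.ss_subject + a.ss_measure + a.ss_error == pytest.approx(
        a.ss_total, rel=1e-9
    )


def test_twoway_trivial_cases():
    same = rm.MeasurementMatrix.from_occasions([[1, 2, 3], [1, 2, 3]])
    a = rm.decompose_twoway(same)
    assert a.ms_error == 0 and a.ms_between_measure == 0
    const = rm.MeasurementMatrix(np.full((4, 3), 5.0))
    c = rm.decompose_twoway(const)
    assert c.ss_total == 0 and c.ss_subject == 0 and c.ss_measure == 0 and c.ss_error == 0


def test_oneway_pools_measure_and_error(worked_matrix):
    one = rm.decompose_oneway(worked_matrix)
    two = rm.decompose_twoway(worked_matrix)
    assert one.ss_within == pytest.approx(two.ss_measure + two.ss_error, rel=1e-12)
    assert one.ms_within == pytest.approx(108.4, abs=1e-9)  # (384.4 + 157.6) / 5
    dup = rm.MeasurementMatrix(np.tile([[1.0], [4.0], [9.0]], (1, 3)))
    assert rm.decompose_oneway(dup).ms_within == 0


def test_invalid_designs_rejected():
    with pytest.raises(InvalidDesignError):
        rm.MeasurementMatrix(np.ones((1, 2)))
    with pytest.raises(InvalidDesignError):
        rm.MeasurementMatrix(np.ones((5, 1)))
    with pytest.raises(InvalidDesignError):
        rm.MeasurementMatrix(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ---------------------------------------------------------------------------
# ICC point estimates and confidence bounds
# ---------------------------------------------------------------------------


def test_icc3_worked_example_is_point_six(worked_matrix):
    est = rm.icc(worked_matrix, "icc_3")
    assert est.estimate == pytest.approx(0.60, abs=1e-12)
    assert not est.degenerate
    assert est.lower <= est.estimate <= est.upper


def test_icc_perfect_consistency():
    m = rm.MeasurementMatrix.from_occasions([[1, 3, 6, 9, 12]] * 2)
    est = rm.icc(m, "icc_3")
    assert est.estimate == 1.0
    assert (est.lower, est.upper) == (1.0, 1.0)


def test_icc2_and_icc1_worked_example(worked_matrix):
    # Shrout-Fleiss forms fed with the loop-oracle mean squares
    assert rm.icc(worked_matrix, "icc_2").estimate == pytest.approx(
        118.2 / (157.6 + 39.4 + 2 * (384.4 - 39.4) / 5), rel=1e-9
    )
    assert rm.icc(worked_matrix, "icc_1").estimate == pytest.approx(
        (157.6 - 108.4) / (157.6 + 108.4), rel=1e-9
    )


def test_icc3_ci_matches_f_quantile_oracle(worked_matrix):
    """Recompute the bounds from F = 4.0 with df (4,4) independently."""
    est = rm.icc(worked_matrix, "icc_3", alpha=0.05)
    F = 157.6 / 39.4
    assert F == pytest.approx(4.0, abs=1e-9)
    fl = F / sps.f.ppf(0.975, 4, 4)
    fu = F * sps.f.ppf(0.975, 4, 4)
    assert est.lower == pytest.approx((fl - 1) / (fl + 1), rel=1e-12)
    assert est.upper == pytest.approx((fu - 1) / (fu + 1), rel=1e-12)


@pytest.mark.parametrize("kind", ["icc_1", "icc_2", "icc_3"])
@pytest.mark.parametrize("seed", [7, 8, 9])
def test_icc_agrees_with_pingouin(kind, seed):
    m = random_matrix(np.random.default_rng(seed), n=8, k=2 + seed % 2)
    est = rm.icc(m, kind)
    ref_est, ref_ci = pingouin_icc(m.values, kind)
    assert est.estimate == pytest.approx(ref_est, abs=1e-10)
    # pingouin rounds its CI to 2 decimals
    assert est.lower == pytest.approx(ref_ci[0], abs=5.1e-3)
    assert est.upper == pytest.approx(ref_ci[1], abs=5.1e-3)


def test_icc_ci_operation_matches_icc(worked_matrix):
    a = rm.decompose_twoway(worked_matrix)
    for kind in ("icc_2", "icc_3"):
        est = rm.icc(worked_matrix, kind)
        lo, hi = rm.icc_confidence_interval(a, kind, 5, 2, 0.05)
        assert (lo, hi) == pytest.approx((est.lower, est.upper), rel=1e-12)
    one = rm.decompose_oneway(worked_matrix)
    est1 = rm.icc(worked_matrix, "icc_1")
    assert rm.icc_confidence_interval(one, "icc_1", 5, 2, 0.05) == pytest.approx(
        (est1.lower, est1.upper), rel=1e-12
    )


def test_interval_collapses_as_alpha_grows(worked_matrix):
    wide = rm.icc(worked_matrix, "icc_3", alpha=0.05)
    narrow = rm.icc(worked_matrix, "icc_3", alpha=0.999)
    assert narrow.upper - narrow.lower < 0.1 * (wide.upper - wide.lower)
    assert narrow.lower <= narrow.estimate <= narrow.upper


def test_zero_variance_is_degenerate_not_a_crash():
    est = rm.icc(rm.MeasurementMatrix(np.full((4, 2), 7.0)), "icc_3")
    assert est.degenerate
    assert math.isnan(est.estimate) and math.isnan(est.lower) and math.isnan(est.upper)


def test_negative_icc_survives_untruncated():
    # anti-correlated occasions: between-subject MS below error MS
    m = rm.MeasurementMatrix.from_occasions([[1, 2, 3, 4], [4, 3, 2, 1]])
    est = rm.icc(m, "icc_3")
    assert est.estimate < 0
    assert est.lower <= est.estimate <= est.upper


@given(st.integers(0, 500), st.floats(0.5, 50.0))
def test_icc3_shift_invariant_icc2_decreases(seed, shift):
    """Consistency ignores a per-occasion additive bias; agreement does not."""
    m = random_matrix(np.random.default_rng(seed), n=8, k=3)
    base3 = rm.icc(m, "icc_3")
    assume(not base3.degenerate and base3.estimate > 0)
    shifted = m.values.copy()
    shifted[:, 1] += shift
    ms = rm.MeasurementMatrix(shifted)
    assert rm.icc(ms, "icc_3").estimate == pytest.approx(base3.estimate, rel=1e-9)
    assert rm.icc(ms, "icc_2").estimate < rm.icc(m, "icc_2").estimate


@given(st.integers(0, 500))
def test_icc3_component_identity_and_k2_form(seed):
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, n=6, k=2)
    a = rm.decompose_twoway(m)
    assume(a.ss_total > 1e-8)
    est = rm.icc(m, "icc_3")
    # printed two-occasion form
    assert est.estimate == pytest.approx(
        (a.ms_between_subject - a.ms_error) / (a.ms_between_subject + a.ms_error),
        rel=1e-12,
    )
    # sigma-ratio identity
    c = est.components
    assert est.estimate == pytest.approx(
        c.sigma2_between / (c.sigma2_between + c.sigma2_within), rel=1e-12
    )


# ---------------------------------------------------------------------------
# fixed effects, efficiency, effect size, correlation
# ---------------------------------------------------------------------------


def test_fixed_effects_combine_values():
    assert rm.fixed_effects_combine([2, 4], [1, 1]) == pytest.approx((3.0, 0.5))
    assert rm.fixed_effects_combine([2, 4], [1, 3]) == pytest.approx((2.5, 0.75))
    assert rm.fixed_effects_combine([5.5], [2.0]) == pytest.approx((5.5, 2.0))
    with pytest.raises(ValueError):
        rm.fixed_effects_combine([1, 2], [1, 0])


@given(st.lists(st.floats(-5, 5), min_size=2, max_size=6), st.floats(0.1, 4.0))
def test_fixed_effects_equal_weights_is_mean(betas, v):
    beta, var = rm.fixed_effects_combine(betas, [v] * len(betas))
    assert beta == pytest.approx(np.mean(betas), abs=1e-9)
    assert var < v  # combining shrinks the variance


def test_contrast_efficiency():
    assert rm.contrast_efficiency(np.eye(2), [1, 0]) == pytest.approx(1.0)
    X = np.array([[1.0, 1.0], [1.0, -1.0]])
    assert rm.contrast_efficiency(X, [0, 1]) == pytest.approx(2.0)
    assert rm.contrast_efficiency(2 * X, [0, 1]) == pytest.approx(8.0)  # x4 scaling
    with pytest.raises(SingularDesignError):
        rm.contrast_efficiency(np.ones((4, 2)), [1, 0])
    # invariant to consistent column/contrast permutation
    rng = np.random.default_rng(3)
    D = rng.normal(size=(10, 3))
    c = np.array([1.0, -1.0, 0.5])
    perm = [2, 0, 1]
    assert rm.contrast_efficiency(D[:, perm], c[perm]) == pytest.approx(
        rm.contrast_efficiency(D, c), rel=1e-10
    )


def test_t_to_cohens_d():
    assert rm.t_to_cohens_d(3.2, 64) == pytest.approx(0.4)
    assert rm.t_to_cohens_d(0.0, 10) == 0.0
    assert rm.t_to_cohens_d(3.2, 60) == pytest.approx(3.2 / math.sqrt(60), rel=1e-12)
    with pytest.raises(ValueError):
        rm.t_to_cohens_d(1.0, 0)


def test_pearson_r(worked_matrix):
    a, b = worked_matrix.values[:, 0], worked_matrix.values[:, 1]
    assert rm.pearson_r(a, b) == pytest.approx(1.0)
    assert rm.pearson_r(a, -a) == pytest.approx(-1.0)
    assert rm.pearson_r([1, -1, 1, -1], [1, 1, -1, -1]) == pytest.approx(0.0, abs=1e-12)
    assert math.isnan(rm.pearson_r([1, 1, 1], [1, 2, 3]))
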