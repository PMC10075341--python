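"""Inferential layer: GOF with exposure, exact binomial post hocs, the
debarking GLM, AICc comparison, ANOVA + Tukey."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ursamark.errors import SeparationError
from ursamark.inference import (
    DebarkingModel,
    aicc,
    anova_tukey,
    binomial_posthoc,
    chisq_gof_exposure,
    compare_models_aicc,
    exact_binomial_two_sided,
    fit_debarking_model,
)


# ---------------------------------------------------------------------------
# chi-square GOF


def test_gof_null_case():
    res = chisq_gof_exposure([10, 10], [1, 1], posthoc=False)
    assert res.chi2 == 0.0
    assert res.p == 1.0


def test_gof_hand_arithmetic():
    res = chisq_gof_exposure([15, 5], [1, 1], posthoc=False)
    assert res.chi2 == pytest.approx(5.0)  # 25/10 + 25/10
    assert res.df == 1


def test_gof_exposure_proportional_is_zero():
    res = chisq_gof_exposure([30, 10, 20], [3, 1, 2], posthoc=False)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)


def test_gof_small_expected_warns():
    with pytest.warns(UserWarning, match="below 1"):
        chisq_gof_exposure([5, 1], [100, 1], posthoc=False)


def test_gof_input_validation():
    with pytest.raises(ValueError):
        chisq_gof_exposure([0, 0], [1, 1])
    with pytest.raises(ValueError):
        chisq_gof_exposure([1, 1], [1, 0])


def test_gof_matches_brute_force_oracle():
    """chi2 equals sum((O-E)^2/E) computed independently, random tables."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        n_bins = rng.integers(2, 13)
        observed = rng.integers(1, 50, size=n_bins).astype(float)
        exposure = rng.uniform(0.5, 5, size=n_bins)
        res = chisq_gof_exposure(observed, exposure, posthoc=False)
        total = observed.sum()
        chi2 = 0.0
        for o, w in zip(observed, exposure):
            e = total * w / exposure.sum()
            chi2 += (o - e) ** 2 / e
        assert res.chi2 == pytest.approx(chi2, abs=1e-9)
        assert res.expected.sum() == pytest.approx(total, abs=1e-6)
        assert res.p == pytest.approx(stats.chi2.sf(chi2, n_bins - 1), abs=1e-12)


# ---------------------------------------------------------------------------
# exact binomial post hocs


def _enumeration_oracle(k, n, p0):
    """Tail-doubling p-value by explicit pmf summation."""
    pmf = [stats.binom.pmf(i, n, p0) for i in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    return min(1.0, 2 * min(lower, upper))


def test_exact_binomial_examples():
    assert exact_binomial_two_sided(10, 10, 0.5) == pytest.approx(2 * 0.5**10)
    assert exact_binomial_two_sided(5, 10, 0.5) == 1.0  # central value capped


def test_exact_binomial_matches_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(1, 51))
        k = int(rng.integers(0, n + 1))
        p0 = float(rng.uniform(0.05, 0.95))
        assert exact_binomial_two_sided(k, n, p0) == pytest.approx(
            _enumeration_oracle(k, n, p0), abs=1e-9
        )


def test_binomial_posthoc_bonferroni_cap():
    table = binomial_posthoc([10, 10], [1, 1], m=12)
    assert (table.adjusted_p == 1.0).all()  # raw 1.0 capped
    skewed = binomial_posthoc([20, 0], [1, 1], m=2)
    assert skewed.adjusted_p.iloc[0] == pytest.approx(
        min(1.0, 2 * exact_binomial_two_sided(20, 20, 0.5))
    )
    assert skewed.direction.tolist() == ["above", "below"]


# ---------------------------------------------------------------------------
# debarking GLM


def _simulate_logit(rng, n, beta_j=-0.02, beta_t=0.0, beta_0=0.0, beta_int=0.0):
    jd = rng.integers(1, 366, size=n)
    t = rng.uniform(-1, 1, size=n)
    lp = beta_0 + beta_j * jd + beta_t * t + beta_int * t * jd
    y = rng.random(n) < 1 / (1 + np.exp(-lp))
    return pd.DataFrame({"debark": y, "julian_date": jd, "sun_time": t})


def test_glm_rejects_degenerate_response():
    df = pd.DataFrame({"debark": [0] * 20, "julian_date": range(20)})
    with pytest.raises(ValueError, match="single class"):
        fit_debarking_model(df, ["1", "julian_date"])


def test_glm_null_model_balanced_response():
    df = pd.DataFrame({"debark": [0, 1] * 20, "x": range(40)})
    fit = fit_debarking_model(df, ["1"])
    assert fit.estimate[0] == pytest.approx(0.0, abs=1e-6)


def test_glm_detects_separation():
    x = np.arange(40, dtype=float)
    df = pd.DataFrame({"debark": (x >= 20).astype(float), "x": x})
    with pytest.raises(SeparationError):
        fit_debarking_model(df, ["1", "x"])


def test_glm_ci_is_wald_1_96():
    rng = np.random.default_rng(3)
    fit = fit_debarking_model(_simulate_logit(rng, 400), ["1", "julian_date"])
    np.testing.assert_allclose(fit.ci_lower, fit.estimate - 1.96 * fit.se)
    np.testing.assert_allclose(fit.ci_upper, fit.estimate + 1.96 * fit.se)
    assert "AICc" in fit.summary()


def test_glm_coverage_of_julian_slope():
    """95% Wald CI covers the true slope in >=93 of 100 replicates at n=500."""
    rng = np.random.default_rng(2024)
    covered = 0
    for _ in range(100):
        fit = fit_debarking_model(_simulate_logit(rng, 500), ["1", "julian_date"])
        i = fit.terms.index("julian_date")
        covered += fit.ci_lower[i] <= -0.02 <= fit.ci_upper[i]
    assert covered >= 93


# ---------------------------------------------------------------------------
# AICc comparison


def test_aicc_hand_arithmetic():
    assert aicc(-10, 2, 20) == pytest.approx(24 + 12 / 17)


def test_compare_models():
    rng = np.random.default_rng(5)
    df = _simulate_logit(rng, 300, beta_j=-0.02)
    model = DebarkingModel.from_dataframe(df)
    single = compare_models_aicc([model.fit(["1", "julian_date"])])
    assert single.delta_aicc.tolist() == [0.0]

    f = model.fit(["1", "julian_date"])
    both = compare_models_aicc([f, f])
    assert both.delta_aicc.tolist() == [0.0, 0.0]
    assert both.competing.all()

    other = fit_debarking_model(df.iloc[:200], ["1", "julian_date"])
    with pytest.raises(ValueError, match="sample sizes"):
        compare_models_aicc([f, other])


def test_model_ranking_prefers_true_structure():
    rng = np.random.default_rng(8)
    df = _simulate_logit(rng, 2000, beta_j=-0.02, beta_t=1.5, beta_0=1.0)
    _, comparison = DebarkingModel.from_dataframe(df).fit_all()
    assert "julian_date" in comparison.iloc[0]["model"]
    assert "sun_time" in comparison.iloc[0]["model"]


# ---------------------------------------------------------------------------
# ANOVA + Tukey


def test_anova_hand_arithmetic():
    res = anova_tukey(["a"] * 3 + ["b"] * 3, [1, 2, 3, 2, 3, 4])
    assert res.F == pytest.approx(1.5)
    assert (res.df1, res.df2) == (1, 4)


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(1)
    a, b = rng.normal(size=8), rng.normal(0.5, 1, size=10)
    res = anova_tukey(["a"] * 8 + ["b"] * 10, np.concatenate([a, b]))
    t, _ = stats.ttest_ind(a, b)
    assert res.F == pytest.approx(t**2)


def test_anova_identical_groups():
    res = anova_tukey(["a"] * 3 + ["b"] * 3, [1, 2, 3, 1, 2, 3])
    assert res.F == pytest.approx(0.0)
    assert (res.pairwise.adjusted_p == 1.0).all()


def test_anova_requires_two_obs_per_group():
    with pytest.raises(ValueError, match="fewer than two"):
        anova_tukey(["a", "a", "b"], [1, 2, 3])


def test_anova_matches_sums_of_squares_oracle():
    rng = np.random.default_rng(9)
    for _ in range(20):
        k = int(rng.integers(2, 6))
        sizes = rng.integers(3, 9, size=k)
        values, groups = [], []
        for g, size in enumerate(sizes):
            values.extend(rng.normal(g * 0.3, 1.0, size=size))
            groups.extend([f"g{g}"] * size)
        res = anova_tukey(groups, values)
        values = np.asarray(values)
        grand = values.mean()
        ssb = sum(
            len(v) * (np.mean(v) - grand) ** 2
            for v in (values[np.array(groups) == f"g{g}"] for g in range(k))
        )
        ssw = sum(
            ((v - np.mean(v)) ** 2).sum()
            for v in (values[np.array(groups) == f"g{g}"] for g in range(k))
        )
        f_oracle = (ssb / (k - 1)) / (ssw / (len(values) - k))
        assert res.F == pytest.approx(f_oracle, abs=1e-9)
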