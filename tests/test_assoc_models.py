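"""Unit and property tests for the statistical kernel: IRLS logistic
regression, LRT/AIC model comparison, VIF, Wilcoxon, Spearman, OLS."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from genestrata.assoc_models import (
    DEFAULT_LADDER,
    ModelSpec,
    fit_logistic,
    fit_logistic_frame,
    lrt,
    lrt_identical_ok,
    model_ladder,
    ols_fit,
    spearman,
    vif,
    wilcoxon_rank_sum,
)
from genestrata.errors import ValidationError


class TestFitLogistic:
    def test_intercept_only_matches_log_odds(self):
        X = np.ones((100, 1))
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(X, y, names=["intercept"])
        assert fit.converged
        assert fit.coef[0] == pytest.approx(np.log(30 / 70), abs=1e-6)

    def test_matches_statsmodels_glm(self):
        """Independent cross-check of estimates and SEs against a separate
        GLM implementation on the same data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        eta = 0.5 - 0.8 * X[:, 1] + 0.3 * X[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = fit_logistic(X, y, names=["intercept", "x1", "x2"])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(ours.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.se, ref.bse, rtol=1e-4)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)
        assert ours.aic == pytest.approx(ref.aic, abs=1e-5)

    def test_null_predictor_rarely_significant(self):
        rng = np.random.default_rng(21)
        big_z = 0
        for _ in range(50):
            n = 5000
            x = rng.normal(size=n)
            y = (rng.random(n) < 0.3).astype(float)
            fit = fit_logistic(np.column_stack([np.ones(n), x]), y)
            if abs(fit.z[1]) >= 4:
                big_z += 1
        assert big_z == 0

    def test_aic_identity(self):
        rng = np.random.default_rng(2)
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 0.4).astype(float)
        fit = fit_logistic(X, y)
        assert fit.aic == pytest.approx(2 * fit.df - 2 * fit.loglik, abs=1e-9)

    def test_separation_flagged_not_raised(self):
        x = np.r_[np.linspace(-2, -0.1, 20), np.linspace(0.1, 2, 20)]
        y = (x > 0).astype(float)
        fit = fit_logistic(np.column_stack([np.ones(40), x]), y)
        assert fit.separated
        assert not fit.converged

    def test_rank_deficiency_names_collinear_terms(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, x])
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(ValidationError, match="rank-deficient"):
            fit_logistic(X, y, names=["intercept", "a", "a_copy"])

    def test_nonbinary_response_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic(np.ones((10, 1)), np.arange(10.0))

    def test_recovers_generator_truth_coefficients(self, generated_cohort):
        """Fitting the generating term set on a synthetic cohort recovers the
        true coefficients (including D = 0.29) within the 95% CI."""
        cohort, _ = generated_cohort
        spec = ModelSpec(("D", "lnL", "T", "DxlnL"))
        fit = fit_logistic_frame(cohort.to_frame(), spec)
        ci = fit.conf_int()
        true = {"D": 0.29, "lnL": 0.22, "T": 0.0041, "DxlnL": -0.027}
        for term, beta in true.items():
            i = fit.names.index(term)
            assert ci[i, 0] <= beta <= ci[i, 1], (term, ci[i], beta)


class TestLRT:
    @staticmethod
    def _two_fits(seed=4, n=600):
        rng = np.random.default_rng(seed)
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.5 * x1))).astype(float)
        nested = fit_logistic(
            np.column_stack([np.ones(n), x1]), y,
            names=["intercept", "x1"], spec=ModelSpec(("x1",)),
        )
        full = fit_logistic(
            np.column_stack([np.ones(n), x1, x2]), y,
            names=["intercept", "x1", "x2"], spec=ModelSpec(("x1", "x2")),
        )
        return nested, full

    def test_statistic_nonnegative_and_chi2_p(self):
        nested, full = self._two_fits()
        res = lrt(nested, full)
        assert res.statistic >= 0
        assert res.p_value == pytest.approx(
            stats.chi2.sf(res.statistic, 1), abs=1e-12
        )

    def test_known_loglik_difference(self):
        nested, full = self._two_fits()
        nested.loglik, full.loglik = 100.0, 110.0
        res = lrt(nested, full)
        assert res.statistic == pytest.approx(20.0)
        assert res.p_value == pytest.approx(7.744216e-6, rel=1e-4)

    def test_identical_specs_p_one(self):
        nested, _ = self._two_fits()
        res = lrt_identical_ok(nested, nested)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_non_nested_rejected(self):
        nested, full = self._two_fits()
        with pytest.raises(ValidationError):
            lrt(full, nested)


class TestModelLadder:
    def test_selects_generating_term_set(self, generated_cohort):
        cohort, _ = generated_cohort
        ladder = model_ladder(cohort.to_frame(), DEFAULT_LADDER)
        assert set(ladder.selected.spec.terms) == {"D", "lnL", "T", "DxlnL"}

    def test_tie_break_by_spec_order(self):
        rng = np.random.default_rng(6)
        n = 300
        frame = _toy_frame(rng, n)
        specs = [ModelSpec(("T",), "A"), ModelSpec(("T",), "B")]
        ladder = model_ladder(frame, specs)
        assert ladder.table.iloc[0]["model"] == "A"
        aics = ladder.table["aic"].to_numpy()
        assert aics[0] == pytest.approx(aics[1])

    def test_failed_spec_annotated_not_fatal(self):
        rng = np.random.default_rng(8)
        frame = _toy_frame(rng, 200)
        frame["gene_length"] = frame["protein_length"]  # makes lnL_g == lnL
        ladder = model_ladder(
            frame,
            [ModelSpec(("lnL",), "a"), ModelSpec(("lnL", "lnL_g"), "collinear"),
             ModelSpec(("T",), "b")],
        )
        assert 1 in ladder.errors
        assert ladder.selected is not None


def _toy_frame(rng, n):
    import pandas as pd

    L = np.exp(rng.normal(6, 0.5, n))
    return pd.DataFrame(
        {
            "protein_length": L,
            "gene_length": L * 30,
            "dnv_burden": rng.poisson(2, n).astype(float),
            "rare_burden": rng.poisson(3, n).astype(float),
            "age_mya": rng.choice([74, 159, 312, 435], n).astype(float),
            "is_disease": (rng.random(n) < 0.3).astype(int),
        }
    )


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        X = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        assert np.allclose(vif(X).to_numpy(), 1.0)

    def test_duplicate_predictor_infinite(self):
        x = np.arange(10.0)
        res = vif(np.column_stack([x, x]))
        assert np.isinf(res).all()

    def test_known_correlation_closed_form(self):
        rng = np.random.default_rng(9)
        n = 200_000
        z = rng.normal(size=n)
        x1 = z + 0.75 * rng.normal(size=n)
        x2 = 0.8 * (x1) + 0.6 * rng.normal(size=n) * np.std(x1)
        r = np.corrcoef(x1, x2)[0, 1]
        res = vif(np.column_stack([x1, x2]))
        assert res.iloc[0] == pytest.approx(1 / (1 - r**2), rel=1e-9)

    def test_vif_at_least_one(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(100, 4))
        assert (vif(X) >= 1.0 - 1e-12).all()


def _exact_rank_sum_p(x, y):
    """Enumeration oracle: two-sided p over all C(n+m, n) group labelings."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    n = len(x)
    stats_all = [
        sum(pooled.index(v) + 1 for v in comb)
        for comb in itertools.combinations(pooled, n)
    ]
    mean = (len(x) * (len(pooled) + 1)) / 2
    extreme = sum(
        1 for s in stats_all if abs(s - mean) >= abs(obs - mean) - 1e-12
    )
    return extreme / len(stats_all)


class TestWilcoxonRankSum:
    def test_small_sample_exact_p(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_samples_degenerate(self):
        res = wilcoxon_rank_sum([5, 5, 5], [5, 5])
        assert res.degenerate and res.p_value == 1.0

    def test_same_multiset_p_near_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value > 0.9

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        res = wilcoxon_rank_sum(x, y)
        assert res.method == "normal-approx"
        assert res.p_value < 1e-10

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 60), min_size=1, max_size=6, unique=True),
        y=st.lists(st.integers(61, 120), min_size=1, max_size=6, unique=True),
    )
    def test_exact_p_matches_enumeration(self, x, y):
        """Property: for tie-free samples with min(n) <= 8, the exact p equals
        full enumeration over group labelings."""
        # shuffle values across groups so the split is nontrivial
        pooled = x + y
        x2, y2 = pooled[::2], pooled[1::2]
        if not x2 or not y2:
            return
        res = wilcoxon_rank_sum(x2, y2)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(_exact_rank_sum_p(x2, y2), abs=1e-12)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert spearman(x, sorted(x)).statistic is not None
        assert spearman(x, x).statistic == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8)

    def test_constant_vector_flagged(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert res.degenerate


class TestOLS:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = ols_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        fit = ols_fit([1, 2, 3, 4], [5, 5, 5, 5])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.3, 2.9, 5.1, 8.2, 12.5])
        A = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        fit = ols_fit(x, y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        np.testing.assert_allclose(fit.fitted, A @ beta, atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            ols_fit([2, 2, 2], [1, 2, 3])
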