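import numpy as np
import pandas as pd
import pytest

from sfcoupling.datatypes import AnalysisConfig
from sfcoupling.inference import (
    compare_groups,
    fwe_correct,
    partial_correlation,
    residualize,
    route_test,
)

from _oracles import pearson_oracle


def _covariates(rng, n):
    return pd.DataFrame(
        {
            "age": rng.uniform(55, 80, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.uniform(6, 16, n),
        }
    )


class TestResidualize:
    def test_outcome_linear_in_age_leaves_zero_residuals(self):
        rng = np.random.default_rng(0)
        cov = _covariates(rng, 40)
        y = 2.0 + 0.5 * cov["age"].to_numpy()
        res = residualize(y, cov)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_orthogonal_outcome_is_just_demeaned(self):
        rng = np.random.default_rng(1)
        n = 2000
        cov = _covariates(rng, n)
        y = rng.standard_normal(n)
        res = residualize(y, cov)
        assert abs(res.mean()) < 1e-10
        # orthogonality only approximate in finite samples; residual variance
        # must essentially equal the demeaned variance
        assert np.var(res) == pytest.approx(np.var(y - y.mean()), rel=0.01)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        cov = _covariates(rng, 50)
        y = rng.standard_normal(50)
        x = np.column_stack(
            [np.ones(50), cov["age"], cov["sex"], cov["education"]]
        )
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(residualize(y, cov), y - x @ beta, atol=1e-10)

    def test_rank_deficient_design_names_the_collinear_column(self):
        rng = np.random.default_rng(3)
        cov = _covariates(rng, 30)
        cov["education"] = 2.0 * cov["age"]  # collinear with age
        with pytest.raises(ValueError, match="education"):
            residualize(rng.standard_normal(30), cov)


class TestRouteTest:
    def test_normal_samples_route_to_t(self):
        rng = np.random.default_rng(10)
        a, b = rng.standard_normal(30), rng.standard_normal(30) + 0.2
        res = route_test(a, b)
        assert res.test_used == "t"

    def test_exponential_samples_route_to_mann_whitney(self):
        rng = np.random.default_rng(11)
        a, b = rng.exponential(1.0, 30), rng.exponential(1.0, 30)
        res = route_test(a, b)
        assert res.test_used == "mann_whitney"

    def test_identical_samples_give_null_statistic(self):
        rng = np.random.default_rng(12)
        a = rng.standard_normal(20)
        res = route_test(a, a.copy())
        assert res.p_raw > 0.99
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_categorical_goes_to_chi_squared(self):
        a = np.array(["male"] * 12 + ["female"] * 8)
        b = np.array(["male"] * 7 + ["female"] * 13)
        res = route_test(a, b, kind="categorical")
        assert res.test_used == "chi_squared"
        assert 0 <= res.p_raw <= 1

    def test_degenerate_constant_input_is_an_error(self):
        with pytest.raises(ValueError, match="identical"):
            route_test(np.full(5, 2.0), np.full(6, 2.0))


class TestFweCorrect:
    def _results(self, p_values):
        return [
            route_test(np.arange(5, dtype=float) + p, np.arange(5, dtype=float))
            for p in p_values
        ]

    def test_bonferroni_multiplies_by_family_size(self):
        from sfcoupling.inference import ComparisonResult

        results = [
            ComparisonResult("f1", "t", 2.0, 0.01),
            ComparisonResult("f2", "t", 1.0, 0.04),
        ]
        out = fwe_correct(results, method="bonferroni")
        assert out[0].p_fwe == pytest.approx(0.02)
        assert out[1].p_fwe == pytest.approx(0.08)

    def test_single_feature_needs_no_correction(self):
        from sfcoupling.inference import ComparisonResult

        res = [ComparisonResult("f", "t", 2.0, 0.03)]
        assert fwe_correct(res, method="bonferroni")[0].p_fwe == pytest.approx(0.03)

    def test_permutation_maxT_p_fwe_dominates_p_raw(self):
        rng = np.random.default_rng(0)
        n, m = 40, 15
        x = rng.standard_normal((n, m))
        is_a = np.zeros(n, dtype=bool)
        is_a[:20] = True
        results = [
            route_test(x[is_a, j], x[~is_a, j], feature=f"f{j}") for j in range(m)
        ]
        out = fwe_correct(
            results, method="permutation_maxT", residuals=x, is_group_a=is_a,
            permutations=300, seed=5,
        )
        for r in out:
            assert r.p_fwe >= r.p_raw - 1e-12
            assert 0 < r.p_fwe <= 1

    def test_empty_family_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            fwe_correct([], method="bonferroni")

    def test_maxT_invariant_to_monotone_feature_rescaling_when_rank_based(self):
        rng = np.random.default_rng(1)
        n, m = 30, 6
        x = rng.standard_normal((n, m))
        is_a = np.zeros(n, dtype=bool)
        is_a[:15] = True

        def pvals(data):
            results = [route_test(data[is_a, j], data[~is_a, j]) for j in range(m)]
            out = fwe_correct(results, method="permutation_maxT", residuals=data,
                              is_group_a=is_a, permutations=200, seed=9, rank_based=True)
            return [r.p_fwe for r in out]

        scaled = x.copy()
        scaled[:, 0] = np.exp(scaled[:, 0])
        scaled[:, 1] = scaled[:, 1] * 17.0 + 3.0
        assert pvals(x) == pvals(scaled)


class TestCompareGroups:
    def _cohort_frames(self, rng, n_per_group=20, m=8, shift=0.0):
        n = 2 * n_per_group
        manifest = pd.DataFrame(
            {
                "group": ["VCI"] * n_per_group + ["HC"] * n_per_group,
                "age": rng.uniform(55, 80, n),
                "sex": rng.choice(["male", "female"], n),
                "education": rng.uniform(6, 16, n),
            },
            index=[f"S{i:02d}" for i in range(n)],
        )
        features = pd.DataFrame(
            rng.standard_normal((n, m)),
            index=manifest.index,
            columns=[f"f{j}" for j in range(m)],
        )
        features.iloc[:n_per_group, 0] += shift
        return features, manifest

    def test_planted_shift_is_detected_with_direction(self):
        rng = np.random.default_rng(21)
        features, manifest = self._cohort_frames(rng, shift=2.0)
        cfg = AnalysisConfig(permutations=500, seed=3)
        results = compare_groups(features, manifest, cfg)
        by_name = {r.feature: r for r in results}
        assert by_name["f0"].p_fwe < 0.05
        assert by_name["f0"].direction == 1
        others = [r for r in results if r.feature != "f0"]
        assert sum(r.p_fwe < 0.05 for r in others) == 0

    def test_constant_feature_is_an_error_naming_it(self):
        rng = np.random.default_rng(22)
        features, manifest = self._cohort_frames(rng)
        features["f3"] = 1.0
        with pytest.raises(ValueError, match="f3"):
            compare_groups(features, manifest, AnalysisConfig(permutations=50))


def test_null_cohort_p_values_are_uniform():
    """With every planted effect zero, raw p-values of the nodal coupling
    contrast are approximately uniform (Kolmogorov-Smirnov) across
    simulated contrasts."""
    from scipy import stats as sps

    from sfcoupling.evaluation import coupling_contrast
    from sfcoupling.simulate import SimulationParams, generate_cohort

    p_values = []
    for rep in range(3):
        params = SimulationParams(
            n_hc=20, n_vci=20, n_timepoints=200, coupling_boost=0.0,
            vci_structural_deficit=0.0, seed=9000 + rep,
        )
        cohort, _ = generate_cohort(params)
        results = coupling_contrast(cohort, AnalysisConfig(min_coupling_pairs=5),
                                    permutations=100, seed=rep)
        p_values += [r.p_raw for r in results]
    assert len(p_values) >= 200
    assert sps.kstest(np.asarray(p_values), "uniform").pvalue > 0.01


class TestPartialCorrelation:
    def test_reduces_to_zero_order_when_covariates_are_irrelevant(self):
        rng = np.random.default_rng(30)
        n = 500
        cov = _covariates(rng, n)
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        res = partial_correlation(x, y, cov, method="pearson")
        # orthogonalizing against irrelevant covariates leaves the correlation
        assert res.rho_partial == pytest.approx(pearson_oracle(x, y), abs=0.02)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(31)
        cov = _covariates(rng, 30)
        x = rng.standard_normal(30)
        res = partial_correlation(x, x.copy(), cov, method="pearson")
        assert res.rho_partial == pytest.approx(1.0, abs=1e-10)
        assert res.p_raw == pytest.approx(0.0, abs=1e-12)

    def test_confound_attenuation_matches_residual_oracle(self):
        rng = np.random.default_rng(32)
        n = 200
        cov = _covariates(rng, n)
        z = cov["age"].to_numpy()
        x = z + rng.standard_normal(n)
        y = z + rng.standard_normal(n)
        res = partial_correlation(x, y, cov, method="pearson")
        rx = residualize(x, cov)
        ry = residualize(y, cov)
        oracle = pearson_oracle(rx, ry)
        assert res.rho_partial == pytest.approx(oracle, abs=1e-10)
        assert abs(res.rho_partial) < abs(pearson_oracle(x, y))  # attenuated

    def test_insufficient_n_is_an_error(self):
        rng = np.random.default_rng(33)
        cov = _covariates(rng, 5)
        with pytest.raises(ValueError, match="n > 5"):
            partial_correlation(np.ones(5), np.ones(5), cov)
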