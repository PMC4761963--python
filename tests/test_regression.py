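"""Model search, bootstrap RC distributions, significance, classification."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import tfbsreg as t
from tfbsreg.regression import (
    BudgetExceededError,
    RCDistribution,
    _criterion,
    calibrated_penalty,
)
from tfbsreg.scan import FeatureMatrix


def make_fm(X, y, names=None):
    names = names or [f"m{j+1}" for j in range(X.shape[1])]
    values = pd.DataFrame(
        X, index=pd.Index([f"g{i}" for i in range(len(X))], name="gene_id"),
        columns=names,
    )
    return FeatureMatrix(values, pd.Series(np.asarray(y, float), index=values.index))


class TestFitLinear:
    def test_exact_interpolation(self, small_features):
        fit = t.fit_linear(small_features, ["m1"])
        assert fit.coefficients["m1"] == pytest.approx(2.0, abs=1e-9)
        assert fit.coefficients["intercept"] == pytest.approx(1.0, abs=1e-9)

    def test_empty_subset_gives_mean_intercept(self, small_features):
        fit = t.fit_linear(small_features, [])
        assert fit.coefficients["intercept"] == pytest.approx(
            small_features.response.mean(), abs=1e-12
        )

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        fm = make_fm(X, y)
        fit = t.fit_linear(fm, fm.tfbs_ids)
        Z = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        got = [fit.coefficients["intercept"]] + [
            fit.coefficients[m] for m in fm.tfbs_ids
        ]
        np.testing.assert_allclose(got, beta, atol=1e-9)

    def test_matches_statsmodels_cross_check(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        X = rng.poisson(1.0, size=(30, 2)).astype(float)
        y = 0.5 + 1.2 * X[:, 0] + rng.normal(0, 0.3, 30)
        fm = make_fm(X, y)
        fit = t.fit_linear(fm, fm.tfbs_ids)
        sm_fit = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(
            [fit.coefficients["intercept"], fit.coefficients["m1"],
             fit.coefficients["m2"]],
            sm_fit.params, atol=1e-9,
        )
        assert fit.fit_criterion == pytest.approx(
            _criterion("bic", 30, float(sm_fit.ssr), 3, float(sm_fit.centered_tss)),
            abs=1e-9,
        )

    def test_collinear_subset_rejected(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        fm = make_fm(np.column_stack([X[:, 1], 2 * X[:, 1]]), np.arange(10))
        with pytest.raises(ValueError, match="rank"):
            t.fit_linear(fm, fm.tfbs_ids)


class TestSearchModels:
    def test_exhaustive_equals_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(1.0, size=(25, 5)).astype(float)
        y = rng.normal(size=25)
        fm = make_fm(X, y)
        best = t.search_models(fm, max_model_size=2, mode="exhaustive")
        # oracle: evaluate all C(5,0)+C(5,1)+C(5,2)=16 subsets independently
        cands = []
        for k in range(3):
            for sub in combinations(fm.tfbs_ids, k):
                try:
                    cands.append(t.fit_linear(fm, list(sub)))
                except ValueError:
                    pass
        oracle = min(cands, key=lambda f: (f.fit_criterion, len(f.selected_tfbs)))
        assert best.fit_criterion == pytest.approx(oracle.fit_criterion, abs=1e-9)
        assert set(best.selected_tfbs) == set(oracle.selected_tfbs)

    def test_noiseless_planted_model_is_selected(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(1.5, size=(30, 4)).astype(float)
        y = 1.0 + 2.5 * X[:, 1]
        fm = make_fm(X, y)
        best = t.search_models(fm, max_model_size=2, mode="exhaustive")
        assert best.selected_tfbs == ("m2",)
        assert best.coefficients["m2"] == pytest.approx(2.5, abs=1e-6)

    def test_forward_equals_exhaustive_on_orthogonal_design(self):
        n = 64
        X = np.zeros((n, 3))
        X[:, 0] = np.tile([0, 1], n // 2)
        X[:, 1] = np.tile([0, 0, 1, 1], n // 4)
        X[:, 2] = np.tile([0] * 4 + [1] * 4, n // 8)
        rng = np.random.default_rng(4)
        y = 2.0 * X[:, 0] - 1.5 * X[:, 1] + rng.normal(0, 0.1, n)
        fm = make_fm(X, y)
        ex = t.search_models(fm, max_model_size=3, mode="exhaustive")
        fw = t.search_models(fm, max_model_size=3, mode="forward")
        assert set(ex.selected_tfbs) == set(fw.selected_tfbs)

    def test_budget_exceeded_directs_to_forward(self):
        rng = np.random.default_rng(5)
        fm = make_fm(rng.normal(size=(40, 25)), rng.normal(size=40))
        with pytest.raises(BudgetExceededError, match="forward"):
            t.search_models(fm, max_model_size=10, mode="exhaustive", budget=100)


class TestBootstrapRCs:
    @pytest.fixture(scope="class")
    def planted_fm(self):
        rng = np.random.default_rng(7)
        X = rng.poisson(1.0, size=(120, 4)).astype(float)
        y = 1.0 + 2.0 * X[:, 0] + rng.normal(0, 0.5, 120)
        return make_fm(X, y)

    def test_every_distribution_has_exactly_B_entries(self, planted_fm):
        dists = t.bootstrap_rcs(planted_fm, max_model_size=3, B=50, seed=1)
        assert set(dists) == set(planted_fm.tfbs_ids)
        for d in dists.values():
            assert len(d.rcs) == 50
            assert d.mean_rc == pytest.approx(d.rcs.mean(), abs=1e-12)

    def test_seed_determinism(self, planted_fm):
        a = t.bootstrap_rcs(planted_fm, max_model_size=3, B=30, seed=9)
        b = t.bootstrap_rcs(planted_fm, max_model_size=3, B=30, seed=9)
        for m in a:
            np.testing.assert_array_equal(a[m].rcs, b[m].rcs)

    def test_planted_tfbs_strongly_significant(self, planted_fm):
        dists = t.bootstrap_rcs(planted_fm, max_model_size=3, B=100, seed=3)
        sig, sign = t.test_rcs(dists["m1"])
        assert sig and sign == 1
        assert dists["m1"].mean_rc > 1.0
        assert dists["m1"].selection_frequency > 0.95

    def test_subset_scheme_same_contract(self, planted_fm):
        dists = t.bootstrap_rcs(
            planted_fm, max_model_size=3, B=40, seed=2, scheme="subset"
        )
        for d in dists.values():
            assert len(d.rcs) == 40


class TestTestRCs:
    def test_all_zero_not_significant(self):
        d = RCDistribution("m", np.zeros(100))
        sig, sign = t.test_rcs(d, 10)
        assert not sig and sign == 0

    def test_constant_nonzero_significant_by_convention(self):
        d = RCDistribution("m", np.full(100, 3.0))
        sig, sign = t.test_rcs(d, 10)
        assert sig and sign == 1

    def test_null_false_positive_rate_under_bonferroni(self):
        """N(0,1) RC draws, 100 TFBSs tested: FPR at Bonferroni 0.01 <= 1%."""
        rng = np.random.default_rng(11)
        n_sig = 0
        reps = 20
        for _ in range(reps):
            for _ in range(100):
                d = RCDistribution("m", rng.normal(0, 1, 1000))
                sig, _ = t.test_rcs(d, 100, alpha=0.01)
                n_sig += sig
        assert n_sig / (reps * 100) <= 0.01

    def test_bonferroni_stored_in_distribution(self):
        d = RCDistribution("m", np.array([0.1, 0.2, 0.15, 0.12]), n_tested=5)
        assert d.p_bonferroni == pytest.approx(min(1.0, d.p_raw * 5))


class TestClassifyTFBS:
    @staticmethod
    def _dist(mean, significant=True):
        if significant:
            rcs = np.full(100, mean) + np.linspace(-0.01, 0.01, 100)
        else:
            rcs = np.linspace(-1, 1, 100)  # mean 0, wide: never significant
        return RCDistribution("x", rcs, n_tested=1)

    def test_constructed_statuses(self):
        resA = {
            "t_ident": self._dist(2.0),
            "t_opp": self._dist(1.5),
            "t_uniqA": self._dist(-1.0),
            "t_uniqB": self._dist(0.0, significant=False),
            "t_ns": self._dist(0.0, significant=False),
        }
        resB = {
            "t_ident": self._dist(1.0),
            "t_opp": self._dist(-1.5),
            "t_uniqA": self._dist(0.0, significant=False),
            "t_uniqB": self._dist(2.0),
            "t_ns": self._dist(0.0, significant=False),
        }
        cls = t.classify_tfbs(resA, resB)
        assert cls.status == {
            "t_ident": "identical",
            "t_opp": "opposite",
            "t_uniqA": "unique_to_A",
            "t_uniqB": "unique_to_B",
            "t_ns": "not_significant",
        }
        assert cls.counts()["identical"] == 1

    def test_mismatched_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            t.classify_tfbs({"a": self._dist(1)}, {"b": self._dist(1)})


class TestRefitExcluding:
    def test_no_exclusion_is_identical_to_baseline(self):
        rng = np.random.default_rng(13)
        X = rng.poisson(1.0, size=(60, 3)).astype(float)
        y = 1.0 + 1.5 * X[:, 0] + rng.normal(0, 0.4, 60)
        fm = make_fm(X, y)
        base = t.bootstrap_rcs(fm, max_model_size=2, B=30, seed=4)
        after, shifts = t.refit_excluding(fm, set(), max_model_size=2, B=30, seed=4)
        for m in base:
            np.testing.assert_array_equal(after[m].rcs, base[m].rcs)
        assert all(abs(s) < 1e-12 for s in shifts.values())

    def test_excluding_all_carriers_kills_selection(self):
        rng = np.random.default_rng(14)
        X = rng.poisson(1.0, size=(80, 2)).astype(float)
        X[40:, 1] = 0.0  # m2 carried only by the first 40 genes
        X[:40, 1] += 1.0
        y = 1.0 + 2.0 * X[:, 1] + rng.normal(0, 0.3, 80)
        fm = make_fm(X, y)
        carriers = {f"g{i}" for i in range(40)}
        after, _ = t.refit_excluding(fm, carriers, max_model_size=2, B=40, seed=5)
        assert after["m2"].selection_frequency <= 0.05

    def test_too_few_remaining_genes_errors(self):
        rng = np.random.default_rng(15)
        fm = make_fm(rng.poisson(1.0, (10, 2)).astype(float), rng.normal(size=10))
        with pytest.raises(ValueError, match="remain"):
            t.refit_excluding(fm, {f"g{i}" for i in range(9)}, max_model_size=2, B=10)


def test_calibrated_penalty_exceeds_bic_scale():
    # the bootstrap selection threshold must be far stricter than BIC's
    assert calibrated_penalty(10, 200) > np.log(300) * 2


def test_rc_quantile_summary_shape():
    dists = {
        "a": RCDistribution("a", np.linspace(-1, 1, 50)),
        "b": RCDistribution("b", np.zeros(50)),
    }
    q = t.rc_quantiles(dists)
    assert list(q.columns) == ["q5", "q25", "q50", "q75", "q95"]
    assert q.loc["a", "q50"] == pytest.approx(0.0, abs=1e-9)
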