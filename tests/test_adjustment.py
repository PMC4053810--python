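import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import methdecon as md
from methdecon._lm import CollinearityError
from methdecon.adjustment import (
    CetsProfiles,
    cets_bias,
    cets_transform,
    naive_adjust,
    ruv2_adjust,
    scree_singular_values,
    univariate_ewas,
)
from methdecon.deconvolution import CellProportions
from methdecon.matrix_io import BetaMatrix, ValidationError


def _beta_from(values, sample_ids=None):
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return BetaMatrix(
        values=pd.DataFrame(
            values,
            index=[f"cg{i}" for i in range(values.shape[0])],
            columns=sample_ids,
        )
    )


def _null_cohort(rng, n_probes=300, n_samples=40):
    beta = _beta_from(np.clip(rng.normal(0.5, 0.05, (n_probes, n_samples)), 0, 1))
    age = pd.Series(rng.uniform(20, 70, n_samples), index=beta.sample_ids)
    return beta, age


class TestUnivariateEwas:
    def test_exact_slope_recovered(self):
        ages = np.linspace(20, 60, 20)
        y = 0.3 + 0.001 * ages
        beta = _beta_from(np.vstack([y, np.full(20, 0.5)]))
        res = univariate_ewas(beta, pd.Series(ages, index=beta.sample_ids))
        assert res.table["estimate"].iloc[0] == pytest.approx(0.001, abs=1e-12)
        assert res.table["p"].iloc[0] < 1e-12

    def test_matches_statsmodels_single_probe(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(50)
        beta, age = _null_cohort(rng, n_probes=5)
        res = univariate_ewas(beta, age)
        y = beta.values.iloc[2].to_numpy()
        fit = sm.OLS(y, sm.add_constant(age.to_numpy())).fit()
        assert res.table["t"].iloc[2] == pytest.approx(fit.tvalues[1], abs=1e-10)
        assert res.table["p"].iloc[2] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_permuted_age_rejection_rate_nominal(self):
        rng = np.random.default_rng(51)
        beta, age = _null_cohort(rng, n_probes=4000, n_samples=50)
        perm = pd.Series(
            rng.permutation(age.to_numpy()), index=age.index
        )
        res = univariate_ewas(beta, perm)
        rate = (res.table["p"] < 0.05).mean()
        assert 0.035 < rate < 0.065

    def test_confounded_covariate_errors(self):
        rng = np.random.default_rng(52)
        beta, age = _null_cohort(rng, n_probes=10, n_samples=20)
        plate = pd.DataFrame({"plate": 2.0 * age.to_numpy()}, index=age.index)
        with pytest.raises(CollinearityError, match="plate"):
            univariate_ewas(beta, age, covariates=plate)

    def test_fdr_threshold_is_min_significant_t(self):
        rng = np.random.default_rng(53)
        beta, age = _null_cohort(rng, n_probes=200, n_samples=40)
        # plant strong signal in 30 probes
        vals = beta.values.to_numpy()
        vals[:30] = np.clip(
            0.3 + 0.004 * age.to_numpy() + rng.normal(0, 0.02, (30, 40)), 0, 1
        )
        res = univariate_ewas(_beta_from(vals), age)
        sig = res.table[res.table["significant"]]
        assert len(sig) > 0
        assert res.fdr_threshold_t == pytest.approx(sig["t"].abs().min())
        assert (res.table["t"].abs() >= res.fdr_threshold_t).eq(
            res.table["significant"]
        ).all()


class TestBhFdr:
    def test_significance_calls_match_step_up_oracle(self):
        """The FDR calls attached to an EWAS follow the BH step-up rule."""
        rng = np.random.default_rng(54)
        beta, age = _null_cohort(rng, n_probes=90, n_samples=30)
        vals = beta.values.to_numpy()
        vals[:15] = np.clip(
            0.3 + 0.003 * age.to_numpy() + rng.normal(0, 0.03, (15, 30)), 0, 1
        )
        res = univariate_ewas(_beta_from(vals), age)
        p = res.table["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        passing = np.flatnonzero(
            p[order] <= 0.05 * np.arange(1, m + 1) / m
        )
        k = passing.max() + 1 if len(passing) else 0
        oracle_reject = np.zeros(m, bool)
        oracle_reject[order[:k]] = True
        assert (res.table["significant"].to_numpy() == oracle_reject).all()


class TestNaiveAdjust:
    def _confounded(self, seed=55):
        cfg = md.SimulationConfig(
            seed=seed, n_probes=600, n_mixture_samples=80, trend_amplitude=0.3
        )
        beta, sheet, truth = md.simulate_confounded_ewas(cfg)
        props = CellProportions(
            proportions=truth.proportions,
            constraint_mode="truth",
            residual_norm=pd.Series(0.0, index=truth.proportions.index),
        )
        return beta, sheet.table["age"], props

    def test_attenuates_composition_driven_t(self):
        beta, age, props = self._confounded()
        uni = univariate_ewas(beta, age)
        naive = naive_adjust(beta, age, props)
        assert (
            naive.table["t"].abs().mean() < uni.table["t"].abs().mean()
        )
        assert naive.meta["dropped_cell_type"] == props.cell_types[-1]

    def test_constant_composition_equals_univariate(self):
        rng = np.random.default_rng(56)
        beta, age = _null_cohort(rng, n_probes=50)
        props = CellProportions(
            proportions=pd.DataFrame(
                1.0 / 3, index=beta.sample_ids, columns=list("ABC")
            ),
            constraint_mode="simplex",
            residual_norm=pd.Series(0.0, index=beta.sample_ids),
        )
        # constant composition carries no adjustment information: the naive
        # model reduces to the univariate one
        naive = naive_adjust(beta, age, props)
        uni = univariate_ewas(beta, age)
        assert np.allclose(naive.table["t"], uni.table["t"], atol=1e-10)

    def test_all_columns_would_be_collinear(self):
        rng = np.random.default_rng(57)
        beta, age = _null_cohort(rng, n_probes=20)
        W = rng.dirichlet(np.ones(3), len(age.index))
        props = CellProportions(
            proportions=pd.DataFrame(W, index=beta.sample_ids, columns=list("ABC")),
            constraint_mode="simplex",
            residual_norm=pd.Series(0.0, index=beta.sample_ids),
        )
        # with one column dropped the fit succeeds
        res = naive_adjust(beta, age, props)
        assert res.method == "naive"
        # manually adding all columns trips the simplex collinearity
        with pytest.raises(CollinearityError):
            univariate_ewas(beta, age, covariates=props.proportions)


class TestRuv2:
    def test_k_zero_identical_to_univariate(self):
        rng = np.random.default_rng(58)
        beta, age = _null_cohort(rng)
        uni = univariate_ewas(beta, age)
        ruv = ruv2_adjust(beta, age, beta.probe_ids[:50], k=0)
        assert np.allclose(ruv.table["t"], uni.table["t"], atol=1e-10)

    def test_pure_confounding_attenuated(self):
        cfg = md.SimulationConfig(
            seed=59, n_probes=1200, n_mixture_samples=100, trend_amplitude=0.3
        )
        beta, sheet, truth = md.simulate_confounded_ewas(cfg)
        age = sheet.table["age"]
        uni = univariate_ewas(beta, age)
        controls = pd.Index(truth.marker_ids())
        ruv = ruv2_adjust(beta, age, controls, k=5)
        assert uni.n_significant > 50
        assert ruv.n_significant < 0.1 * uni.n_significant
        assert ruv.table["t"].abs().mean() < uni.table["t"].abs().mean()

    def test_power_retained_for_true_signal_orthogonal_to_composition(self):
        cfg = md.SimulationConfig(
            seed=60,
            n_probes=1500,
            n_mixture_samples=150,
            trend_amplitude=0.3,
            n_age_effect_probes=25,
            age_effect_slope=0.004,
        )
        beta, sheet, truth = md.simulate_confounded_ewas(cfg)
        age = sheet.table["age"]
        controls = pd.Index(truth.marker_ids())
        ruv = ruv2_adjust(beta, age, controls, k=5)
        # oracle adjusts for the true composition instead of surrogates
        props = CellProportions(
            proportions=truth.proportions,
            constraint_mode="truth",
            residual_norm=pd.Series(0.0, index=truth.proportions.index),
        )
        oracle = naive_adjust(beta, age, props)
        affected = truth.age_effects.index
        power_ruv = ruv.table.loc[affected, "significant"].mean()
        power_oracle = oracle.table.loc[affected, "significant"].mean()
        assert power_ruv >= power_oracle - 0.10

    def test_invalid_k_rejected(self):
        rng = np.random.default_rng(61)
        beta, age = _null_cohort(rng, n_probes=30, n_samples=10)
        with pytest.raises(ValidationError, match="sample"):
            ruv2_adjust(beta, age, beta.probe_ids[:20], k=10)
        with pytest.raises(ValidationError, match="control"):
            ruv2_adjust(beta, age, beta.probe_ids[:3], k=5)

    def test_scree_aid_shape(self):
        rng = np.random.default_rng(62)
        beta, _ = _null_cohort(rng, n_probes=50, n_samples=12)
        sv = scree_singular_values(beta, beta.probe_ids[:20])
        assert len(sv) == 12
        assert (np.diff(sv) <= 1e-9).all()


class TestMethodCalibration:
    def test_all_three_methods_uniform_under_global_null(self):
        """No confounding, no signal: p values from univariate, naive and
        RUV-2 are uniform (KS test)."""
        rng = np.random.default_rng(63)
        n_probes, n_samples = 5000, 60
        beta = _beta_from(
            np.clip(rng.normal(0.5, 0.04, (n_probes, n_samples)), 0, 1)
        )
        age = pd.Series(rng.uniform(20, 70, n_samples), index=beta.sample_ids)
        W = rng.dirichlet(np.ones(4), n_samples)  # composition independent of age
        props = CellProportions(
            proportions=pd.DataFrame(
                W, index=beta.sample_ids, columns=list("ABCD")
            ),
            constraint_mode="simplex",
            residual_norm=pd.Series(0.0, index=beta.sample_ids),
        )
        from scipy.stats import kstest

        for res in (
            univariate_ewas(beta, age),
            naive_adjust(beta, age, props),
            ruv2_adjust(beta, age, beta.probe_ids[:300], k=3),
        ):
            assert kstest(res.table["p"], "uniform").pvalue > 0.01, res.method


class TestCets:
    def _profiles(self, rng, n=8, p=40, equal=False, eps_sd=0.01):
        mu_bar_N = rng.uniform(0.2, 0.8, p)
        mu_bar_G = rng.uniform(0.2, 0.8, p)
        dev_N = rng.normal(0, 0.05, (n, p))
        dev_G = dev_N if equal else rng.normal(0, 0.05, (n, p))
        return CetsProfiles.assemble(
            pi=rng.uniform(0, 1, n),
            mu_N=np.clip(mu_bar_N + dev_N, 0, 1),
            mu_G=np.clip(mu_bar_G + dev_G, 0, 1),
            mu_bar_N=mu_bar_N,
            mu_bar_G=mu_bar_G,
            eps=rng.normal(0, eps_sd, (n, p)),
        )

    def test_pi_one_is_identity(self):
        rng = np.random.default_rng(64)
        prof = self._profiles(rng)
        prof.pi[:] = 1.0
        assert np.allclose(cets_transform(prof), prof.Y, atol=1e-15)

    def test_average_profiles_recover_signal_exactly(self):
        """When individual profiles equal the population averages and there is
        no measurement error, the transform returns the neuronal profile."""
        rng = np.random.default_rng(65)
        mu_bar_N = rng.uniform(0.2, 0.8, 30)
        mu_bar_G = rng.uniform(0.2, 0.8, 30)
        prof = CetsProfiles.assemble(
            pi=rng.uniform(0, 1, 6),
            mu_N=np.tile(mu_bar_N, (6, 1)),
            mu_G=np.tile(mu_bar_G, (6, 1)),
            mu_bar_N=mu_bar_N,
            mu_bar_G=mu_bar_G,
            eps=np.zeros((6, 30)),
        )
        assert np.allclose(cets_transform(prof), prof.mu_N, atol=1e-12)

    def test_individual_deviation_leaves_closed_form_bias(self):
        """mu_N deviating by delta while mu_G matches its average biases the
        transform by -(1-pi) delta."""
        rng = np.random.default_rng(66)
        mu_bar_N = rng.uniform(0.3, 0.6, 20)
        mu_bar_G = rng.uniform(0.3, 0.6, 20)
        delta = 0.05
        pi = np.array([0.25, 0.75])
        prof = CetsProfiles.assemble(
            pi=pi,
            mu_N=np.tile(mu_bar_N + delta, (2, 1)),
            mu_G=np.tile(mu_bar_G, (2, 1)),
            mu_bar_N=mu_bar_N,
            mu_bar_G=mu_bar_G,
            eps=np.zeros((2, 20)),
        )
        residual = cets_transform(prof) - prof.mu_N
        expected = -(1 - pi)[:, None] * delta
        assert np.allclose(residual, expected, atol=1e-12)
        assert np.allclose(residual, cets_bias(prof), atol=1e-12)

    def test_equal_deviations_bias_is_noise_only(self):
        rng = np.random.default_rng(67)
        prof = self._profiles(rng, equal=True, eps_sd=0.005)
        assert np.allclose(cets_bias(prof), prof.eps, atol=1e-12)

    @given(
        pi=arrays(np.float64, 4, elements=st.floats(0, 1)),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=40, deadline=None)
    def test_identity_holds_for_arbitrary_profiles(self, pi, seed):
        rng = np.random.default_rng(seed)
        prof = self._profiles(rng, n=4)
        prof = CetsProfiles.assemble(
            pi=pi,
            mu_N=prof.mu_N,
            mu_G=prof.mu_G,
            mu_bar_N=prof.mu_bar_N,
            mu_bar_G=prof.mu_bar_G,
            eps=prof.eps,
        )
        assert np.allclose(
            cets_transform(prof), prof.mu_N + cets_bias(prof), atol=1e-12
        )

    def test_pi_outside_range_rejected(self):
        rng = np.random.default_rng(68)
        prof = self._profiles(rng)
        with pytest.raises(ValidationError):
            CetsProfiles.assemble(
                pi=np.array([1.5] * 8),
                mu_N=prof.mu_N,
                mu_G=prof.mu_G,
                mu_bar_N=prof.mu_bar_N,
                mu_bar_G=prof.mu_bar_G,
                eps=prof.eps,
            )
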