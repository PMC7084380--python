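"""Joint-model likelihood, priors and imputation against component oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

import msprev as mp
from msprev import ModelConfig, ModelData, ModelState, ValidationError
from msprev.multiscale_model import (
    aggregate_linear_predictors,
    aggregate_loglik,
    augment_missing_outcome,
    beta_to_original_scale,
    draw_truncated_poisson,
    individual_linear_predictor,
    individual_linear_predictors,
    individual_loglik,
    impute_sampling_weight,
    impute_unsampled_province,
    log1pexp,
    log_posterior,
    log_posterior_components,
)
from msprev.spatial_graph import AdjacencyGraph
from msprev.survey_data import ProvinceAggregate

from conftest import make_individual


def small_fixture(seed=0, n_prov=3, per_prov=7, config=None):
    """Tiny fully-observed survey on a path graph."""
    rng = np.random.default_rng(seed)
    graph = AdjacencyGraph.from_edges(
        [(j, j + 1) for j in range(1, n_prov)], n_nodes=n_prov, one_based=True)
    inds = []
    for j in range(n_prov):
        for i in range(per_prov):
            inds.append(make_individual(
                f"p{j}_{i}", j + 1, age=float(rng.uniform(20, 80)),
                sex=int(rng.integers(2)),
                sampling_weight=float(rng.uniform(0.5, 3.0)),
                fasting_glucose=float(rng.uniform(80, 200)),
                bmi=float(rng.uniform(20, 40)),
                sbp=float(rng.uniform(100, 180)),
                dbp=float(rng.uniform(60, 110)),
                ldl=float(rng.uniform(60, 220)),
            ))
    data = ModelData.from_survey(inds, graph, config or ModelConfig())
    return data


def randomized_state(data, seed=5, scale=0.4):
    rng = np.random.default_rng(seed)
    st = ModelState.initial(data, rng)
    st.fixed.beta += scale * rng.standard_normal(st.fixed.beta.shape) \
        / np.maximum(data.X.std(axis=0), 1.0)
    st.fixed.alpha += scale * rng.standard_normal(st.fixed.alpha.shape)
    st.fixed.gamma += 0.1 * rng.standard_normal(data.K)
    st.random.v = scale * rng.standard_normal(st.random.v.shape)
    st.random.vs = scale * rng.standard_normal(st.random.vs.shape)
    st.random.vp = scale * rng.standard_normal(st.random.vp.shape)
    up = scale * rng.standard_normal(st.random.up.shape)
    st.random.up = up - up.mean(axis=0)  # centering convention
    st.precisions.tau_v = rng.uniform(0.5, 4.0, data.K)
    st.precisions.tau_vs = rng.uniform(0.5, 4.0, st.precisions.tau_vs.shape)
    st.precisions.tau_vp = rng.uniform(0.5, 4.0, data.K)
    st.precisions.tau_up = rng.uniform(0.5, 4.0, data.K)
    return st


class TestLinearPredictors:
    def test_zero_state_gives_half_probability(self):
        data = small_fixture()
        st = ModelState.initial(data)
        st.fixed.beta[:] = 0.0
        eta = individual_linear_predictors(st, data)
        assert np.allclose(eta, 0.0)
        assert np.allclose(expit(eta), 0.5)

    def test_intercept_inverts_to_probability(self):
        data = small_fixture()
        st = ModelState.initial(data)
        st.fixed.beta[:] = 0.0
        st.fixed.beta[:, 0] = logit(0.1)
        # original-scale intercept is centred-scale intercept here only if
        # slopes are zero, so the probability at any covariates is 0.1
        p = expit(individual_linear_predictors(st, data))
        assert np.allclose(p, 0.1)

    def test_term_sum_oracle(self):
        """Vectorised predictors must equal the term-by-term reference path
        and a fully independent re-evaluation."""
        data = small_fixture(seed=3)
        st = randomized_state(data)
        eta = individual_linear_predictors(st, data)
        for i in (0, 5, 13, 20):
            for k in range(4):
                j = data.prov[i]
                manual = (float(data.X[i] @ st.fixed.beta[k])
                          + st.random.v[i, k] + st.random.vs[i, 0]
                          + st.random.vp[j, k] + st.random.up[j, k])
                assert eta[i, k] == pytest.approx(manual, rel=1e-12)
                assert individual_linear_predictor(st, data, i, k) == \
                    pytest.approx(manual, rel=1e-12)

    def test_probabilities_strictly_inside_unit_interval(self):
        data = small_fixture(seed=9)
        st = randomized_state(data, scale=3.0)
        p = expit(individual_linear_predictors(st, data))
        assert np.all((p > 0) & (p < 1))


class TestAggregateLikelihood:
    def test_binomial_closed_form(self):
        """One province with y=1 of n=2 at p=0.5 contributes
        log C(2,1) + log(0.25) = log(0.5)."""
        data = small_fixture(n_prov=1, per_prov=2)
        data.y_p[:] = 0
        data.n_obs_p[:] = 0
        data.y_p[0, 0], data.n_obs_p[0, 0] = 1, 2
        st = ModelState.initial(data)
        st.fixed.alpha[:] = 0.0
        st.fixed.gamma[:] = 0.0
        assert aggregate_loglik(st, data, k=0) == pytest.approx(np.log(0.5))

    def test_brute_force_sum_oracle(self):
        data = small_fixture(seed=7, n_prov=5, per_prov=9)
        st = randomized_state(data, seed=11)
        eta_p = aggregate_linear_predictors(st, data)
        expected = 0.0
        for j in range(5):
            for k in range(4):
                n = data.n_obs_p[j, k]
                if n > 0:
                    expected += stats.binom.logpmf(
                        data.y_p[j, k], n, expit(eta_p[j, k]))
        assert aggregate_loglik(st, data) == pytest.approx(expected, rel=1e-10)

    def test_shared_effect_touches_both_scales(self):
        """uP_jk is one object: perturbing it must move the individual and
        the aggregate log-likelihood together (the multi-scale link)."""
        data = small_fixture(seed=2)
        st = randomized_state(data)
        base_ind = individual_loglik(st, data)
        base_agg = aggregate_loglik(st, data)
        st.random.up[1, 2] += 0.37
        assert individual_loglik(st, data) != pytest.approx(base_ind)
        assert aggregate_loglik(st, data) != pytest.approx(base_agg)

    def test_count_exceeding_denominator_errors(self):
        data = small_fixture()
        data.y_p[0, 0] = data.n_obs_p[0, 0] + 1
        with pytest.raises(ValidationError, match="exceeds"):
            aggregate_loglik(ModelState.initial(data), data)


class TestImputation:
    def test_weight_identity_for_sampled(self):
        aggs = [
            ProvinceAggregate(1, 2, np.zeros(4), np.zeros(4), 40.0, 0.5, 3.0, 1),
            ProvinceAggregate(2, 2, np.zeros(4), np.zeros(4), 50.0, 0.5, 7.0, 1),
            ProvinceAggregate(3, 0, np.zeros(4), np.zeros(4), None, None, None, 0),
        ]
        sw = impute_sampling_weight(aggs)
        assert sw[0] == pytest.approx(3.0)       # keeps its own mean
        assert sw[2] == pytest.approx(5.0)       # global mean of sampled
        # degenerate: all sampled with equal means
        equal = [ProvinceAggregate(i + 1, 1, np.zeros(4), np.zeros(4),
                                   40.0, 0.5, 4.2, 1) for i in range(3)]
        assert np.allclose(impute_sampling_weight(equal), 4.2)

    def test_no_sampled_province_errors(self):
        empty = [ProvinceAggregate(1, 0, np.zeros(4), np.zeros(4), None, None, None, 0)]
        with pytest.raises(ValidationError):
            impute_sampling_weight(empty)

    def test_truncated_poisson_mean(self, rng):
        draws = draw_truncated_poisson(rng, 110.0, size=20000)
        assert np.all(draws >= 1)
        assert draws.mean() == pytest.approx(110.0, abs=0.5)

    def test_unsampled_province_draws(self, rng):
        """Repeated per-sweep imputation: n centres at the Poisson rate,
        p at the flat-prior mean, y at their product."""
        graph = AdjacencyGraph.from_edges([(1, 2)], n_nodes=2, one_based=True)
        inds = [make_individual("A", 1)]
        data = ModelData.from_survey(inds, graph)
        st = ModelState.initial(data, rng)
        ns, ps, ys = [], [], []
        for _ in range(4000):
            n, p, y = impute_unsampled_province(rng, st, data, 1)
            ns.append(n), ps.append(p), ys.append(y.mean())
        assert np.mean(ns) == pytest.approx(110.0, abs=1.0)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.02)
        assert np.mean(ys) == pytest.approx(55.0, abs=2.0)
        assert np.all(np.array(ys) <= np.array(ns))

    def test_impute_sampled_province_rejected(self, rng):
        data = small_fixture()
        st = ModelState.initial(data, rng)
        with pytest.raises(ValidationError):
            impute_unsampled_province(rng, st, data, 0)

    def test_binomial_predictive_mean_oracle(self, rng):
        # with p and n pinned, the predictive count centres at n*p
        draws = rng.binomial(110, 0.1, size=20000)
        assert draws.mean() == pytest.approx(11.0, abs=0.3)


class TestAugmentation:
    def _masked_fixture(self):
        inds = [make_individual("A", 1, bmi=None), make_individual("B", 1)]
        graph = AdjacencyGraph.from_edges([(1, 2)], n_nodes=2, one_based=True)
        return ModelData.from_survey(inds, graph)

    def test_degenerate_probability_draw(self, rng):
        data = self._masked_fixture()
        st = ModelState.initial(data, rng)
        st.fixed.beta[:] = 0.0
        st.fixed.beta[1, 0] = 50.0  # p ~ 1 for obesity
        assert augment_missing_outcome(rng, st, data, 0, 1) == 1

    def test_long_run_frequency_matches_probability(self, rng):
        data = self._masked_fixture()
        st = ModelState.initial(data, rng)
        st.fixed.beta[:] = 0.0
        st.fixed.beta[1, 0] = logit(0.3)
        draws = [augment_missing_outcome(rng, st, data, 0, 1) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(0.3, abs=0.025)

    def test_observed_outcome_rejected(self, rng):
        data = self._masked_fixture()
        st = ModelState.initial(data, rng)
        with pytest.raises(ValidationError):
            augment_missing_outcome(rng, st, data, 1, 1)

    def test_shared_effect_propagates_into_imputation(self, rng):
        """A person whose shared effect is strongly positive (as it would be
        after observing three positive outcomes) is imputed positive for the
        fourth outcome more often than the population marginal rate."""
        data = self._masked_fixture()
        st = ModelState.initial(data, rng)
        st.fixed.beta[:] = 0.0
        st.fixed.beta[1, 0] = logit(0.3)   # marginal rate 0.3
        st.random.vs[0, 0] = 2.0           # strong positive shared effect
        freq = np.mean([augment_missing_outcome(rng, st, data, 0, 1)
                        for _ in range(2000)])
        assert freq > 0.3 + 0.2
        assert freq == pytest.approx(expit(logit(0.3) + 2.0), abs=0.04)


class TestLogPosterior:
    def test_prior_only_is_finite(self):
        graph = AdjacencyGraph.from_edges([(1, 2)], n_nodes=2, one_based=True)
        cfg = ModelConfig(include_aggregate_level=False,
                          unsampled_pseudo_data=False)
        data = ModelData.from_survey([], graph, cfg)
        st = ModelState.initial(data)
        assert np.isfinite(log_posterior(st, data))

    def test_component_sum_oracle(self):
        """The joint log-posterior equals an independent component-wise
        evaluation built from scipy distributions on a 3-province,
        21-person fixture."""
        data = small_fixture(seed=13, n_prov=3, per_prov=7)
        st = randomized_state(data, seed=17)
        eta = individual_linear_predictors(st, data)
        eta_p = aggregate_linear_predictors(st, data)
        cfg = data.config
        a, b = cfg.tau_prior_shape, cfg.tau_prior_rate

        expected = float(np.sum(stats.bernoulli.logpmf(st.y_aug, expit(eta))))
        for j in range(3):
            for k in range(4):
                if data.n_obs_p[j, k] > 0:
                    expected += stats.binom.logpmf(
                        data.y_p[j, k], data.n_obs_p[j, k], expit(eta_p[j, k]))
        tau0 = 1.0 / cfg.fixed_effect_variance
        for mat in (st.fixed.beta, st.fixed.alpha):
            expected += np.sum(stats.norm.logpdf(mat, 0, np.sqrt(1 / tau0)))
        expected += np.sum(stats.norm.logpdf(st.fixed.gamma, 0, np.sqrt(1 / tau0)))
        for k in range(4):
            expected += np.sum(stats.norm.logpdf(
                st.random.v[:, k], 0, 1 / np.sqrt(st.precisions.tau_v[k])))
            expected += np.sum(stats.norm.logpdf(
                st.random.vp[:, k], 0, 1 / np.sqrt(st.precisions.tau_vp[k])))
        expected += np.sum(stats.norm.logpdf(
            st.random.vs, 0, 1 / np.sqrt(st.precisions.tau_vs[0])))
        rank = data.graph.rank
        for k in range(4):
            tau = st.precisions.tau_up[k]
            ss = sum((st.random.up[e0, k] - st.random.up[e1, k]) ** 2
                     for e0, e1 in data.graph.edges)
            expected += (-0.5 * tau * ss
                         + 0.5 * rank * (np.log(tau) - np.log(2 * np.pi)))
        for tau_arr in (st.precisions.tau_v, st.precisions.tau_vs,
                        st.precisions.tau_vp, st.precisions.tau_up):
            expected += np.sum(stats.gamma.logpdf(tau_arr, a, scale=1 / b))

        assert log_posterior(st, data) == pytest.approx(expected, rel=1e-9)

    def test_gaussian_penalty_decreases_posterior(self):
        data = small_fixture(seed=1)
        st = ModelState.initial(data)
        st.fixed.beta[:] = 0.0  # flat likelihood in v at balanced outcomes
        base = log_posterior(st, data)
        st.random.v[0, 0] = 30.0
        assert log_posterior(st, data) < base - 100.0

    def test_non_finite_component_named(self):
        data = small_fixture()
        st = ModelState.initial(data)
        st.precisions.tau_v[0] = np.inf
        with pytest.raises(ValidationError, match="tau_v_prior|frailty"):
            log_posterior(st, data)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = ModelConfig(shared_effect="per_outcome", tau_prior_shape=0.1,
                          standardize_weights=True)
        path = tmp_path / "model.yaml"
        cfg.to_yaml(path)
        assert ModelConfig.from_yaml(path) == cfg
        with pytest.raises(ValueError):
            ModelConfig(shared_effect="telepathic")


class TestStateExport:
    def test_named_parameter_table(self):
        from msprev.multiscale_model import state_to_table

        data = small_fixture(seed=4)
        st = randomized_state(data, seed=6)
        tbl = state_to_table(st, data).set_index("parameter")
        assert tbl.loc["tau_v[diabetes]", "value"] == st.precisions.tau_v[0]
        assert tbl.loc["vp[2,obesity]", "value"] == st.random.vp[1, 1]
        beta_orig = beta_to_original_scale(st.fixed.beta, data)
        assert tbl.loc["beta[diabetes,age]", "value"] == pytest.approx(
            beta_orig[0, 1])


class TestReportingTransform:
    def test_centred_and_original_scale_agree_on_probabilities(self):
        """Back-transformed coefficients must reproduce the same linear
        predictor on the raw covariates."""
        data = small_fixture(seed=21)
        st = randomized_state(data, seed=23)
        eta_centred = data.X @ st.fixed.beta.T
        raw = np.column_stack([np.ones(data.m), data.age, data.sex,
                               data.age * data.sex, data.sw])
        beta_orig = beta_to_original_scale(st.fixed.beta, data)
        assert np.allclose(raw @ beta_orig.T, eta_centred)
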