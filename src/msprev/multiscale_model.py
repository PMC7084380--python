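"""The joint multi-scale multivariate prevalence model.

Two likelihood levels are fitted **jointly** for K = 4 correlated binary
outcomes (diabetes, obesity, hypertension, elevated LDL):

Individual level (Bernoulli-logistic), person i in province j:

    y_ik ~ Bern(p_ik)
    logit(p_ik) = b0k + b1k Age_i + b2k Sex_i + b3k Age_i*Sex_i + b4k sw_i
                  + v_ik + vs_i + vP_jk + uP_jk

Province level (binomial on aggregated counts), province j:

    yP_jk ~ Bin(pP_jk, nP_jk)
    logit(pP_jk) = a0k + a1k AgeP_j + a2k SexP_j + a3k AgeP_j*SexP_j
                   + g_k swP_j + vP_jk + uP_jk

The province effects ``vP_jk`` (uncorrelated, Gaussian) and ``uP_jk``
(spatially correlated, ICAR) are the *same objects* at both scales — the
multi-scale link through which individuals inherit provincial context and
the aggregate model borrows individually-estimated spatial structure.  The
survey design weight ``sw`` enters as a predictor, following the
weight-as-covariate approach to design adjustment, never as a likelihood
weight.  ``v_ik`` is a per-person per-outcome frailty and ``vs_i`` a shared
per-person effect inducing correlation between the four outcomes.

Missingness (assumed MAR) is handled inside the model: masked outcomes are
augmented from their Bernoulli predictive each MCMC sweep; provinces with no
sample receive an imputed sample size n ~ Poisson(110) truncated to >= 1, a
flat Beta(1,1) prevalence draw and a binomial predictive pseudo-count, and
their mean sampling weight is replaced by the global mean over sampled
provinces.

Priors: fixed effects N(0, 1000); all precisions Gamma(0.5, 0.0005) (shape,
rate); ICAR for the u fields.  Everything is configurable via
:class:`ModelConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln

from .spatial_graph import AdjacencyGraph, SpatialField, icar_log_density, icar_pairwise_ss
from .survey_data import (
    OUTCOMES,
    OutcomeVector,
    ProvinceAggregate,
    SurveyIndividual,
    ValidationError,
    aggregate_to_province,
    derive_outcomes,
)

__all__ = [
    "ModelConfig",
    "ModelData",
    "FixedEffects",
    "RandomEffects",
    "Precisions",
    "ImputationState",
    "ModelState",
    "individual_linear_predictor",
    "individual_linear_predictors",
    "aggregate_linear_predictor",
    "aggregate_linear_predictors",
    "individual_loglik",
    "aggregate_loglik",
    "impute_sampling_weight",
    "impute_unsampled_province",
    "draw_truncated_poisson",
    "augment_missing_outcome",
    "augment_missing_outcomes",
    "log_posterior",
    "log_posterior_components",
    "beta_to_original_scale",
    "alpha_gamma_to_original_scale",
]

K_OUTCOMES = len(OUTCOMES)


def log1pexp(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable log(1 + e^x) (softplus)."""
    x = np.asarray(x)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


@dataclass
class ModelConfig:
    """Model structure, priors and imputation switches.

    ``shared_effect`` selects the between-outcome linkage: ``"person"`` (one
    vs_i per person, common to all outcomes — the default), ``"per_outcome"``
    (outcome-specific vs_ik, person-level shrinkage only) or ``"none"``.
    ``intercept_prior="uniform_probability"`` places a uniform prior on the
    inverse-logit of each intercept (standard-logistic on the logit scale),
    the choice under which a one-province intercept-only model has the
    conjugate Beta posterior.  ``unsampled_pseudo_data`` controls whether
    the flat predictive pseudo-counts drawn for unsampled provinces also
    enter the aggregate likelihood.  Default off: a missing count augmented
    from a predictive carries no net likelihood information, so unsampled
    provinces are estimated from the spatial prior and covariates alone
    (likelihood feedback would instead pull them toward the flat-prior 0.5
    and leak that shift into neighbours through the shared spatial field).
    The imputation draws themselves are always available as the predictive
    report for unsampled areas.
    """

    tau_prior_shape: float = 0.5
    tau_prior_rate: float = 0.0005
    fixed_effect_variance: float = 1000.0
    intercept_prior: str = "normal"  # or "uniform_probability"
    shared_effect: str = "person"  # "person" | "per_outcome" | "none"
    include_frailty: bool = True
    include_province_uncorrelated: bool = True
    include_spatial: bool = True
    include_individual_level: bool = True
    include_aggregate_level: bool = True
    intercept_only: bool = False
    standardize_weights: bool = False
    unsampled_pseudo_data: bool = False
    unsampled_n_rate: float = 110.0

    def __post_init__(self) -> None:
        if self.shared_effect not in ("person", "per_outcome", "none"):
            raise ValueError(f"unknown shared_effect {self.shared_effect!r}")
        if self.intercept_prior not in ("normal", "uniform_probability"):
            raise ValueError(f"unknown intercept_prior {self.intercept_prior!r}")
        if self.tau_prior_shape <= 0 or self.tau_prior_rate <= 0:
            raise ValueError("tau prior parameters must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self)))


IND_COLUMNS = ("intercept", "age", "sex", "age_sex", "weight")
AGG_COLUMNS = ("intercept", "mean_age", "prop_male", "mean_age_prop_male")


@dataclass
class ModelData:
    """Analysis-ready arrays for the joint model.

    Individual covariates are centred internally (age and weight) for MCMC
    mixing; coefficients are transformed back to the original scale for
    reporting.  Aggregate covariates of unsampled provinces are filled with
    the global means of the sampled provinces (and are therefore 0 after
    centring), mirroring the global-mean rule used for sampling weights.
    """

    age: np.ndarray          # (m,)
    sex: np.ndarray          # (m,)
    sw: np.ndarray           # (m,)
    prov: np.ndarray         # (m,) 0-based province index
    Y: np.ndarray            # (m, K) observed outcomes, -1 where missing
    obs: np.ndarray          # (m, K) bool
    X: np.ndarray            # (m, p_ind) centred design
    A: np.ndarray            # (J, p_agg) centred aggregate design
    swp: np.ndarray          # (J,) province mean weight after imputation
    swp_c: np.ndarray        # (J,) centred version entering g_k * swP_j
    y_p: np.ndarray          # (J, K) observed case counts
    n_obs_p: np.ndarray      # (J, K) observed denominators
    n_sampled: np.ndarray    # (J,)
    sampled: np.ndarray      # (J,) bool
    graph: AdjacencyGraph
    config: ModelConfig
    age_mean: float
    sw_mean: float
    sw_scale: float
    agep_mean: float
    swp_mean: float
    aggregates: list[ProvinceAggregate] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.age)

    @property
    def J(self) -> int:
        return self.graph.n_nodes

    @property
    def K(self) -> int:
        return K_OUTCOMES

    @property
    def p_ind(self) -> int:
        return self.X.shape[1]

    @property
    def p_agg(self) -> int:
        return self.A.shape[1]

    @classmethod
    def from_survey(
        cls,
        individuals: Sequence[SurveyIndividual],
        graph: AdjacencyGraph,
        config: ModelConfig | None = None,
        outcomes: Sequence[OutcomeVector] | None = None,
    ) -> "ModelData":
        config = config or ModelConfig()
        if outcomes is None:
            outcomes = [derive_outcomes(ind) for ind in individuals]
        aggregates = aggregate_to_province(individuals, graph.n_nodes, outcomes)

        age = np.array([ind.age for ind in individuals], dtype=float)
        sex = np.array([ind.sex for ind in individuals], dtype=float)
        sw = np.array([ind.sampling_weight for ind in individuals], dtype=float)
        prov = np.array([ind.province_id - 1 for ind in individuals], dtype=np.int64)
        obs = np.stack([ov.observed_mask for ov in outcomes]) if individuals else \
            np.zeros((0, K_OUTCOMES), dtype=bool)
        Y = np.where(
            obs,
            np.stack([ov.y for ov in outcomes]) if individuals else
            np.zeros((0, K_OUTCOMES), dtype=np.int8),
            -1,
        ).astype(np.int8)

        age_mean = float(age.mean()) if len(age) else 0.0
        sw_mean = float(sw.mean()) if len(sw) else 0.0
        sw_scale = float(sw.std()) if config.standardize_weights and len(sw) > 1 else 1.0
        if sw_scale == 0.0:
            sw_scale = 1.0
        age_c = age - age_mean
        sw_c = (sw - sw_mean) / sw_scale
        if config.intercept_only:
            X = np.ones((len(age), 1))
        else:
            X = np.column_stack([np.ones(len(age)), age_c, sex, age_c * sex, sw_c])

        J = graph.n_nodes
        sampled = np.array([a.sampled_flag == 1 for a in aggregates])
        n_sampled = np.array([a.n_sampled for a in aggregates], dtype=np.int64)
        y_p = np.stack([a.case_counts for a in aggregates]).astype(np.int64)
        n_obs_p = np.stack([a.n_observed for a in aggregates]).astype(np.int64)

        swp = impute_sampling_weight(aggregates) if sampled.any() else np.zeros(J)
        swp_mean = float(swp[sampled].mean()) if sampled.any() else 0.0
        swp_c = (swp - swp_mean) / sw_scale

        agep = np.array(
            [a.mean_age if a.mean_age is not None else np.nan for a in aggregates]
        )
        sexp = np.array(
            [a.prop_male if a.prop_male is not None else np.nan for a in aggregates]
        )
        agep_mean = float(np.nanmean(agep)) if sampled.any() else 0.0
        sexp_mean = float(np.nanmean(sexp)) if sampled.any() else 0.0
        agep = np.where(np.isnan(agep), agep_mean, agep)
        sexp = np.where(np.isnan(sexp), sexp_mean, sexp)
        agep_c = agep - agep_mean
        if config.intercept_only:
            A = np.ones((J, 1))
        else:
            A = np.column_stack([np.ones(J), agep_c, sexp, agep_c * sexp])

        return cls(
            age=age, sex=sex, sw=sw, prov=prov, Y=Y, obs=obs, X=X, A=A,
            swp=swp, swp_c=swp_c, y_p=y_p, n_obs_p=n_obs_p,
            n_sampled=n_sampled, sampled=sampled, graph=graph, config=config,
            age_mean=age_mean, sw_mean=sw_mean, sw_scale=sw_scale,
            agep_mean=agep_mean, swp_mean=swp_mean, aggregates=list(aggregates),
        )


# ---------------------------------------------------------------------------
# State containers


@dataclass
class FixedEffects:
    beta: np.ndarray   # (K, p_ind) on the centred scale
    alpha: np.ndarray  # (K, p_agg)
    gamma: np.ndarray  # (K,)


@dataclass
class RandomEffects:
    v: np.ndarray   # (m, K) per-person per-outcome frailty
    vs: np.ndarray  # (m, 1) shared per person, or (m, K) per outcome
    vp: np.ndarray  # (J, K) province uncorrelated
    up: np.ndarray  # (J, K) province ICAR


@dataclass
class Precisions:
    tau_v: np.ndarray   # (K,)
    tau_vs: np.ndarray  # (1,) or (K,)
    tau_vp: np.ndarray  # (K,)
    tau_up: np.ndarray  # (K,)

    def validate(self) -> None:
        for name in ("tau_v", "tau_vs", "tau_vp", "tau_up"):
            if not np.all(getattr(self, name) > 0):
                raise ValidationError(f"{name} must be strictly positive")


@dataclass
class ImputationState:
    """Per-sweep imputed quantities for unsampled provinces."""

    n_imp: np.ndarray  # (J,) imputed sample size, 0 on sampled provinces
    p_imp: np.ndarray  # (J,) flat Beta(1,1) prevalence draw
    y_imp: np.ndarray  # (J, K) binomial predictive pseudo-counts


@dataclass
class ModelState:
    """Full parameter vector of the joint model at one MCMC iteration."""

    fixed: FixedEffects
    random: RandomEffects
    precisions: Precisions
    imputation: ImputationState
    y_aug: np.ndarray  # (m, K) completed outcomes in {0,1}

    @classmethod
    def initial(
        cls, data: ModelData, rng: np.random.Generator | None = None,
        jitter: float = 0.0,
    ) -> "ModelState":
        """Starting state: intercepts at the empirical logit of the pooled
        observed rate, all other effects zero, precisions one, missing
        outcomes filled with fair-coin draws.  The optional jitter (scaled
        by each design column's spread) separates parallel chains without
        throwing any into a region of absurd likelihood."""
        cfg = data.config
        m, J, K = data.m, data.J, data.K
        Ks = 1 if cfg.shared_effect in ("person", "none") else K
        rng = rng or np.random.default_rng(0)

        def col_scales(M: np.ndarray) -> np.ndarray:
            s = M.std(axis=0) if len(M) else np.ones(M.shape[1])
            return np.where(s > 0, s, 1.0)

        n_obs_k = data.obs.sum(axis=0) if m else np.zeros(K)
        y_obs_k = np.where(data.obs, np.maximum(data.Y, 0), 0).sum(axis=0) if m \
            else np.zeros(K)
        crude = (y_obs_k + 0.5) / (n_obs_k + 1.0)
        logit0 = np.log(crude / (1.0 - crude))
        beta = np.zeros((K, data.p_ind))
        beta[:, 0] = logit0
        beta += jitter * rng.standard_normal((K, data.p_ind)) / col_scales(data.X)
        alpha = np.zeros((K, data.p_agg))
        alpha[:, 0] = logit0
        alpha += jitter * rng.standard_normal((K, data.p_agg)) / col_scales(data.A)
        sw_sd = data.swp_c.std() if data.swp_c.std() > 0 else 1.0
        fx = FixedEffects(
            beta=beta,
            alpha=alpha,
            gamma=jitter * rng.standard_normal(K) / sw_sd if not cfg.intercept_only
            else np.zeros(K),
        )
        re = RandomEffects(
            v=np.zeros((m, K)), vs=np.zeros((m, Ks)),
            vp=np.zeros((J, K)), up=np.zeros((J, K)),
        )
        # starting precisions of 100 (effect SDs of 0.1) keep early burn-in
        # out of the minor large-frailty basin of the posterior
        pr = Precisions(
            tau_v=np.full(K, 100.0), tau_vs=np.full(Ks, 100.0),
            tau_vp=np.full(K, 100.0), tau_up=np.full(K, 100.0),
        )
        y_aug = np.where(data.obs, np.maximum(data.Y, 0), rng.integers(0, 2, (m, K)))
        imp = ImputationState(
            n_imp=np.zeros(J, dtype=np.int64), p_imp=np.full(J, 0.5),
            y_imp=np.zeros((J, K), dtype=np.int64),
        )
        st = cls(fixed=fx, random=re, precisions=pr, imputation=imp,
                 y_aug=y_aug.astype(np.int8))
        if (~data.sampled).any():
            refresh_unsampled_imputation(rng, st, data)
        return st


# ---------------------------------------------------------------------------
# Linear predictors and likelihoods


def individual_linear_predictors(state: ModelState, data: ModelData) -> np.ndarray:
    """(m, K) matrix of individual-level logits."""
    cfg = data.config
    eta = data.X @ state.fixed.beta.T
    if cfg.include_frailty:
        eta = eta + state.random.v
    if cfg.shared_effect != "none":
        eta = eta + state.random.vs  # broadcasts (m,1) or (m,K)
    if cfg.include_province_uncorrelated:
        eta = eta + state.random.vp[data.prov]
    if cfg.include_spatial:
        eta = eta + state.random.up[data.prov]
    return eta


def individual_linear_predictor(
    state: ModelState, data: ModelData, i: int, k: int
) -> float:
    """Single-person logit, evaluated term by term (reference path)."""
    cfg = data.config
    eta = float(data.X[i] @ state.fixed.beta[k])
    if cfg.include_frailty:
        eta += state.random.v[i, k]
    if cfg.shared_effect == "person":
        eta += state.random.vs[i, 0]
    elif cfg.shared_effect == "per_outcome":
        eta += state.random.vs[i, k]
    j = data.prov[i]
    if cfg.include_province_uncorrelated:
        eta += state.random.vp[j, k]
    if cfg.include_spatial:
        eta += state.random.up[j, k]
    return eta


def aggregate_linear_predictors(state: ModelState, data: ModelData) -> np.ndarray:
    """(J, K) matrix of province-level logits."""
    cfg = data.config
    eta = data.A @ state.fixed.alpha.T + np.outer(data.swp_c, state.fixed.gamma)
    if cfg.include_province_uncorrelated:
        eta = eta + state.random.vp
    if cfg.include_spatial:
        eta = eta + state.random.up
    return eta


def aggregate_linear_predictor(
    state: ModelState, data: ModelData, j: int, k: int
) -> float:
    return float(aggregate_linear_predictors(state, data)[j, k])


def individual_loglik(state: ModelState, data: ModelData) -> float:
    """Completed-data Bernoulli log-likelihood over all persons/outcomes."""
    if data.m == 0:
        return 0.0
    eta = individual_linear_predictors(state, data)
    y = state.y_aug
    return float(np.sum(y * eta - log1pexp(eta)))


def _binom_logpmf(y: np.ndarray, n: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Binomial log-pmf with logit-scale probability, incl. the coefficient."""
    return (gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
            + y * eta - n * log1pexp(eta))


def aggregate_loglik(state: ModelState, data: ModelData, k: int | None = None) -> float:
    """Binomial log-likelihood at the province scale.

    Sampled provinces contribute their observed case counts out of the
    per-outcome observed denominators; unsampled provinces contribute their
    flat-predictive pseudo-counts when ``unsampled_pseudo_data`` is on.
    Raises when any count exceeds its denominator.
    """
    eta_p = aggregate_linear_predictors(state, data)
    ks = range(data.K) if k is None else [k]
    total = 0.0
    for kk in ks:
        y, n = data.y_p[:, kk], data.n_obs_p[:, kk]
        if np.any(y > n):
            raise ValidationError(f"case count exceeds denominator for outcome {kk}")
        use = data.sampled & (n > 0)
        total += float(_binom_logpmf(y[use], n[use], eta_p[use, kk]).sum())
        if data.config.unsampled_pseudo_data and (~data.sampled).any():
            un = ~data.sampled
            yi = state.imputation.y_imp[un, kk]
            ni = state.imputation.n_imp[un]
            if np.any(yi > ni):
                raise ValidationError("imputed count exceeds imputed denominator")
            total += float(_binom_logpmf(yi, ni, eta_p[un, kk]).sum())
    return total


# ---------------------------------------------------------------------------
# Imputation machinery


def impute_sampling_weight(aggregates: Sequence[ProvinceAggregate]) -> np.ndarray:
    """Province mean sampling weights with global-mean fill for unsampled.

    Sampled provinces keep their own mean weight; unsampled provinces get the
    global mean over the sampled provinces' means:
    swP_j = sw_bar + I_j (swP_j - sw_bar).
    """
    means = np.array(
        [a.mean_weight if a.mean_weight is not None else np.nan for a in aggregates]
    )
    sampled = np.array([a.sampled_flag == 1 for a in aggregates])
    if not sampled.any():
        raise ValidationError("cannot impute sampling weights: no sampled province")
    global_mean = float(means[sampled].mean())
    return np.where(sampled, means, global_mean)


def draw_truncated_poisson(
    rng: np.random.Generator, rate: float, size: int | None = None, lower: int = 1
) -> np.ndarray | int:
    """Poisson(rate) draws conditioned on >= ``lower`` (rejection sampling;
    at rate 110 the truncation is numerically negligible)."""
    n = 1 if size is None else size
    out = rng.poisson(rate, n)
    bad = out < lower
    while bad.any():
        out[bad] = rng.poisson(rate, int(bad.sum()))
        bad = out < lower
    return int(out[0]) if size is None else out


def impute_unsampled_province(
    rng: np.random.Generator, state: ModelState, data: ModelData, j: int
) -> tuple[int, float, np.ndarray]:
    """Fresh predictive imputation for one unsampled province.

    Draws n ~ Poisson(rate) truncated at >= 1, p ~ Beta(1, 1) and a binomial
    predictive pseudo-count y_k ~ Bin(n, p) per outcome, and stores them in
    the state.  Called once per MCMC sweep per unsampled province.
    """
    if data.sampled[j]:
        raise ValidationError(f"province {j + 1} is sampled; nothing to impute")
    n = draw_truncated_poisson(rng, data.config.unsampled_n_rate)
    p = float(rng.beta(1.0, 1.0))
    y = rng.binomial(n, p, size=data.K).astype(np.int64)
    state.imputation.n_imp[j] = n
    state.imputation.p_imp[j] = p
    state.imputation.y_imp[j] = y
    return n, p, y


def refresh_unsampled_imputation(
    rng: np.random.Generator, state: ModelState, data: ModelData
) -> None:
    for j in np.flatnonzero(~data.sampled):
        impute_unsampled_province(rng, state, data, int(j))


def augment_missing_outcome(
    rng: np.random.Generator, state: ModelState, data: ModelData, i: int, k: int
) -> int:
    """One Bernoulli predictive draw for a masked outcome.

    The person's current linear predictor includes the shared effect vs_i,
    so information from the observed outcomes of the same person propagates
    into the imputation."""
    if data.obs[i, k]:
        raise ValidationError(f"outcome {k} of person {i} is observed")
    p = expit(individual_linear_predictor(state, data, i, k))
    draw = int(rng.random() < p)
    state.y_aug[i, k] = draw
    return draw


def augment_missing_outcomes(
    rng: np.random.Generator, state: ModelState, data: ModelData,
    eta: np.ndarray | None = None,
) -> None:
    """Vectorised refresh of every masked outcome from its predictive."""
    miss = ~data.obs
    if not miss.any():
        return
    if eta is None:
        eta = individual_linear_predictors(state, data)
    p = expit(eta[miss])
    state.y_aug[miss] = (rng.random(p.shape) < p).astype(np.int8)


# ---------------------------------------------------------------------------
# Priors and the joint posterior


def _gaussian_logpdf_sum(x: np.ndarray, tau: float) -> float:
    n = x.size
    return float(-0.5 * tau * np.sum(x * x) + 0.5 * n * (np.log(tau) - np.log(2 * np.pi)))


def _gamma_logpdf(x: np.ndarray, shape: float, rate: float) -> float:
    x = np.atleast_1d(x)
    return float(np.sum(shape * np.log(rate) - gammaln(shape)
                        + (shape - 1) * np.log(x) - rate * x))


def _fixed_effect_logprior(state: ModelState, data: ModelData) -> float:
    cfg = data.config
    tau0 = 1.0 / cfg.fixed_effect_variance
    total = 0.0
    for mat in (state.fixed.beta, state.fixed.alpha):
        if cfg.intercept_prior == "uniform_probability":
            ic = mat[:, 0]
            total += float(np.sum(ic - 2.0 * log1pexp(ic)))  # standard logistic
            rest = mat[:, 1:]
        else:
            rest = mat
        if rest.size:
            total += _gaussian_logpdf_sum(rest, tau0)
    if not cfg.intercept_only:
        total += _gaussian_logpdf_sum(state.fixed.gamma, tau0)
    return total


def log_posterior_components(state: ModelState, data: ModelData) -> dict[str, float]:
    """Named additive components of the joint log-posterior."""
    cfg = data.config
    pr = state.precisions
    comp: dict[str, float] = {}
    if cfg.include_individual_level:
        comp["individual_loglik"] = individual_loglik(state, data)
    if cfg.include_aggregate_level:
        comp["aggregate_loglik"] = aggregate_loglik(state, data)
    comp["fixed_effect_prior"] = _fixed_effect_logprior(state, data)
    if cfg.include_frailty:
        comp["frailty_prior"] = sum(
            _gaussian_logpdf_sum(state.random.v[:, k], pr.tau_v[k])
            for k in range(data.K)
        )
        comp["tau_v_prior"] = _gamma_logpdf(pr.tau_v, cfg.tau_prior_shape, cfg.tau_prior_rate)
    if cfg.shared_effect != "none":
        comp["shared_effect_prior"] = sum(
            _gaussian_logpdf_sum(state.random.vs[:, s], pr.tau_vs[s])
            for s in range(state.random.vs.shape[1])
        )
        comp["tau_vs_prior"] = _gamma_logpdf(pr.tau_vs, cfg.tau_prior_shape, cfg.tau_prior_rate)
    if cfg.include_province_uncorrelated:
        comp["province_uncorrelated_prior"] = sum(
            _gaussian_logpdf_sum(state.random.vp[:, k], pr.tau_vp[k])
            for k in range(data.K)
        )
        comp["tau_vp_prior"] = _gamma_logpdf(pr.tau_vp, cfg.tau_prior_shape, cfg.tau_prior_rate)
    if cfg.include_spatial:
        comp["icar_prior"] = sum(
            icar_log_density(
                SpatialField(state.random.up[:, k], float(pr.tau_up[k])), data.graph
            )
            for k in range(data.K)
        )
        comp["tau_up_prior"] = _gamma_logpdf(pr.tau_up, cfg.tau_prior_shape, cfg.tau_prior_rate)
    return comp


def log_posterior(state: ModelState, data: ModelData) -> float:
    """Joint log-posterior (up to a constant); raises naming the offending
    component if any term is non-finite."""
    comp = log_posterior_components(state, data)
    for name, val in comp.items():
        if not np.isfinite(val):
            raise ValidationError(f"non-finite log-posterior component {name!r}: {val}")
    return float(sum(comp.values()))


def state_to_table(state: ModelState, data: ModelData):
    """Flatten a full model state into a (parameter, value) table.

    Fixed effects are reported on the original covariate scale; random
    effects and precisions under their field names, indexed 1-based.
    """
    import pandas as pd

    rows: list[tuple[str, float]] = []
    beta = beta_to_original_scale(state.fixed.beta, data)
    alpha, gamma = alpha_gamma_to_original_scale(
        state.fixed.alpha, state.fixed.gamma, data)
    ind_cols = IND_COLUMNS[: data.p_ind]
    agg_cols = AGG_COLUMNS[: data.p_agg]
    for k, o in enumerate(OUTCOMES):
        rows += [(f"beta[{o},{c}]", beta[k, i]) for i, c in enumerate(ind_cols)]
        rows += [(f"alpha[{o},{c}]", alpha[k, i]) for i, c in enumerate(agg_cols)]
        rows.append((f"gamma[{o}]", gamma[k]))
        rows.append((f"tau_v[{o}]", state.precisions.tau_v[k]))
        rows.append((f"tau_vp[{o}]", state.precisions.tau_vp[k]))
        rows.append((f"tau_up[{o}]", state.precisions.tau_up[k]))
        for j in range(data.J):
            rows.append((f"vp[{j + 1},{o}]", state.random.vp[j, k]))
            rows.append((f"up[{j + 1},{o}]", state.random.up[j, k]))
    for s in range(state.precisions.tau_vs.shape[0]):
        name = "tau_vs" if state.precisions.tau_vs.shape[0] == 1 \
            else f"tau_vs[{OUTCOMES[s]}]"
        rows.append((name, state.precisions.tau_vs[s]))
    return pd.DataFrame(rows, columns=["parameter", "value"])


# ---------------------------------------------------------------------------
# Reporting-scale transforms (centred -> original covariate scale)


def beta_to_original_scale(beta_c: np.ndarray, data: ModelData) -> np.ndarray:
    """Map centred-scale individual coefficients back to the raw scale.

    With age centred at a_bar and weight at w_bar (unit weight scale unless
    standardisation was requested):
    b0 = b0c - b1 a_bar - b4 w_bar / s_w,  b2 = b2c - b3 a_bar; slopes are
    unchanged (weight slope divided by the standardisation scale).
    Works on any trailing (..., p_ind) axis.
    """
    beta_c = np.asarray(beta_c, dtype=float)
    if data.config.intercept_only:
        return beta_c.copy()
    out = beta_c.copy()
    out[..., 4] = beta_c[..., 4] / data.sw_scale
    out[..., 0] = (beta_c[..., 0] - beta_c[..., 1] * data.age_mean
                   - out[..., 4] * data.sw_mean)
    out[..., 2] = beta_c[..., 2] - beta_c[..., 3] * data.age_mean
    return out


def alpha_gamma_to_original_scale(
    alpha_c: np.ndarray, gamma_c: np.ndarray, data: ModelData
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate-model analogue of :func:`beta_to_original_scale`."""
    alpha_c = np.asarray(alpha_c, dtype=float)
    gamma_c = np.asarray(gamma_c, dtype=float)
    if data.config.intercept_only:
        return alpha_c.copy(), gamma_c.copy()
    gamma = gamma_c / data.sw_scale
    out = alpha_c.copy()
    out[..., 0] = (alpha_c[..., 0] - alpha_c[..., 1] * data.agep_mean
                   - gamma * data.swp_mean)
    out[..., 2] = alpha_c[..., 2] - alpha_c[..., 3] * data.agep_mean
    return out, gamma
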