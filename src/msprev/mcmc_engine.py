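"""Posterior sampling for the joint multi-scale model.

The sampler is a Metropolis-within-Gibbs sweep:

* precisions — conjugate Gamma draws (Gaussian effects) and the
  pseudo-determinant-rank Gamma draw for each ICAR precision;
* fixed-effect blocks (per outcome, individual and aggregate) — adaptive
  random-walk Metropolis with an empirical-covariance proposal seeded from
  the inverse logistic information;
* person effects (frailty v_ik, shared vs_i) — single-site random-walk
  Metropolis, vectorised across persons (they are conditionally independent
  given the rest);
* province effects — uncorrelated vP_jk updated jointly across provinces
  (independent given the rest); the ICAR field uP_jk by single-site updates
  swept over graph-colouring classes so that no two neighbours move in the
  same vectorised step, followed by a per-component re-centering whose mean
  shift is absorbed into the intercepts (sum-to-zero convention);
* imputation — masked outcomes redrawn from their Bernoulli predictive and
  unsampled-province pseudo-data refreshed, every sweep.

Proposal scales adapt during burn-in only (Robbins–Monro towards 0.44
acceptance for scalar sites, 0.234 for blocks) and are frozen afterwards, so
the retained chain is a genuine Markov chain.  Runs are reproducible: a
single integer seed drives every chain through independent spawned streams,
and identical seeds give identical traces.

Convergence diagnostics follow standard practice for multi-chain output:
the potential scale reduction factor (between/within-chain variance ratio),
batch-means Monte Carlo standard errors, and the deviance trace
(-2 log-likelihood per retained draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .multiscale_model import (
    ModelData,
    ModelState,
    OUTCOMES,
    _binom_logpmf,
    aggregate_linear_predictors,
    alpha_gamma_to_original_scale,
    augment_missing_outcomes,
    beta_to_original_scale,
    individual_linear_predictors,
    log1pexp,
    log_posterior,
    refresh_unsampled_imputation,
)
from .spatial_graph import icar_pairwise_ss

__all__ = [
    "ChainConfig",
    "PosteriorDraws",
    "run_mcmc",
    "gelman_rubin",
    "mc_error",
    "deviance_trace",
]


@dataclass
class ChainConfig:
    """MCMC protocol.  The defaults mirror the reporting protocol of the
    original analysis (two chains, thinning 50, 5000 retained draws); the
    burn-in length is this package's choice.  Tests and examples use much
    shorter, explicitly configured protocols."""

    n_chains: int = 2
    thin: int = 50
    retained: int = 5000
    burn_in: int = 10_000
    seed: int = 0
    jitter: float = 0.1
    adapt: bool = True

    def __post_init__(self) -> None:
        if min(self.n_chains, self.thin, self.retained) < 1 or self.burn_in < 0:
            raise ValueError("chain configuration values must be positive")


@dataclass
class PosteriorDraws:
    """Retained posterior draws, one leading axis per chain.

    Fixed effects are stored on the original covariate scale.  ``get(name)``
    returns the (n_chains, n_draws) trace of a named scalar parameter, e.g.
    ``"beta[diabetes,age]"``, ``"tau_up[obesity]"``, ``"p[12,hypertension]"``
    (1-based province ids) or ``"deviance"``.
    """

    beta: np.ndarray      # (C, G, K, p_ind)
    alpha: np.ndarray     # (C, G, K, p_agg)
    gamma: np.ndarray     # (C, G, K)
    tau_v: np.ndarray     # (C, G, K)
    tau_vs: np.ndarray    # (C, G, Ks)
    tau_vp: np.ndarray    # (C, G, K)
    tau_up: np.ndarray    # (C, G, K)
    p_prov: np.ndarray    # (C, G, J, K)
    up: np.ndarray        # (C, G, J, K)
    vp: np.ndarray        # (C, G, J, K)
    deviance: np.ndarray  # (C, G)
    ind_cols: tuple[str, ...]
    agg_cols: tuple[str, ...]
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.deviance.shape[0]

    @property
    def n_draws(self) -> int:
        return self.deviance.shape[1]

    def param_names(self) -> list[str]:
        K, J = self.gamma.shape[2], self.p_prov.shape[2]
        names = [f"beta[{o},{c}]" for o in OUTCOMES for c in self.ind_cols]
        names += [f"alpha[{o},{c}]" for o in OUTCOMES for c in self.agg_cols]
        names += [f"gamma[{o}]" for o in OUTCOMES]
        names += [f"tau_v[{o}]" for o in OUTCOMES]
        names += (["tau_vs"] if self.tau_vs.shape[2] == 1
                  else [f"tau_vs[{o}]" for o in OUTCOMES])
        names += [f"tau_vp[{o}]" for o in OUTCOMES]
        names += [f"tau_up[{o}]" for o in OUTCOMES]
        names += [f"p[{j + 1},{o}]" for j in range(J) for o in OUTCOMES]
        names += ["deviance"]
        return names

    def get(self, name: str) -> np.ndarray:
        if name == "deviance":
            return self.deviance
        if name == "tau_vs":
            return self.tau_vs[:, :, 0]
        base, _, inside = name.partition("[")
        inside = inside.rstrip("]")
        parts = inside.split(",") if inside else []
        k_of = {o: k for k, o in enumerate(OUTCOMES)}
        if base in ("beta", "alpha"):
            cols = self.ind_cols if base == "beta" else self.agg_cols
            return getattr(self, base)[:, :, k_of[parts[0]], cols.index(parts[1])]
        if base in ("gamma", "tau_v", "tau_vs", "tau_vp", "tau_up"):
            arr = getattr(self, base)
            return arr[:, :, k_of[parts[0]]]
        if base in ("p", "up", "vp"):
            arr = self.p_prov if base == "p" else getattr(self, base)
            return arr[:, :, int(parts[0]) - 1, k_of[parts[1]]]
        raise KeyError(f"unknown parameter {name!r}")

    def to_dataframe(self, chain: int):
        """One chain's named-parameter trace as a DataFrame (for export)."""
        import pandas as pd

        return pd.DataFrame(
            {nm: self.get(nm)[chain] for nm in self.param_names()}
        )


# ---------------------------------------------------------------------------
# Diagnostics


def _as_chain_matrix(draws, parameter) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorDraws input")
        x = draws.get(parameter)
    else:
        x = np.asarray(draws, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (n_chains, n_draws) array")
    return x


def gelman_rubin(draws, parameter: str | None = None) -> float:
    """Potential scale reduction factor R-hat (between/within variance ratio).

    R-hat = sqrt( ((G-1)/G * W + B/G) / W ) over >= 2 equal-length chains;
    values close to 1 indicate convergence.  By construction the statistic
    cannot fall below sqrt((G-1)/G).
    """
    x = _as_chain_matrix(draws, parameter)
    C, G = x.shape
    if C < 2:
        raise ValueError("gelman_rubin requires at least two chains")
    if G < 10:
        raise ValueError("gelman_rubin requires chains of length >= 10")
    chain_means = x.mean(axis=1)
    W = float(x.var(axis=1, ddof=1).mean())
    B = G * float(chain_means.var(ddof=1))
    if W == 0.0:
        return 1.0
    var_plus = (G - 1) / G * W + B / G
    return float(np.sqrt(var_plus / W))


def mc_error(draws, parameter: str | None = None) -> float:
    """Batch-means Monte Carlo standard error of the pooled posterior mean.

    Each chain is split into ~sqrt(G) batches; the pooled standard error
    combines the per-chain batch-means errors as independent estimates.
    """
    x = _as_chain_matrix(draws, parameter)
    C, G = x.shape
    if G < 100:
        raise ValueError("mc_error requires at least 100 retained draws")
    nb = int(np.floor(np.sqrt(G)))
    bs = G // nb
    se2 = []
    for c in range(C):
        bm = x[c, : nb * bs].reshape(nb, bs).mean(axis=1)
        v = bm.var(ddof=1)
        se2.append(v / nb)
    return float(np.sqrt(np.sum(se2)) / C)


def deviance_trace(draws: PosteriorDraws) -> np.ndarray:
    """-2 log-likelihood per retained draw, per chain."""
    return draws.deviance


# ---------------------------------------------------------------------------
# Sampler internals


class _Sampler:
    """One-chain sampler holding cached predictors and adaptation state."""

    def __init__(self, data: ModelData, cc: ChainConfig, rng: np.random.Generator):
        self.data = data
        self.cfg = data.config
        self.cc = cc
        self.rng = rng
        self.state = ModelState.initial(data, rng, jitter=cc.jitter)
        log_posterior(self.state, data)  # raises naming the bad component

        d, cfg = data, self.cfg
        self.eta = individual_linear_predictors(self.state, d)        # (m, K)
        self.eta_p = aggregate_linear_predictors(self.state, d)       # (J, K)

        # logistic-information seeds for the block proposals
        if d.m:
            info = 0.25 * d.X.T @ d.X + 1e-8 * np.eye(d.p_ind)
        else:
            info = np.eye(d.p_ind)
        self.cov_beta = [np.linalg.inv(info) for _ in range(d.K)]
        Ag = np.column_stack([d.A, d.swp_c]) if not cfg.intercept_only else d.A
        n_eff = np.where(d.sampled, d.n_sampled, cfg.unsampled_n_rate)
        info_a = 0.25 * (Ag * n_eff[:, None]).T @ Ag + 1e-8 * np.eye(Ag.shape[1])
        self.cov_alpha = [np.linalg.inv(info_a) for _ in range(d.K)]
        self.p_ab = Ag.shape[1]
        self.Ag = Ag

        # adaptive scales (log-space) and acceptance accumulators
        self.ls_beta = np.zeros(d.K)
        self.ls_alpha = np.zeros(d.K)
        Ks = self.state.random.vs.shape[1]
        self.ls_v = np.zeros(d.K)
        self.ls_vs = np.zeros(Ks)
        self.ls_vp = np.full((d.J, d.K), np.log(0.5))
        self.ls_up = np.full((d.J, d.K), np.log(0.5))
        self._acc: dict[str, list[float]] = {}

        # running moments for block-covariance adaptation; accumulation
        # starts only after the initial transient has died down
        self._bmom = [[0, np.zeros(d.p_ind), np.zeros((d.p_ind, d.p_ind))]
                      for _ in range(d.K)]
        self._amom = [[0, np.zeros(self.p_ab), np.zeros((self.p_ab, self.p_ab))]
                      for _ in range(d.K)]
        self._moment_start = max(50, cc.burn_in // 4)
        self._nadapt = 0

        g = d.graph
        self.colors = [c[np.array([len(g.neighbors[j]) > 0 for j in c])]
                       for c in g.coloring()]
        self.colors = [c for c in self.colors if len(c)]
        self.nbr_flat = {}
        self.nbr_offs = {}
        for ci, cls_nodes in enumerate(self.colors):
            flat, offs = [], [0]
            for j in cls_nodes:
                flat.extend(g.neighbors[j])
                offs.append(len(flat))
            self.nbr_flat[ci] = np.array(flat, dtype=np.int64)
            self.nbr_offs[ci] = np.array(offs[:-1], dtype=np.int64)
        self.n_nbr = g.n_neighbors.astype(float)
        self.comps = [np.array(c, dtype=np.int64) for c in g.components]
        self.big_comps = [c for c in self.comps if len(c) > 1]
        self.edges = g.edges
        # per-outcome aggregate denominators (observed scale)
        self.agg_use = d.sampled[:, None] & (d.n_obs_p > 0)  # (J, K)

    # -- helpers ------------------------------------------------------------

    def _alpha_vec(self, k: int) -> np.ndarray:
        st = self.state
        if self.cfg.intercept_only:
            return st.fixed.alpha[k].copy()
        return np.append(st.fixed.alpha[k], st.fixed.gamma[k])

    def _record_acc(self, name: str, rate: float) -> None:
        self._acc.setdefault(name, []).append(float(rate))

    def _gamma_step(self, t: int) -> float:
        return min(0.5, 2.0 / max(t, 1) ** 0.6)

    def _agg_yn(self, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Effective (use_mask, y, n) for outcome k at the aggregate level."""
        d, st = self.data, self.state
        y = d.y_p[:, k].astype(float).copy()
        n = d.n_obs_p[:, k].astype(float).copy()
        use = self.agg_use[:, k].copy()
        if self.cfg.unsampled_pseudo_data:
            un = ~d.sampled
            y[un] = st.imputation.y_imp[un, k]
            n[un] = st.imputation.n_imp[un]
            use |= un
        return use, y, n

    # -- update steps -------------------------------------------------------

    def update_precisions(self) -> None:
        d, st, cfg, rng = self.data, self.state, self.cfg, self.rng
        a, b = cfg.tau_prior_shape, cfg.tau_prior_rate
        re, pr = st.random, st.precisions
        if cfg.include_frailty and d.m:
            ss = np.sum(re.v * re.v, axis=0)
            pr.tau_v = rng.gamma(a + 0.5 * d.m, 1.0 / (b + 0.5 * ss))
        if cfg.shared_effect != "none" and d.m:
            ss = np.sum(re.vs * re.vs, axis=0)
            pr.tau_vs = rng.gamma(a + 0.5 * d.m, 1.0 / (b + 0.5 * ss))
        if cfg.include_province_uncorrelated:
            ss = np.sum(re.vp * re.vp, axis=0)
            pr.tau_vp = rng.gamma(a + 0.5 * d.J, 1.0 / (b + 0.5 * ss))
        if cfg.include_spatial:
            rank = d.graph.rank
            for k in range(d.K):
                ss = icar_pairwise_ss(re.up[:, k], d.graph)
                pr.tau_up[k] = rng.gamma(a + 0.5 * rank, 1.0 / (b + 0.5 * ss))

    def update_beta(self, t: int, adapting: bool) -> None:
        d, st, cfg, rng = self.data, self.state, self.cfg, self.rng
        if not cfg.include_individual_level or d.m == 0:
            return
        tau0 = 1.0 / cfg.fixed_effect_variance
        for k in range(d.K):
            cov = self.cov_beta[k]
            cnt, _, M2 = self._bmom[k]
            if adapting and cnt > max(50, 4 * d.p_ind):
                cov = M2 / (cnt - 1) + 1e-10 * np.eye(d.p_ind)
            scale = np.exp(self.ls_beta[k]) * 2.38 / np.sqrt(d.p_ind)
            try:
                step = scale * np.linalg.cholesky(cov) @ rng.standard_normal(d.p_ind)
            except np.linalg.LinAlgError:
                step = scale * np.sqrt(np.diag(cov)) * rng.standard_normal(d.p_ind)
            new = st.fixed.beta[k] + step
            deta = d.X @ step
            e0, e1 = self.eta[:, k], self.eta[:, k] + deta
            y = st.y_aug[:, k]
            dll = float(np.sum(y * deta) - np.sum(log1pexp(e1) - log1pexp(e0)))
            dll += self._fixed_prior_delta(st.fixed.beta[k], new, tau0)
            acc = np.log(rng.random()) < dll
            if acc:
                st.fixed.beta[k] = new
                self.eta[:, k] = e1
            if adapting:
                self.ls_beta[k] += self._gamma_step(t) * ((1.0 if acc else 0.0) - 0.234)
                if t > self._moment_start:
                    self._update_moments(self._bmom[k], st.fixed.beta[k])
            self._record_acc(f"beta[{OUTCOMES[k]}]", 1.0 if acc else 0.0)

    def _fixed_prior_delta(self, old: np.ndarray, new: np.ndarray, tau0: float) -> float:
        if self.cfg.intercept_prior == "uniform_probability":
            d_int = ((new[0] - 2 * log1pexp(new[0]))
                     - (old[0] - 2 * log1pexp(old[0])))
            rest = -0.5 * tau0 * (np.sum(new[1:] ** 2) - np.sum(old[1:] ** 2))
            return float(d_int + rest)
        return float(-0.5 * tau0 * (np.sum(new ** 2) - np.sum(old ** 2)))

    def _update_moments(self, mom: list, x: np.ndarray) -> None:
        mom[0] += 1
        cnt, mean, M2 = mom
        delta = x - mean
        mean += delta / cnt
        M2 += np.outer(delta, x - mean)

    def update_alpha(self, t: int, adapting: bool) -> None:
        d, st, cfg, rng = self.data, self.state, self.cfg, self.rng
        if not cfg.include_aggregate_level:
            return
        tau0 = 1.0 / cfg.fixed_effect_variance
        for k in range(d.K):
            cov = self.cov_alpha[k]
            cnt, _, M2 = self._amom[k]
            if adapting and cnt > max(50, 4 * self.p_ab):
                cov = M2 / (cnt - 1) + 1e-10 * np.eye(self.p_ab)
            scale = np.exp(self.ls_alpha[k]) * 2.38 / np.sqrt(self.p_ab)
            try:
                step = scale * np.linalg.cholesky(cov) @ rng.standard_normal(self.p_ab)
            except np.linalg.LinAlgError:
                step = scale * np.sqrt(np.diag(cov)) * rng.standard_normal(self.p_ab)
            old = self._alpha_vec(k)
            new = old + step
            deta = self.Ag @ step
            use, y, n = self._agg_yn(k)
            e0 = self.eta_p[use, k]
            e1 = e0 + deta[use]
            dll = float(np.sum(y[use] * deta[use])
                        - np.sum(n[use] * (log1pexp(e1) - log1pexp(e0))))
            dll += self._fixed_prior_delta(old, new, tau0)
            acc = np.log(rng.random()) < dll
            if acc:
                if cfg.intercept_only:
                    st.fixed.alpha[k] = new
                else:
                    st.fixed.alpha[k] = new[:-1]
                    st.fixed.gamma[k] = new[-1]
                self.eta_p[:, k] += deta
            if adapting:
                self.ls_alpha[k] += self._gamma_step(t) * ((1.0 if acc else 0.0) - 0.234)
                if t > self._moment_start:
                    self._update_moments(self._amom[k], self._alpha_vec(k))
            self._record_acc(f"alpha[{OUTCOMES[k]}]", 1.0 if acc else 0.0)

    def update_person_effects(self, t: int, adapting: bool) -> None:
        d, st, cfg, rng = self.data, self.state, self.cfg, self.rng
        if not cfg.include_individual_level or d.m == 0:
            return
        re, pr = st.random, st.precisions
        y = st.y_aug
        if cfg.include_frailty:
            delta = np.exp(self.ls_v)[None, :] * rng.standard_normal((d.m, d.K))
            e1 = self.eta + delta
            dll = (y * delta - (log1pexp(e1) - log1pexp(self.eta))
                   - 0.5 * pr.tau_v[None, :] * ((re.v + delta) ** 2 - re.v ** 2))
            acc = np.log(rng.random((d.m, d.K))) < dll
            re.v += np.where(acc, delta, 0.0)
            self.eta += np.where(acc, delta, 0.0)
            rates = acc.mean(axis=0)
            if adapting:
                self.ls_v += self._gamma_step(t) * (rates - 0.44)
            self._record_acc("frailty", float(rates.mean()))
        if cfg.shared_effect != "none":
            Ks = re.vs.shape[1]
            delta = np.exp(self.ls_vs)[None, :] * rng.standard_normal((d.m, Ks))
            if Ks == 1:
                e1 = self.eta + delta
                dll = (np.sum(y * delta - (log1pexp(e1) - log1pexp(self.eta)), axis=1,
                              keepdims=True)
                       - 0.5 * pr.tau_vs[None, :] * ((re.vs + delta) ** 2 - re.vs ** 2))
            else:
                e1 = self.eta + delta
                dll = (y * delta - (log1pexp(e1) - log1pexp(self.eta))
                       - 0.5 * pr.tau_vs[None, :] * ((re.vs + delta) ** 2 - re.vs ** 2))
            acc = np.log(rng.random((d.m, Ks))) < dll
            re.vs += np.where(acc, delta, 0.0)
            self.eta += np.where(acc, delta, 0.0)  # broadcasts for Ks == 1
            rates = acc.mean(axis=0)
            if adapting:
                self.ls_vs += self._gamma_step(t) * (rates - 0.44)
            self._record_acc("shared_effect", float(rates.mean()))

    def _province_likelihood_delta(self, delta: np.ndarray, k: int) -> np.ndarray:
        """(J,) change in total log-likelihood when province effect (j, k)
        moves by delta[j] at both scales."""
        d, st = self.data, self.state
        out = np.zeros(d.J)
        if self.cfg.include_individual_level and d.m:
            dpp = delta[d.prov]
            e0 = self.eta[:, k]
            e1 = e0 + dpp
            dll = st.y_aug[:, k] * dpp - (log1pexp(e1) - log1pexp(e0))
            out += np.bincount(d.prov, weights=dll, minlength=d.J)
        if self.cfg.include_aggregate_level:
            use, y, n = self._agg_yn(k)
            e0 = self.eta_p[:, k]
            e1 = e0 + delta
            dagg = y * delta - n * (log1pexp(e1) - log1pexp(e0))
            out += np.where(use, dagg, 0.0)
        return out

    def _apply_province_move(self, moved: np.ndarray, k: int) -> None:
        d = self.data
        if self.cfg.include_individual_level and d.m:
            self.eta[:, k] += moved[d.prov]
        self.eta_p[:, k] += moved

    def update_province_uncorrelated(self, t: int, adapting: bool) -> None:
        d, st, rng = self.data, self.state, self.rng
        if not self.cfg.include_province_uncorrelated:
            return
        re, pr = st.random, st.precisions
        for k in range(d.K):
            delta = np.exp(self.ls_vp[:, k]) * rng.standard_normal(d.J)
            dll = self._province_likelihood_delta(delta, k)
            dll -= 0.5 * pr.tau_vp[k] * ((re.vp[:, k] + delta) ** 2 - re.vp[:, k] ** 2)
            acc = np.log(rng.random(d.J)) < dll
            moved = np.where(acc, delta, 0.0)
            re.vp[:, k] += moved
            self._apply_province_move(moved, k)
            if adapting:
                self.ls_vp[:, k] += self._gamma_step(t) * (acc - 0.44)
            self._record_acc("province_uncorrelated", float(acc.mean()))

    def update_spatial(self, t: int, adapting: bool) -> None:
        d, st, rng = self.data, self.state, self.rng
        if not self.cfg.include_spatial:
            return
        re, pr = st.random, st.precisions
        for k in range(d.K):
            u = re.up[:, k]
            for ci, nodes in enumerate(self.colors):
                nbr_sum = np.add.reduceat(u[self.nbr_flat[ci]], self.nbr_offs[ci])
                nd = self.n_nbr[nodes]
                mbar = nbr_sum / nd
                delta_s = np.exp(self.ls_up[nodes, k]) * rng.standard_normal(len(nodes))
                delta = np.zeros(d.J)
                delta[nodes] = delta_s
                dll = self._province_likelihood_delta(delta, k)[nodes]
                u0 = u[nodes]
                dll -= 0.5 * pr.tau_up[k] * nd * ((u0 + delta_s - mbar) ** 2
                                                  - (u0 - mbar) ** 2)
                acc = np.log(rng.random(len(nodes))) < dll
                moved = np.zeros(d.J)
                moved[nodes] = np.where(acc, delta_s, 0.0)
                u += moved
                self._apply_province_move(moved, k)
                if adapting:
                    self.ls_up[nodes, k] += self._gamma_step(t) * (acc - 0.44)
                self._record_acc("spatial", float(acc.mean()))
            self._recenter(k)

    def _recenter(self, k: int) -> None:
        """Sum-to-zero per connected component; the removed mean is absorbed
        into the intercepts so the cached predictors stay exact (exact for a
        connected graph; with several components the residual per-component
        shifts require a predictor refresh)."""
        st, d = self.state, self.data
        u = st.random.up[:, k]
        if len(self.big_comps) == 1:
            comp = self.big_comps[0]
            c = float(u[comp].mean())
            u[comp] -= c
            st.fixed.beta[k, 0] += c
            st.fixed.alpha[k, 0] += c
        elif self.big_comps:
            for comp in self.big_comps:
                c = float(u[comp].mean())
                u[comp] -= c
            self._refresh_caches()

    def _refresh_caches(self) -> None:
        self.eta = individual_linear_predictors(self.state, self.data)
        self.eta_p = aggregate_linear_predictors(self.state, self.data)

    def current_deviance(self) -> float:
        """-2 * (completed-data Bernoulli + observed aggregate binomial)."""
        d, st = self.data, self.state
        ll = 0.0
        if self.cfg.include_individual_level and d.m:
            ll += float(np.sum(st.y_aug * self.eta - log1pexp(self.eta)))
        if self.cfg.include_aggregate_level:
            for k in range(d.K):
                use = self.agg_use[:, k]
                ll += float(_binom_logpmf(
                    d.y_p[use, k], d.n_obs_p[use, k], self.eta_p[use, k]
                ).sum())
        return -2.0 * ll

    def update_scale_moves(self) -> None:
        """Joint (precision, effect-vector) rescaling moves.

        Proposes tau' = tau e^eps with the whole effect vector scaled by
        e^{-eps/2}, which leaves the Gaussian (or ICAR pairwise) prior
        exponent exactly invariant; the normalising-constant and Jacobian
        terms cancel, leaving only the likelihood change and the Gamma
        hyperprior ratio a*eps - b*tau*(e^eps - 1).  This traverses the
        funnel between an effect vector and its precision far faster than
        alternating single-site updates.
        """
        d, st, cfg, rng = self.data, self.state, self.cfg, self.rng
        a, b = cfg.tau_prior_shape, cfg.tau_prior_rate
        re, pr = st.random, st.precisions

        def hyper_delta(tau: float, eps: float) -> float:
            return a * eps - b * tau * (np.expm1(eps))

        y = st.y_aug
        if cfg.include_individual_level and d.m and cfg.include_frailty:
            for k in range(d.K):
                eps = 0.6 * rng.standard_normal()
                c = np.exp(-0.5 * eps)
                deta = (c - 1.0) * re.v[:, k]
                e0 = self.eta[:, k]
                e1 = e0 + deta
                dll = float(np.sum(y[:, k] * deta)
                            - np.sum(log1pexp(e1) - log1pexp(e0)))
                dll += hyper_delta(float(pr.tau_v[k]), eps)
                if np.log(rng.random()) < dll:
                    re.v[:, k] *= c
                    pr.tau_v[k] *= np.exp(eps)
                    self.eta[:, k] = e1
        if cfg.include_individual_level and d.m and cfg.shared_effect != "none":
            for s in range(re.vs.shape[1]):
                eps = 0.6 * rng.standard_normal()
                c = np.exp(-0.5 * eps)
                deta = (c - 1.0) * re.vs[:, s]
                if re.vs.shape[1] == 1:
                    e1 = self.eta + deta[:, None]
                    dll = float(np.sum(y * deta[:, None])
                                - np.sum(log1pexp(e1) - log1pexp(self.eta)))
                else:
                    e1 = self.eta[:, s] + deta
                    dll = float(np.sum(y[:, s] * deta)
                                - np.sum(log1pexp(e1) - log1pexp(self.eta[:, s])))
                dll += hyper_delta(float(pr.tau_vs[s]), eps)
                if np.log(rng.random()) < dll:
                    re.vs[:, s] *= c
                    pr.tau_vs[s] *= np.exp(eps)
                    if re.vs.shape[1] == 1:
                        self.eta = np.asarray(e1)
                    else:
                        self.eta[:, s] = e1
        for name, arr, tau in (("vp", re.vp, pr.tau_vp), ("up", re.up, pr.tau_up)):
            if name == "vp" and not cfg.include_province_uncorrelated:
                continue
            if name == "up" and not cfg.include_spatial:
                continue
            for k in range(d.K):
                eps = 0.6 * rng.standard_normal()
                c = np.exp(-0.5 * eps)
                delta = (c - 1.0) * arr[:, k]
                dll = float(self._province_likelihood_delta(delta, k).sum())
                dll += hyper_delta(float(tau[k]), eps)
                if np.log(rng.random()) < dll:
                    arr[:, k] *= c
                    tau[k] *= np.exp(eps)
                    self._apply_province_move(delta, k)

    #: squared logit-attenuation constant (16 sqrt(3) / (15 pi))^2: marginal
    #: logistic coefficients attenuate by ~1/sqrt(1 + ATTEN * sigma^2) when a
    #: N(0, sigma^2) effect is integrated out
    _ATTEN = (16.0 * np.sqrt(3.0) / (15.0 * np.pi)) ** 2

    def update_ridge_moves(self) -> None:
        """Joint (precision, effect, fixed-effect) moves along the
        attenuation ridge of observation-level frailties.

        A Bernoulli outcome observed once per frailty leaves (tau_v, beta)
        nearly unidentified along the ridge where inflating beta by the
        logit-attenuation factor compensates a growing frailty scale.
        Plain updates cross this ridge on a 10^4-sweep timescale; here the
        whole triple moves at once: tau -> tau e^eps, v -> v e^{-eps/2},
        beta -> beta * r(eps) with r the attenuation ratio.  The map is an
        involution under eps -> -eps; the acceptance ratio carries the exact
        likelihood change, the Gamma hyperprior term, the fixed-effect prior
        change and the log-Jacobian p*log r (the v-part cancels against the
        Gaussian normaliser as in the scale moves).
        """
        d, st, cfg, rng = self.data, self.state, self.cfg, self.rng
        if not (cfg.include_individual_level and d.m):
            return
        re, pr = st.random, st.precisions
        a, b = cfg.tau_prior_shape, cfg.tau_prior_rate
        tau0 = 1.0 / cfg.fixed_effect_variance
        y = st.y_aug

        def attenuation_ratio(tau_old: float, tau_new: float) -> float:
            return np.sqrt((1.0 + self._ATTEN / tau_new)
                           / (1.0 + self._ATTEN / tau_old))

        if cfg.include_frailty:
            for k in range(d.K):
                tau = float(pr.tau_v[k])
                eps = 0.5 * rng.standard_normal()
                tau_new = tau * np.exp(eps)
                r = attenuation_ratio(tau, tau_new)
                beta_new = st.fixed.beta[k] * r
                dv = (np.exp(-0.5 * eps) - 1.0) * re.v[:, k]
                deta = d.X @ (beta_new - st.fixed.beta[k]) + dv
                e0 = self.eta[:, k]
                e1 = e0 + deta
                dll = float(np.sum(y[:, k] * deta)
                            - np.sum(log1pexp(e1) - log1pexp(e0)))
                dll += a * eps - b * tau * np.expm1(eps)
                dll += self._fixed_prior_delta(st.fixed.beta[k], beta_new, tau0)
                dll += d.p_ind * np.log(r)
                if np.log(rng.random()) < dll:
                    st.fixed.beta[k] = beta_new
                    re.v[:, k] *= np.exp(-0.5 * eps)
                    pr.tau_v[k] = tau_new
                    self.eta[:, k] = e1
        if cfg.shared_effect != "none" and re.vs.shape[1] == 1:
            tau = float(pr.tau_vs[0])
            eps = 0.5 * rng.standard_normal()
            tau_new = tau * np.exp(eps)
            r = attenuation_ratio(tau, tau_new)
            beta_new = st.fixed.beta * r
            dvs = (np.exp(-0.5 * eps) - 1.0) * re.vs[:, 0]
            deta = d.X @ (beta_new - st.fixed.beta).T + dvs[:, None]
            e1 = self.eta + deta
            dll = float(np.sum(y * deta)
                        - np.sum(log1pexp(e1) - log1pexp(self.eta)))
            dll += a * eps - b * tau * np.expm1(eps)
            dll += sum(self._fixed_prior_delta(st.fixed.beta[k], beta_new[k], tau0)
                       for k in range(d.K))
            dll += d.K * d.p_ind * np.log(r)
            if np.log(rng.random()) < dll:
                st.fixed.beta = beta_new
                re.vs[:, 0] *= np.exp(-0.5 * eps)
                pr.tau_vs[0] = tau_new
                self.eta = e1

    def update_location_moves(self) -> None:
        """Likelihood-invariant translation moves between effect means and
        intercepts.

        Shifting every element of an effect vector by -c while adding c to
        the intercept(s) it feeds leaves all linear predictors unchanged, so
        the acceptance ratio involves only the Gaussian priors.  These moves
        decorrelate the intercepts from the (weakly identified) means of the
        frailty, shared and province-uncorrelated effect vectors.
        """
        d, st, cfg, rng = self.data, self.state, self.cfg, self.rng
        re, pr = st.random, st.precisions
        tau0 = 1.0 / cfg.fixed_effect_variance

        def int_prior_delta(x_old: float, c: float) -> float:
            if cfg.intercept_prior == "uniform_probability":
                return float((x_old + c - 2 * log1pexp(x_old + c))
                             - (x_old - 2 * log1pexp(x_old)))
            return float(-0.5 * tau0 * ((x_old + c) ** 2 - x_old ** 2))

        def gauss_shift_delta(x: np.ndarray, tau: float, shift: float) -> float:
            # log N(x + shift) - log N(x) under N(0, 1/tau), summed
            n = x.size
            return float(-0.5 * tau * (n * shift * shift + 2 * shift * x.sum()))

        if cfg.include_individual_level and d.m and cfg.include_frailty:
            for k in range(d.K):
                tau = float(pr.tau_v[k])
                c = rng.standard_normal() / np.sqrt(d.m * tau)
                dll = gauss_shift_delta(re.v[:, k], tau, -c) \
                    + int_prior_delta(st.fixed.beta[k, 0], c)
                if np.log(rng.random()) < dll:
                    re.v[:, k] -= c
                    st.fixed.beta[k, 0] += c
        if cfg.include_individual_level and d.m and cfg.shared_effect != "none":
            for s in range(re.vs.shape[1]):
                tau = float(pr.tau_vs[s])
                c = rng.standard_normal() / np.sqrt(d.m * tau)
                ks = range(d.K) if re.vs.shape[1] == 1 else [s]
                dll = gauss_shift_delta(re.vs[:, s], tau, -c) + sum(
                    int_prior_delta(st.fixed.beta[k, 0], c) for k in ks)
                if np.log(rng.random()) < dll:
                    re.vs[:, s] -= c
                    for k in ks:
                        st.fixed.beta[k, 0] += c
        if cfg.include_province_uncorrelated:
            # both intercepts shift so every cached predictor stays exact
            for k in range(d.K):
                tau = float(pr.tau_vp[k])
                c = rng.standard_normal() / np.sqrt(d.J * tau)
                dll = (gauss_shift_delta(re.vp[:, k], tau, -c)
                       + int_prior_delta(st.fixed.beta[k, 0], c)
                       + int_prior_delta(st.fixed.alpha[k, 0], c))
                if np.log(rng.random()) < dll:
                    re.vp[:, k] -= c
                    st.fixed.beta[k, 0] += c
                    st.fixed.alpha[k, 0] += c

    def sweep(self, t: int, adapting: bool) -> None:
        d = self.data
        if adapting:
            self._nadapt += 1
        if self.cfg.include_individual_level and (~d.obs).any():
            augment_missing_outcomes(self.rng, self.state, d, self.eta)
        if (~d.sampled).any():
            refresh_unsampled_imputation(self.rng, self.state, d)
        # fixed-effect blocks are the mixing bottleneck (random-walk MH in
        # 5 dimensions); iterating them shortens their autocorrelation time
        for _ in range(2):
            self.update_beta(t, adapting)
            self.update_alpha(t, adapting)
        self.update_person_effects(t, adapting)
        self.update_province_uncorrelated(t, adapting)
        self.update_spatial(t, adapting)
        self.update_precisions()
        for _ in range(2):  # cheap global moves; repetition speeds the ridge
            self.update_scale_moves()
            self.update_ridge_moves()
            self.update_location_moves()
        if t % 256 == 0:
            self._refresh_caches()  # cancel floating-point drift


def run_mcmc(
    data: ModelData,
    chain_config: ChainConfig | None = None,
) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler and collect retained draws.

    Chains are independent streams spawned from ``chain_config.seed``; the
    output is fully determined by the data and the configuration.
    """
    cc = chain_config or ChainConfig()
    d = data
    K, J = d.K, d.J
    streams = np.random.SeedSequence(cc.seed).spawn(cc.n_chains)

    probe = ModelState.initial(d, np.random.default_rng(0), jitter=0.0)
    Ks = probe.random.vs.shape[1]
    C, G = cc.n_chains, cc.retained
    out = PosteriorDraws(
        beta=np.empty((C, G, K, d.p_ind)), alpha=np.empty((C, G, K, d.p_agg)),
        gamma=np.empty((C, G, K)), tau_v=np.empty((C, G, K)),
        tau_vs=np.empty((C, G, Ks)), tau_vp=np.empty((C, G, K)),
        tau_up=np.empty((C, G, K)), p_prov=np.empty((C, G, J, K)),
        up=np.empty((C, G, J, K)), vp=np.empty((C, G, J, K)),
        deviance=np.empty((C, G)),
        ind_cols=("intercept",) if d.config.intercept_only else
        ("intercept", "age", "sex", "age_sex", "weight"),
        agg_cols=("intercept",) if d.config.intercept_only else
        ("intercept", "mean_age", "prop_male", "mean_age_prop_male"),
    )

    acc_all: dict[str, list[float]] = {}
    for c in range(C):
        rng = np.random.default_rng(streams[c])
        smp = _Sampler(d, cc, rng)
        for t in range(1, cc.burn_in + 1):
            smp.sweep(t, adapting=cc.adapt)
        smp._acc.clear()
        g = 0
        t = 0
        while g < G:
            t += 1
            smp.sweep(cc.burn_in + t, adapting=False)
            if t % cc.thin == 0:
                st = smp.state
                out.beta[c, g] = beta_to_original_scale(st.fixed.beta, d)
                a_orig, g_orig = alpha_gamma_to_original_scale(
                    st.fixed.alpha, st.fixed.gamma, d
                )
                out.alpha[c, g] = a_orig
                out.gamma[c, g] = g_orig
                out.tau_v[c, g] = st.precisions.tau_v
                out.tau_vs[c, g] = st.precisions.tau_vs
                out.tau_vp[c, g] = st.precisions.tau_vp
                out.tau_up[c, g] = st.precisions.tau_up
                out.p_prov[c, g] = expit(smp.eta_p)
                out.up[c, g] = st.random.up
                out.vp[c, g] = st.random.vp
                out.deviance[c, g] = smp.current_deviance()
                g += 1
        for name, vals in smp._acc.items():
            acc_all.setdefault(name, []).extend(vals)
    out.acceptance = {k: float(np.mean(v)) for k, v in acc_all.items()}
    return out
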