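"""Bayesian phylogenetic prediction of a held-out tip (PGLS + RJ-MCMC).

The model is a generalized least squares regression whose residuals follow
a multivariate normal with covariance ``sigma2 * C_lambda``, where ``C`` is
the Brownian covariance implied by the tree and ``C_lambda`` is its Pagel
lambda transform.  A reversible-jump MCMC samples, jointly:

* which candidate predictors enter the model (inclusion indicators),
* the coefficients of included predictors and the intercept,
* lambda in [0, 1] (uniform prior),
* the residual rate sigma2 (Jeffreys 1/sigma2 prior, log-scale walk),
* which tree of the posterior tree sample is in force.

The target species is excluded from fitting.  Each retained state yields a
single draw from the conditional (partitioned-Gaussian) predictive normal
for the target, so the set of retained draws integrates over parameter,
model, and phylogenetic uncertainty.  Outliers are species whose observed
value falls in the far two-sided tail of that predictive distribution, with
trait-wise selection by Benjamini-Hochberg FDR.

Priors follow the original analysis where stated (uniform coefficient and
lambda priors); the uniform coefficient prior is made proper by wide bounds
so that reversible-jump birth moves have a density to propose from.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.stats import norm

from .treeio import PhyloCovariance, TreeSet, lambda_scale
from .trait_data import MASS, TraitTable, trait_subset

__all__ = [
    "RegressionState",
    "MCMCConfig",
    "PredictionChain",
    "OutlierResult",
    "pgls_loglik",
    "fit_rjmcmc",
    "predict_target",
    "conditional_moments",
    "outlier_probability",
    "fdr_select",
]

LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class RegressionState:
    """One draw of the PGLS regression model."""

    intercept: float
    include: tuple[bool, ...]
    beta: tuple[float, ...]
    sigma2: float
    lam: float
    tree_index: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        if len(self.include) != len(self.beta):
            raise ValueError("include/beta length mismatch")

    def effective_beta(self) -> np.ndarray:
        return np.where(self.include, self.beta, 0.0)


@dataclass
class MCMCConfig:
    """Sampler settings.  ``seed`` is mandatory: every run is reproducible."""

    steps: int = 200_100
    burn_in: int = 100
    thin: int = 100
    seed: int | None = None
    coef_bound: float = 100.0     # half-width of the proper uniform coefficient prior
    coef_scale: float | None = None  # RW scale for coefficients; default 0.25*sd(y)
    lam_scale: float = 0.15
    logsig_scale: float = 0.6
    autocorr_warn: float = 0.5

    def n_keep(self) -> int:
        if self.steps <= self.burn_in:
            raise ValueError("steps must exceed burn_in")
        return (self.steps - self.burn_in) // self.thin


@dataclass
class PredictionChain:
    """Thinned posterior of regression states plus one predictive draw each."""

    params: pd.DataFrame          # intercept, beta_*, incl_*, sigma2, lam, tree_index
    draws: np.ndarray             # predictive draw for the target per state
    loglik: np.ndarray
    trait: str
    target: str
    observed: float               # target's observed value (NaN if unknown)
    species: list[str]
    predictors: tuple[str, ...]
    config: MCMCConfig
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.draws)

    def state(self, i: int) -> RegressionState:
        row = self.params.iloc[i]
        return RegressionState(
            intercept=float(row["intercept"]),
            include=tuple(bool(row[f"incl_{p}"]) for p in self.predictors),
            beta=tuple(float(row[f"beta_{p}"]) for p in self.predictors),
            sigma2=float(row["sigma2"]),
            lam=float(row["lam"]),
            tree_index=int(row["tree_index"]),
        )


@dataclass
class OutlierResult:
    """Per-trait prediction summary mirroring the headline report columns."""

    trait: str
    n_species: int
    observed: float
    mean: float
    sd: float
    probability: float
    flag: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


# ---------------------------------------------------------------------------
# likelihood


def _mvn_loglik(resid: np.ndarray, cov: np.ndarray) -> float:
    try:
        c, low = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "singular phylogenetic covariance; consider adding a small jitter"
        ) from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = resid @ cho_solve((c, low), resid)
    n = len(resid)
    return -0.5 * (n * LOG2PI + logdet + quad)


def pgls_loglik(
    state: RegressionState, y: np.ndarray, X: np.ndarray, C: PhyloCovariance
) -> float:
    """Log-density of ``y`` under the PGLS model at ``state``.

    Mean is ``intercept + X @ beta`` (included predictors only); covariance
    ``sigma2 * lambda_scale(C, lam)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    resid = y - state.intercept - X @ state.effective_beta()
    cov = state.sigma2 * lambda_scale(C, state.lam).matrix
    return _mvn_loglik(resid, cov)


def conditional_moments(
    state: RegressionState,
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    x_target: np.ndarray,
    C: PhyloCovariance,
    target: str,
) -> tuple[float, float]:
    """Conditional-normal predictive mean and variance for the target tip.

    ``C`` covers the observed species plus the target; all blocks are
    lambda-scaled (diagonals untouched).  A negative variance arising from
    round-off is clamped to zero with a warning.
    """
    labels = list(C.labels)
    t = labels.index(target)
    obs = [i for i in range(len(labels)) if i != t]
    M = lambda_scale(C, state.lam).matrix
    Coo = M[np.ix_(obs, obs)]
    cot = M[obs, t]
    ctt = M[t, t]
    beta = state.effective_beta()
    X_obs = np.asarray(X_obs, dtype=float)
    if X_obs.ndim == 1:
        X_obs = X_obs[:, None]
    x_target = np.atleast_1d(np.asarray(x_target, dtype=float))
    resid = np.asarray(y_obs, float) - state.intercept - X_obs @ beta
    sol = np.linalg.solve(Coo, np.column_stack([resid, cot]))
    mean = state.intercept + float(np.asarray(x_target) @ beta) + cot @ sol[:, 0]
    var = state.sigma2 * (ctt - cot @ sol[:, 1])
    if var < 0:
        if var < -1e-8 * max(ctt, 1.0) * state.sigma2:
            _warnings.warn(f"predictive variance {var:.3g} clamped to 0")
        var = 0.0
    return float(mean), float(var)


def predict_target(
    state: RegressionState,
    target_covariates: np.ndarray,
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    C: PhyloCovariance,
    target: str,
    rng: np.random.Generator,
) -> float:
    """One draw from the conditional predictive normal for the target."""
    mean, var = conditional_moments(state, y_obs, X_obs, target_covariates, C, target)
    return float(rng.normal(mean, math.sqrt(var)))


# ---------------------------------------------------------------------------
# sampler


class _Cache:
    """Cholesky workspace for one (tree, lambda) combination."""

    __slots__ = ("L", "logdet", "ucols", "atail")

    def __init__(self, Coo_lam: np.ndarray, Xd: np.ndarray, cot_lam: np.ndarray):
        self.L = cholesky(Coo_lam, lower=True)
        self.logdet = 2.0 * float(np.sum(np.log(np.diag(self.L))))
        # whitened design columns (intercept first), for O(n) coefficient moves
        self.ucols = solve_triangular(self.L, Xd, lower=True)
        self.atail = solve_triangular(self.L, cot_lam, lower=True)


def _ll(n: int, logdet: float, quad: float, sig2: float) -> float:
    return -0.5 * (n * (LOG2PI + math.log(sig2)) + logdet + quad / sig2)


def fit_rjmcmc(
    table: TraitTable,
    trees: TreeSet,
    trait: str,
    target: str,
    config: MCMCConfig,
    predictors: Sequence[str] = (MASS,),
) -> PredictionChain:
    """Sample the posterior of PGLS models for ``trait`` and predict ``target``.

    The target species is removed from the fitting data and tree covariance
    conditioning handles its phylogenetic position.  Returns the thinned
    chain with one predictive draw per retained state.
    """
    if config.seed is None:
        raise ValueError("MCMCConfig.seed is required")
    rng = np.random.default_rng(config.seed)

    species_all, mass_all, y_all = trait_subset(table, trait)
    have = set(species_all)
    row = table.data.loc[target]
    obs_val = float(row[trait]) if target in have else float("nan")
    # canonical (sorted) fitting order: results do not depend on row order
    species = sorted(s for s in species_all if s != target)
    if len(species) < 3:
        raise ValueError(f"too few species with data for trait {trait!r}")
    sub = table.data.loc[species, list(predictors)]
    if sub.isna().any().any():
        raise ValueError("missing predictor values among fitting species")
    X = sub.to_numpy(dtype=float)
    y = table.data.loc[species, trait].to_numpy(dtype=float)
    x_t = table.data.loc[target, list(predictors)].to_numpy(dtype=float)
    if np.isnan(x_t).any():
        raise ValueError(f"target {target!r} lacks predictor values")
    n = len(species)
    p = len(predictors)

    # per-tree covariance blocks, observed species first, target last
    blocks = []
    order = species + [target]
    for ph in trees:
        C = ph.prune(order).vcv().reorder(order)
        M = C.matrix
        blocks.append((M[:n, :n].copy(), np.diag(M[:n, :n]).copy(), M[:n, n].copy(),
                       float(M[n, n])))
    ntrees = len(blocks)

    # initial state
    sd_y = float(np.std(y)) or 1.0
    coef_scale = config.coef_scale if config.coef_scale is not None else 0.25 * sd_y
    bound = config.coef_bound
    a = float(np.mean(y))
    incl = np.zeros(p, dtype=bool)
    beta = np.zeros(p)
    sig2 = float(np.var(y)) or 1.0
    lam = 0.5
    tidx = 0
    Xd = np.column_stack([np.ones(n), X])  # design incl. intercept

    def make_cache(ti: int, lm: float) -> _Cache:
        Coo, dg, cot, _ = blocks[ti]
        Coo_lam = lm * Coo + (1.0 - lm) * np.diag(dg)
        return _Cache(Coo_lam, Xd, lm * cot)

    cache = make_cache(tidx, lam)
    mu = a + X @ np.where(incl, beta, 0.0)
    r = y - mu
    q = solve_triangular(cache.L, r, lower=True)
    quad = float(q @ q)

    n_keep = config.n_keep()
    keep_i = 0
    P_int = np.empty(n_keep)
    P_beta = np.empty((n_keep, p))
    P_incl = np.empty((n_keep, p), dtype=bool)
    P_sig = np.empty(n_keep)
    P_lam = np.empty(n_keep)
    P_tree = np.empty(n_keep, dtype=int)
    P_ll = np.empty(n_keep)
    P_draw = np.empty(n_keep)
    warns: list[str] = []

    # move mix: toggle, coefficient, lambda, sigma2, tree
    probs = np.array([0.15, 0.30, 0.20, 0.20, 0.15])
    if ntrees == 1:
        probs = np.array([0.18, 0.35, 0.24, 0.23, 0.0])
    cum = np.cumsum(probs / probs.sum())

    ll = _ll(n, cache.logdet, quad, sig2)
    exp = math.exp
    log = math.log

    for step in range(1, config.steps + 1):
        u = rng.random()
        if u < cum[0]:
            # reversible-jump toggle of one predictor.  Birth draws the new
            # coefficient from an independence proposal centred on the
            # conditional GLS estimate; the proper uniform prior enters the
            # acceptance ratio explicitly (Jacobian 1).
            j = int(rng.integers(p))
            uj = cache.ucols[:, j + 1]
            uu = float(uj @ uj)
            log_prior = -log(2.0 * bound)
            if incl[j]:
                q_new = q + beta[j] * uj
                quad_new = float(q_new @ q_new)
                ll_new = _ll(n, cache.logdet, quad_new, sig2)
                bhat = float(uj @ q_new) / uu
                s_p2 = 2.0 * sig2 / uu
                log_q = -0.5 * (LOG2PI + log(s_p2) + (beta[j] - bhat) ** 2 / s_p2)
                if log(rng.random() + 1e-300) < (ll_new - ll) + log_q - log_prior:
                    incl[j] = False
                    q, quad, ll = q_new, quad_new, ll_new
                    r = r + beta[j] * X[:, j]
            else:
                bhat = float(uj @ q) / uu
                s_p2 = 2.0 * sig2 / uu
                b_new = rng.normal(bhat, math.sqrt(s_p2))
                if -bound <= b_new <= bound:
                    log_q = -0.5 * (LOG2PI + log(s_p2) + (b_new - bhat) ** 2 / s_p2)
                    q_new = q - b_new * uj
                    quad_new = float(q_new @ q_new)
                    ll_new = _ll(n, cache.logdet, quad_new, sig2)
                    if log(rng.random() + 1e-300) < (ll_new - ll) + log_prior - log_q:
                        incl[j] = True
                        beta[j] = b_new
                        q, quad, ll = q_new, quad_new, ll_new
                        r = r - b_new * X[:, j]
        elif u < cum[1]:
            # random-walk on the intercept or one included coefficient
            act = [-1] + [j for j in range(p) if incl[j]]
            k = act[int(rng.integers(len(act)))]
            delta = rng.normal(0.0, coef_scale)
            if k == -1:
                new = a + delta
                col = cache.ucols[:, 0]
                xcol = None
            else:
                new = beta[k] + delta
                col = cache.ucols[:, k + 1]
                xcol = X[:, k]
            if -bound <= new <= bound:
                q_new = q - delta * col
                quad_new = float(q_new @ q_new)
                ll_new = _ll(n, cache.logdet, quad_new, sig2)
                if log(rng.random() + 1e-300) < ll_new - ll:
                    if k == -1:
                        a = new
                        r = r - delta
                    else:
                        beta[k] = new
                        r = r - delta * xcol
                    q, quad, ll = q_new, quad_new, ll_new
        elif u < cum[2]:
            # reflected random walk on lambda in [0, 1], uniform prior
            lam_new = lam + rng.normal(0.0, config.lam_scale)
            lam_new = abs(lam_new)
            if lam_new > 1.0:
                lam_new = 2.0 - lam_new
            lam_new = min(max(lam_new, 0.0), 1.0)
            cand = make_cache(tidx, lam_new)
            q_new = solve_triangular(cand.L, r, lower=True)
            quad_new = float(q_new @ q_new)
            ll_new = _ll(n, cand.logdet, quad_new, sig2)
            if log(rng.random() + 1e-300) < ll_new - ll:
                lam, cache, q, quad, ll = lam_new, cand, q_new, quad_new, ll_new
        elif u < cum[3]:
            # log-scale walk on sigma2; Jeffreys prior cancels the Jacobian
            s_new = sig2 * exp(rng.normal(0.0, config.logsig_scale))
            ll_new = _ll(n, cache.logdet, quad, s_new)
            if log(rng.random() + 1e-300) < ll_new - ll:
                sig2, ll = s_new, ll_new
        else:
            # resample which tree of the posterior sample is in force
            t_new = int(rng.integers(ntrees))
            if t_new != tidx:
                cand = make_cache(t_new, lam)
                q_new = solve_triangular(cand.L, r, lower=True)
                quad_new = float(q_new @ q_new)
                ll_new = _ll(n, cand.logdet, quad_new, sig2)
                if log(rng.random() + 1e-300) < ll_new - ll:
                    tidx, cache, q, quad, ll = t_new, cand, q_new, quad_new, ll_new

        if step > config.burn_in and (step - config.burn_in) % config.thin == 0:
            bfull = np.where(incl, beta, 0.0)
            pm = a + float(x_t @ bfull) + float(cache.atail @ q)
            pv = sig2 * (blocks[tidx][3] - float(cache.atail @ cache.atail))
            if pv < 0:
                pv = 0.0
            P_int[keep_i] = a
            P_beta[keep_i] = beta
            P_incl[keep_i] = incl
            P_sig[keep_i] = sig2
            P_lam[keep_i] = lam
            P_tree[keep_i] = tidx
            P_ll[keep_i] = ll
            P_draw[keep_i] = rng.normal(pm, math.sqrt(pv))
            keep_i += 1

    # likelihood autocorrelation check across the thinned chain
    if n_keep >= 10:
        s = P_ll - P_ll.mean()
        denom = float(s @ s)
        if denom > 0:
            ac1 = float(s[:-1] @ s[1:]) / denom
            if ac1 > config.autocorr_warn:
                warns.append(
                    f"thinned log-likelihood lag-1 autocorrelation {ac1:.2f} exceeds "
                    f"{config.autocorr_warn}: chain may be under-thinned"
                )

    cols = {"intercept": P_int}
    for j, name in enumerate(predictors):
        cols[f"beta_{name}"] = P_beta[:, j]
        cols[f"incl_{name}"] = P_incl[:, j]
    cols.update({"sigma2": P_sig, "lam": P_lam, "tree_index": P_tree})
    params = pd.DataFrame(cols)
    return PredictionChain(
        params=params, draws=P_draw, loglik=P_ll, trait=trait, target=target,
        observed=obs_val, species=species, predictors=tuple(predictors),
        config=config, warnings=warns,
    )


# ---------------------------------------------------------------------------
# outlier calls


def outlier_probability(
    draws: np.ndarray, observed: float, mode: str = "normal_approx"
) -> float:
    """Two-sided tail probability of ``observed`` under the predictive draws.

    ``normal_approx`` fits a normal to the draws (the draws are inspected
    for normality upstream); ``empirical`` uses the add-one-smoothed
    empirical two-sided tail fraction.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 predictive draws")
    if not np.isfinite(observed):
        raise ValueError("observed value must be finite")
    m = float(draws.mean())
    if mode == "normal_approx":
        s = float(draws.std(ddof=1))
        if s == 0.0:
            _warnings.warn("zero predictive spread; probability degenerate")
            return 1.0 if observed == m else 0.0
        return float(2.0 * norm.sf(abs(observed - m) / s))
    if mode == "empirical":
        nd = draws.size
        upper = (np.sum(draws >= observed) + 1) / (nd + 1)
        lower = (np.sum(draws <= observed) + 1) / (nd + 1)
        return float(min(1.0, 2.0 * min(upper, lower)))
    raise ValueError(f"unknown mode: {mode!r}")


def fdr_select(
    probabilities: Mapping[str, float], q: float = 0.10, tol: float = 0.0
) -> dict[str, bool]:
    """Benjamini-Hochberg step-up selection at FDR ``q``.

    ``tol`` loosens the step-up comparison (``p_(i) <= q*i/m + tol``) for
    inputs that are printed roundings of the underlying probabilities; leave
    at 0 for exact p-values.
    """
    items = list(probabilities.items())
    if not items:
        return {}
    for k, v in items:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"probability for {k!r} outside [0, 1]")
    m = len(items)
    order = sorted(items, key=lambda kv: kv[1])
    cutoff = -1.0
    for i, (_, pv) in enumerate(order, start=1):
        if pv <= q * i / m + tol:
            cutoff = pv
    return {k: (v <= cutoff) for k, v in items}
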