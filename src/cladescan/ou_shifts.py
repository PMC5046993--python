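"""Multi-optimum Ornstein-Uhlenbeck regime-shift inference on a phylogeny.

A trait evolves along the tree as an OU process with mean-reversion rate
``alpha``, diffusion rate ``sigma2``, a linear effect ``beta`` of log body
mass, and a piecewise-constant optimum: the root regime carries optimum
``theta0`` and each *shift* replaces the optimum at a point on a branch
(at most one shift per branch).  The root state is fixed at ``theta0``
(non-stationary start), so for tip *i* at root-to-tip time ``T_i``:

* mean:  ``E[y_i] = sum_r theta_r * w_ir + beta * mass_i`` where the regime
  weights are ``w = e^{-alpha (T_i - t_end)} - e^{-alpha (T_i - t_start)}``
  per regime segment on the root-to-tip path, with the root regime also
  collecting the initial-condition weight ``e^{-alpha T_i}``; weights sum
  to one for every tip.
* covariance: ``Cov(y_i, y_j) = sigma2/(2 alpha) * e^{-alpha(T_i+T_j-2 t_ij)}
  * (1 - e^{-2 alpha t_ij})`` with ``t_ij`` the shared root-path time.
  As ``alpha -> 0`` this reduces to the Brownian covariance ``sigma2 * C``.

A reversible-jump MCMC samples the shift count ``k`` (Poisson prior), shift
locations (uniform over branches, at most one per branch, uniform position
within a branch), optima (normal prior matched to the trait's moments), and
the scalar parameters (half-Cauchy priors on alpha and sigma2, uniform on
beta).  Two chains are run; convergence is assessed with Gelman's R on the
log-likelihood series, chains are truncated to improve R, combined, and
summarized per branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .treeio import Phylogeny

__all__ = [
    "Shift",
    "ShiftConfiguration",
    "OUState",
    "OUPriors",
    "OUConfig",
    "OUChain",
    "ShiftSummary",
    "Diagnostics",
    "regime_weights",
    "ou_loglik",
    "fit_ou_rjmcmc",
    "gelman_r",
    "effective_size",
    "combine_chains",
    "summarize_shifts",
    "shift_frequencies",
    "shift_decision",
]

LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Shift:
    """An optimum replacement at ``position`` (fraction from the rootward end)
    along the branch identified by ``branch`` (tip-set bipartition string)."""

    branch: str
    position: float
    theta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.position < 1.0):
            raise ValueError("shift position must lie in [0, 1)")


@dataclass(frozen=True)
class ShiftConfiguration:
    shifts: tuple[Shift, ...] = ()

    def __post_init__(self) -> None:
        branches = [s.branch for s in self.shifts]
        if len(set(branches)) != len(branches):
            raise ValueError("at most one shift per branch")

    @property
    def k(self) -> int:
        return len(self.shifts)


@dataclass(frozen=True)
class OUState:
    alpha: float
    sigma2: float
    beta: float
    theta0: float
    shifts: ShiftConfiguration = field(default_factory=ShiftConfiguration)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    def thetas(self) -> np.ndarray:
        """Optimum per regime: root regime first, then one per shift."""
        return np.array([self.theta0] + [s.theta for s in self.shifts.shifts])


@dataclass
class OUPriors:
    """Prior settings; scales unset here are derived from the data and tree."""

    alpha_scale: float | None = None    # half-Cauchy; default 1 / tree height
    sigma2_scale: float | None = None   # half-Cauchy; default var(y) / tree height
    beta_bound: float = 100.0           # proper uniform on [-bound, bound]
    k_mean: float = 1.0                 # Poisson mean for the shift count
    theta_mean: float | None = None     # Normal; default mean(y)
    theta_sd: float | None = None       # Normal; default sd(y)

    def resolved(self, y: np.ndarray, tree_height: float) -> "OUPriors":
        return OUPriors(
            alpha_scale=self.alpha_scale or 1.0 / tree_height,
            sigma2_scale=self.sigma2_scale or float(np.var(y)) / tree_height or 1.0,
            beta_bound=self.beta_bound,
            k_mean=self.k_mean,
            theta_mean=self.theta_mean if self.theta_mean is not None else float(np.mean(y)),
            theta_sd=self.theta_sd or float(np.std(y)) or 1.0,
        )


@dataclass
class OUConfig:
    steps: int = 2_002_000
    burn_in: int = 2_000
    thin: int = 1_000
    chains: int = 2
    seed: int | None = None
    likelihood: str = "full"   # "constant" samples the prior (sanity checks)

    def n_keep(self) -> int:
        if self.steps <= self.burn_in:
            raise ValueError("steps must exceed burn_in")
        return (self.steps - self.burn_in) // self.thin


@dataclass
class OUChain:
    states: list[OUState]
    loglik: np.ndarray
    config: OUConfig
    seed: int
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class ShiftSummary:
    """Posterior summary of optimum shifts on one branch."""

    branch: str
    proportion: float
    mean_shift: float | None
    sd_shift: float | None
    prop_positive: float | None
    rank: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError("proportion must lie in [0, 1]")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


@dataclass
class Diagnostics:
    gelman_r: float
    ess: float
    truncation: float
    n_combined: int


# ---------------------------------------------------------------------------
# model: regime weights, likelihood


def _shift_times(tree: Phylogeny, shifts: ShiftConfiguration) -> dict[int, tuple[float, float]]:
    """Map branch node -> (absolute shift time, theta)."""
    bindex = tree.branch_index()
    out = {}
    for s in shifts.shifts:
        if s.branch not in bindex:
            raise KeyError(f"shift references branch absent from tree: {s.branch!r}")
        node = bindex[s.branch]
        t0 = tree.depth[tree.parent[node]]
        out[node] = (t0 + s.position * tree.length[node], s.theta)
    return out


def regime_weights(
    tree: Phylogeny, shifts: ShiftConfiguration, alpha: float
) -> np.ndarray:
    """Per-tip weights over regimes (column 0 = root regime) summing to one."""
    node_shift = _shift_times(tree, shifts)
    order = [tree.branch_index()[s.branch] for s in shifts.shifts]
    return _regime_weights_nodes(tree, {nd: node_shift[nd][0] for nd in order}, alpha)


def _regime_weights_nodes(
    tree: Phylogeny, shift_time: dict[int, float], alpha: float
) -> np.ndarray:
    """Weights given shift times keyed by branch node, regime columns in the
    iteration order of ``shift_time`` (root regime first)."""
    nodes = list(shift_time)
    col = {nd: j + 1 for j, nd in enumerate(nodes)}
    W = np.zeros((tree.n_tips, len(nodes) + 1))
    for i, tip_node in enumerate(tree.tip_indices):
        T = tree.depth[tip_node]
        # events: (time, regime column), for shifts on the root path
        events = [(0.0, 0)]
        for nd in tree.path_to_root(int(tip_node)):
            if nd in shift_time:
                events.append((shift_time[nd], col[nd]))
        events.sort(key=lambda e: e[0])
        W[i, 0] = math.exp(-alpha * T)
        for j, (t_start, reg) in enumerate(events):
            t_end = events[j + 1][0] if j + 1 < len(events) else T
            W[i, reg] += math.exp(-alpha * (T - t_end)) - math.exp(-alpha * (T - t_start))
    return W


def _ou_cov_factor(tree_C: np.ndarray, depths: np.ndarray, alpha: float) -> np.ndarray:
    """Covariance divided by sigma2, from shared times ``tree_C`` (BM vcv)."""
    t = tree_C
    Tsum = depths[:, None] + depths[None, :]
    with np.errstate(over="ignore"):
        K = (-np.expm1(-2.0 * alpha * t) / (2.0 * alpha)) * np.exp(-alpha * (Tsum - 2.0 * t))
    return K


def ou_loglik(
    state: OUState, y: np.ndarray, mass: np.ndarray, tree: Phylogeny
) -> float:
    """Multivariate-normal log density of ``y`` under the fixed-root OU model."""
    y = np.asarray(y, dtype=float)
    mass = np.asarray(mass, dtype=float)
    if len(y) != tree.n_tips or len(mass) != tree.n_tips:
        raise ValueError("y/mass must align with the tree's tips")
    W = regime_weights(tree, state.shifts, state.alpha)
    mu = W @ state.thetas() + state.beta * mass
    C = tree.vcv().matrix
    K = _ou_cov_factor(C, tree.tip_depths(), state.alpha)
    V = state.sigma2 * K
    try:
        L = cholesky(V, lower=True)
    except np.linalg.LinAlgError:
        V = V + 1e-10 * np.eye(len(y)) * max(V.max(), 1.0)
        L = cholesky(V, lower=True)  # raises again if still non-PSD
    q = solve_triangular(L, y - mu, lower=True)
    return float(-0.5 * (len(y) * LOG2PI + 2.0 * np.sum(np.log(np.diag(L))) + q @ q))


# ---------------------------------------------------------------------------
# sampler


def _half_cauchy_logpdf(x: float, scale: float) -> float:
    return math.log(2.0 / (math.pi * scale * (1.0 + (x / scale) ** 2)))


def _norm_logpdf(x: float, m: float, s: float) -> float:
    return -0.5 * (LOG2PI + 2.0 * math.log(s) + ((x - m) / s) ** 2)


def fit_ou_rjmcmc(
    y: np.ndarray,
    mass: np.ndarray,
    tree: Phylogeny,
    priors: OUPriors | None = None,
    config: OUConfig | None = None,
) -> list[OUChain]:
    """Run ``config.chains`` independent reversible-jump chains.

    Each chain's retained sample has length ``(steps - burn_in) / thin``.
    A warning is recorded when the number of tips is less than four times
    the posterior mean shift count (a regime in which shift-location
    estimates are known to degrade).
    """
    config = config or OUConfig()
    if config.seed is None:
        raise ValueError("OUConfig.seed is required")
    y = np.asarray(y, dtype=float)
    mass = np.asarray(mass, dtype=float)
    pri = (priors or OUPriors()).resolved(y, tree.height)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = []
    for cs in seeds:
        chains.append(_run_one_chain(y, mass, tree, pri, config, cs))
    return chains


def _run_one_chain(
    y: np.ndarray,
    mass: np.ndarray,
    tree: Phylogeny,
    pri: OUPriors,
    config: OUConfig,
    seedseq: np.random.SeedSequence,
) -> OUChain:
    rng = np.random.default_rng(seedseq)
    n = tree.n_tips
    C = tree.vcv().matrix
    depths = tree.tip_depths()
    branch_nodes = list(tree.branches())
    branch_ids = tree.branch_ids()
    B = len(branch_nodes)
    parent = tree.parent
    length = tree.length
    node_depth = tree.depth
    constant_lik = config.likelihood == "constant"

    # state: scalars + shifts as dict node -> [position, theta]
    alpha = 1.0 / tree.height
    sigma2 = float(np.var(y)) or 1.0
    beta = 0.0
    theta0 = float(np.mean(y))
    shifts: dict[int, list[float]] = {}

    # caches
    def cov_chol(al: float, s2: float):
        K = _ou_cov_factor(C, depths, al)
        L = cholesky(s2 * K, lower=True)
        return L, 2.0 * float(np.sum(np.log(np.diag(L))))

    def weights(al: float, sh: dict[int, list[float]]) -> np.ndarray:
        st = {nd: node_depth[parent[nd]] + v[0] * length[nd] for nd, v in sh.items()}
        return _regime_weights_nodes(tree, st, al)

    def mean_vec(W: np.ndarray, th0: float, sh: dict[int, list[float]], b: float):
        th = np.array([th0] + [v[1] for v in sh.values()])
        return W @ th + b * mass

    def loglik(mu, L, logdet, ):
        if constant_lik:
            return 0.0
        q = solve_triangular(L, y - mu, lower=True)
        return float(-0.5 * (n * LOG2PI + logdet + q @ q))

    if constant_lik:
        L, logdet = np.eye(n), 0.0
    else:
        L, logdet = cov_chol(alpha, sigma2)
    W = weights(alpha, shifts)
    mu = mean_vec(W, theta0, shifts, beta)
    ll = loglik(mu, L, logdet)

    lp_alpha = _half_cauchy_logpdf(alpha, pri.alpha_scale)
    lp_sigma2 = _half_cauchy_logpdf(sigma2, pri.sigma2_scale)

    n_keep = config.n_keep()
    states: list[OUState] = []
    lls = np.empty(n_keep)
    keep_i = 0
    warns: list[str] = []

    # move mix: alpha, sigma2, beta, theta0, shift-theta, birth/death, relocate
    probs = np.array([0.13, 0.13, 0.10, 0.10, 0.17, 0.22, 0.15])
    cum = np.cumsum(probs / probs.sum())
    log = math.log
    exp = math.exp
    theta_prop = 0.5 * pri.theta_sd
    accepted = 0
    window = 0

    # tips below each branch, for the data-informed half of the birth proposal
    below: dict[int, np.ndarray] = {}
    tip_pos = {int(nd): i for i, nd in enumerate(tree.tip_indices)}
    for nd in branch_nodes:
        tips = [tip_pos[m] for m in tip_pos
                if nd in tree.path_to_root(m) or nd == m]
        below[nd] = np.array(tips, dtype=int)

    def _birth_q(nd: int, b: float) -> tuple[float, float]:
        """Centre and sd of the data-informed birth proposal for branch nd."""
        sel = below[nd]
        centre = float(np.mean(y[sel] - b * mass[sel]))
        return centre, 0.5 * pri.theta_sd

    def _birth_q_logpdf(th: float, nd: int, b: float) -> float:
        # 50/50 mixture of the theta prior and the data-informed normal
        m_q, s_q = _birth_q(nd, b)
        return float(np.logaddexp(
            math.log(0.5) + _norm_logpdf(th, pri.theta_mean, pri.theta_sd),
            math.log(0.5) + _norm_logpdf(th, m_q, s_q),
        ))

    def b_prob(k: int) -> float:
        if k == 0:
            return 1.0
        if k >= B:
            return 0.0
        return 0.5

    for step in range(1, config.steps + 1):
        u = rng.random()
        window += 1
        if u < cum[0]:
            # log-RW on alpha: covariance factor and regime weights both move
            a_new = alpha * exp(rng.normal(0.0, 0.4))
            lp_new = _half_cauchy_logpdf(a_new, pri.alpha_scale)
            if constant_lik:
                L2, logdet2 = L, logdet
            else:
                L2, logdet2 = cov_chol(a_new, sigma2)
            W2 = weights(a_new, shifts)
            mu2 = mean_vec(W2, theta0, shifts, beta)
            ll2 = loglik(mu2, L2, logdet2)
            if log(rng.random() + 1e-300) < (ll2 - ll) + (lp_new - lp_alpha) + (
                log(a_new) - log(alpha)
            ):
                alpha, L, logdet, W, mu, ll, lp_alpha = a_new, L2, logdet2, W2, mu2, ll2, lp_new
                accepted += 1
        elif u < cum[1]:
            s_new = sigma2 * exp(rng.normal(0.0, 0.5))
            lp_new = _half_cauchy_logpdf(s_new, pri.sigma2_scale)
            if constant_lik:
                ll2 = ll
                if log(rng.random() + 1e-300) < (lp_new - lp_sigma2) + (log(s_new) - log(sigma2)):
                    sigma2, lp_sigma2 = s_new, lp_new
                    accepted += 1
            else:
                # V = sigma2*K: rescale cached factor instead of refactorizing
                ratio = s_new / sigma2
                logdet2 = logdet + n * log(ratio)
                L2 = L * math.sqrt(ratio)
                ll2 = loglik(mu, L2, logdet2)
                if log(rng.random() + 1e-300) < (ll2 - ll) + (lp_new - lp_sigma2) + (
                    log(s_new) - log(sigma2)
                ):
                    sigma2, L, logdet, ll, lp_sigma2 = s_new, L2, logdet2, ll2, lp_new
                    accepted += 1
        elif u < cum[2]:
            b_new = beta + rng.normal(0.0, 0.3)
            if abs(b_new) <= pri.beta_bound:
                mu2 = mu + (b_new - beta) * mass
                ll2 = loglik(mu2, L, logdet)
                if log(rng.random() + 1e-300) < ll2 - ll:
                    beta, mu, ll = b_new, mu2, ll2
                    accepted += 1
        elif u < cum[3]:
            t_new = theta0 + rng.normal(0.0, theta_prop)
            dlp = _norm_logpdf(t_new, pri.theta_mean, pri.theta_sd) - _norm_logpdf(
                theta0, pri.theta_mean, pri.theta_sd
            )
            mu2 = mu + (t_new - theta0) * W[:, 0]
            ll2 = loglik(mu2, L, logdet)
            if log(rng.random() + 1e-300) < (ll2 - ll) + dlp:
                theta0, mu, ll = t_new, mu2, ll2
                accepted += 1
        elif u < cum[4]:
            # update one shift's optimum
            if shifts:
                nodes = list(shifts)
                nd = nodes[int(rng.integers(len(nodes)))]
                jcol = nodes.index(nd) + 1
                old = shifts[nd][1]
                t_new = old + rng.normal(0.0, theta_prop)
                dlp = _norm_logpdf(t_new, pri.theta_mean, pri.theta_sd) - _norm_logpdf(
                    old, pri.theta_mean, pri.theta_sd
                )
                mu2 = mu + (t_new - old) * W[:, jcol]
                ll2 = loglik(mu2, L, logdet)
                if log(rng.random() + 1e-300) < (ll2 - ll) + dlp:
                    shifts[nd][1] = t_new
                    mu, ll = mu2, ll2
                    accepted += 1
        elif u < cum[5]:
            # reversible-jump birth/death of a shift
            k = len(shifts)
            birth = rng.random() < b_prob(k)
            if birth and k < B:
                free = [nd for nd in branch_nodes if nd not in shifts]
                nd = free[int(rng.integers(len(free)))]
                pos = rng.random()
                if rng.random() < 0.5:
                    th = rng.normal(pri.theta_mean, pri.theta_sd)
                else:
                    m_q, s_q = _birth_q(nd, beta)
                    th = rng.normal(m_q, s_q)
                sh2 = dict(shifts)
                sh2[nd] = [pos, th]
                W2 = weights(alpha, sh2)
                mu2 = mean_vec(W2, theta0, sh2, beta)
                ll2 = loglik(mu2, L, logdet)
                lr = (
                    (ll2 - ll)
                    + log(pri.k_mean / (k + 1))
                    + log((1.0 - b_prob(k + 1)) / b_prob(k))
                    + _norm_logpdf(th, pri.theta_mean, pri.theta_sd)
                    - _birth_q_logpdf(th, nd, beta)
                )
                if log(rng.random() + 1e-300) < lr:
                    shifts, W, mu, ll = sh2, W2, mu2, ll2
                    accepted += 1
            elif (not birth) and k > 0:
                nodes = list(shifts)
                nd = nodes[int(rng.integers(len(nodes)))]
                th = shifts[nd][1]
                sh2 = {m: v for m, v in shifts.items() if m != nd}
                W2 = weights(alpha, sh2)
                mu2 = mean_vec(W2, theta0, sh2, beta)
                ll2 = loglik(mu2, L, logdet)
                lr = (
                    (ll2 - ll)
                    + log(k / pri.k_mean)
                    + log(b_prob(k - 1) / (1.0 - b_prob(k)))
                    + _birth_q_logpdf(th, nd, beta)
                    - _norm_logpdf(th, pri.theta_mean, pri.theta_sd)
                )
                if log(rng.random() + 1e-300) < lr:
                    shifts, W, mu, ll = sh2, W2, mu2, ll2
                    accepted += 1
        else:
            # relocate a shift: slide within branch, or jump to a free branch
            if shifts:
                nodes = list(shifts)
                nd = nodes[int(rng.integers(len(nodes)))]
                sh2 = None
                if rng.random() < 0.5:
                    pos = shifts[nd][0] + rng.normal(0.0, 0.2)
                    pos = abs(pos)
                    if pos >= 1.0:
                        pos = max(0.0, 2.0 - pos - 1e-12)
                    sh2 = dict(shifts)
                    sh2[nd] = [pos, shifts[nd][1]]
                else:
                    free = [m for m in branch_nodes if m not in shifts]
                    if free:
                        nd2 = free[int(rng.integers(len(free)))]
                        sh2 = {m: v for m, v in shifts.items() if m != nd}
                        sh2[nd2] = [rng.random(), shifts[nd][1]]
                if sh2 is not None:
                    W2 = weights(alpha, sh2)
                    mu2 = mean_vec(W2, theta0, sh2, beta)
                    ll2 = loglik(mu2, L, logdet)
                    if log(rng.random() + 1e-300) < ll2 - ll:
                        shifts, W, mu, ll = sh2, W2, mu2, ll2
                        accepted += 1

        if step % 5000 == 0:
            if window >= 5000 and accepted == 0:
                warns.append(f"no accepted proposals in the {window} steps ending at {step}")
            accepted = 0
            window = 0

        if step > config.burn_in and (step - config.burn_in) % config.thin == 0:
            cfg = ShiftConfiguration(tuple(
                Shift(branch_ids[nd], v[0], v[1]) for nd, v in shifts.items()
            ))
            states.append(OUState(alpha, sigma2, beta, theta0, cfg))
            lls[keep_i] = ll
            keep_i += 1

    mean_k = float(np.mean([s.shifts.k for s in states])) if states else 0.0
    if tree.n_tips < 4.0 * mean_k:
        warns.append(
            f"only {tree.n_tips} tips for posterior mean {mean_k:.1f} shifts; "
            "estimates may be degraded (want tips >= 4k)"
        )
    return OUChain(states=states, loglik=lls, config=config,
                   seed=int(seedseq.generate_state(1)[0] % 2**31), warnings=warns)


# ---------------------------------------------------------------------------
# diagnostics


def gelman_r(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor (between/within variance form)."""
    arrs = [np.asarray(c, dtype=float) for c in chains]
    if len(arrs) < 2:
        raise ValueError("need at least 2 chains")
    n = len(arrs[0])
    if n < 10 or any(len(a) != n for a in arrs):
        raise ValueError("chains must share a common length >= 10")
    means = np.array([a.mean() for a in arrs])
    variances = np.array([a.var(ddof=1) for a in arrs])
    W = variances.mean()
    if W <= 0:
        raise ValueError("zero within-chain variance (constant chain)")
    Bn = means.var(ddof=1)  # = B/n
    var_hat = (n - 1) / n * W + Bn
    return float(math.sqrt(var_hat / W))


def effective_size(series: np.ndarray) -> float:
    """Autocorrelation-time-adjusted sample size, capped at the series length.

    Uses ``n / (1 + 2 * sum(rho_t))`` with the sum truncated at the first
    non-positive autocorrelation (initial positive sequence).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("series too short")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return float(n)
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / denom
    s = 0.0
    for t in range(1, n):
        if acov[t] <= 0:
            break
        s += acov[t]
    ess = n / (1.0 + 2.0 * s)
    return float(min(ess, n))


def combine_chains(
    chains: Sequence[OUChain], n_candidates: int = 10
) -> tuple[list[OUState], Diagnostics]:
    """Combine chains after an equal front truncation chosen to improve R.

    Candidate truncation fractions 0, 1/20, ..., (n_candidates-1)/20 of each
    chain are scored by Gelman's R on the log-likelihood series; the smallest
    truncation attaining the minimal R is applied before pooling.
    """
    if len(chains) < 2:
        states = list(chains[0].states)
        ess = effective_size(chains[0].loglik)
        return states, Diagnostics(float("nan"), ess, 0.0, len(states))
    n = min(len(c) for c in chains)
    fracs = [i / 20 for i in range(n_candidates)]
    best_frac, best_r = 0.0, float("inf")
    for f in fracs:
        cut = int(f * n)
        if n - cut < 10:
            break
        r = gelman_r([c.loglik[cut:n] for c in chains])
        if r < best_r - 1e-12:
            best_r, best_frac = r, f
    cut = int(best_frac * n)
    states = [s for c in chains for s in c.states[cut:n]]
    lls = np.concatenate([c.loglik[cut:n] for c in chains])
    return states, Diagnostics(best_r, effective_size(lls), best_frac, len(states))


# ---------------------------------------------------------------------------
# summaries


def _shift_magnitudes(state: OUState, tree: Phylogeny) -> dict[str, float]:
    """theta_new - theta_parent-regime for every shift in ``state``."""
    bindex = tree.branch_index()
    node_theta = {bindex[s.branch]: s.theta for s in state.shifts.shifts}
    out = {}
    for s in state.shifts.shifts:
        nd = bindex[s.branch]
        parent_theta = state.theta0
        anc = tree.parent[nd]
        while anc >= 0:
            if anc in node_theta:
                parent_theta = node_theta[anc]
                break
            anc = tree.parent[anc]
        out[s.branch] = s.theta - parent_theta
    return out


def shift_frequencies(states: Sequence[OUState], tree: Phylogeny):
    """Per-branch posterior shift statistics over a combined sample.

    Returns a pandas DataFrame indexed by branch id with columns
    proportion, mean_shift, sd_shift, prop_positive, rank (rank 1 = most
    frequently shifted branch).
    """
    import pandas as pd

    if not states:
        raise ValueError("empty posterior sample")
    mags: dict[str, list[float]] = {bid: [] for bid in tree.branch_ids().values()}
    for st in states:
        for bid, m in _shift_magnitudes(st, tree).items():
            mags[bid].append(m)
    nmod = len(states)
    rows = {}
    for bid, vals in mags.items():
        count = len(vals)
        rows[bid] = {
            "proportion": count / nmod,
            "mean_shift": float(np.mean(vals)) if count else np.nan,
            "sd_shift": float(np.std(vals, ddof=1)) if count > 1 else np.nan,
            "prop_positive": float(np.mean(np.array(vals) > 0)) if count else np.nan,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["rank"] = (
        df["proportion"].rank(method="min", ascending=False).astype(int)
    )
    return df


def summarize_shifts(
    states: Sequence[OUState], tree: Phylogeny, branch: str
) -> ShiftSummary:
    """Posterior shift summary for one branch (tip label or bipartition id)."""
    if branch in tree.tip_labels:
        branch = tree.branch_ids()[tree.tip_node(branch)]
    df = shift_frequencies(states, tree)
    if branch not in df.index:
        raise KeyError(f"branch not in tree: {branch!r}")
    row = df.loc[branch]
    nanless = lambda v: None if (v is None or (isinstance(v, float) and math.isnan(v))) else float(v)
    return ShiftSummary(
        branch=branch,
        proportion=float(row["proportion"]),
        mean_shift=nanless(row["mean_shift"]),
        sd_shift=nanless(row["sd_shift"]),
        prop_positive=nanless(row["prop_positive"]),
        rank=int(row["rank"]),
    )


def shift_decision(
    summary: ShiftSummary, min_prop: float = 0.20, min_direction: float = 0.95
) -> dict:
    """The regime-shift call: enough models must place a shift on the branch
    (>= ``min_prop``) and the shifts must agree in sign (>= ``min_direction``)."""
    if summary.proportion < min_prop or summary.prop_positive is None:
        return {"shifted": False, "direction": "none"}
    pp = summary.prop_positive
    if max(pp, 1.0 - pp) < min_direction:
        return {"shifted": False, "direction": "none"}
    return {"shifted": True, "direction": "up" if pp >= 0.5 else "down"}
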