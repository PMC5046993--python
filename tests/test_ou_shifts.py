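import math

import numpy as np
import pytest
from scipy.stats import chisquare, multivariate_normal, norm, poisson

from cladescan import (
    OUConfig,
    OUPriors,
    OUState,
    Phylogeny,
    Shift,
    ShiftConfiguration,
    ShiftSummary,
    combine_chains,
    effective_size,
    fit_ou_rjmcmc,
    gelman_r,
    ou_loglik,
    regime_weights,
    shift_decision,
    summarize_shifts,
)
from cladescan.ou_shifts import shift_frequencies
from cladescan.synthetic_data import random_tree, simulate_ou


SIX_TIP = "(((A:0.2,B:0.2):0.3,(C:0.35,D:0.35):0.15):0.5,(E:0.6,F:0.6):0.4);"


def euler_oracle_moments(tree, state, n_rep=20_000, dt=2e-3, seed=0):
    """Independent oracle: simulate the OU SDE along the tree by
    Euler-Maruyama and return empirical tip means and covariance."""
    rng = np.random.default_rng(seed)
    shift_at = {}
    bindex = tree.branch_index()
    for s in state.shifts.shifts:
        nd = bindex[s.branch]
        shift_at[nd] = (s.position * tree.length[nd], s.theta)
    children = {i: [] for i in range(tree.n_nodes)}
    for i in range(1, tree.n_nodes):
        children[tree.parent[i]].append(i)
    vals = {0: np.full(n_rep, state.theta0)}
    theta_in = {0: state.theta0}

    def walk(node):
        for c in children[node]:
            y = vals[node].copy()
            theta = theta_in[node]
            t, blen = 0.0, tree.length[c]
            sw = shift_at.get(c)
            while t < blen - 1e-12:
                h = min(dt, blen - t)
                if sw is not None and t <= sw[0] < t + h:
                    theta = sw[1]
                y = y + state.alpha * (theta - y) * h + rng.normal(
                    size=n_rep
                ) * math.sqrt(state.sigma2 * h)
                t += h
            vals[c] = y
            theta_in[c] = theta
            walk(c)

    walk(0)
    tips = np.column_stack([vals[tree.tip_node(lab)] for lab in tree.tip_labels])
    return tips.mean(axis=0), np.cov(tips.T)


class TestRegimeWeights:
    def test_no_shifts_root_regime(self, five_taxon_tree):
        W = regime_weights(five_taxon_tree, ShiftConfiguration(), alpha=2.0)
        assert W.shape == (5, 1)
        assert np.allclose(W, 1.0)

    def test_weights_sum_to_one(self):
        tree = Phylogeny.from_newick(SIX_TIP)
        cfg = ShiftConfiguration((Shift("A|B", 0.3, 2.0), Shift("C", 0.5, -1.0)))
        for alpha in [1e-8, 0.5, 3.0, 50.0]:
            W = regime_weights(tree, cfg, alpha)
            assert np.allclose(W.sum(axis=1), 1.0, atol=1e-10)

    def test_alpha_zero_limit_is_root_regime(self):
        tree = Phylogeny.from_newick(SIX_TIP)
        cfg = ShiftConfiguration((Shift("A|B", 0.3, 2.0),))
        W = regime_weights(tree, cfg, alpha=1e-10)
        assert np.allclose(W[:, 0], 1.0, atol=1e-8)

    def test_large_alpha_terminal_shift_dominates(self):
        tree = Phylogeny.from_newick(SIX_TIP)
        cfg = ShiftConfiguration((Shift("A", 0.0, 2.0),))
        W = regime_weights(tree, cfg, alpha=500.0)
        a = tree.tip_labels.index("A")
        assert W[a, 1] == pytest.approx(1.0, abs=1e-8)

    def test_unknown_branch_rejected(self):
        tree = Phylogeny.from_newick(SIX_TIP)
        with pytest.raises(KeyError):
            regime_weights(tree, ShiftConfiguration((Shift("Z", 0.1, 1.0),)), 1.0)


class TestOuLoglik:
    def test_bm_limit(self):
        tree = Phylogeny.from_newick(SIX_TIP)
        rng = np.random.default_rng(0)
        y = rng.normal(size=6)
        mass = rng.normal(size=6)
        state = OUState(alpha=1e-8, sigma2=1.3, beta=0.4, theta0=0.2)
        ll_ou = ou_loglik(state, y, mass, tree)
        ll_bm = multivariate_normal.logpdf(
            y, mean=0.2 + 0.4 * mass, cov=1.3 * tree.vcv().matrix
        )
        assert ll_ou == pytest.approx(ll_bm, rel=1e-3, abs=1e-4)

    def test_matches_euler_simulation_oracle(self):
        """Mean and covariance implied by the likelihood match an independent
        stochastic simulation of the process (two optimum shifts)."""
        tree = Phylogeny.from_newick(SIX_TIP)
        state = OUState(
            alpha=2.0, sigma2=1.5, beta=0.0, theta0=0.0,
            shifts=ShiftConfiguration((Shift("A|B", 0.2, 2.0), Shift("E", 0.5, -1.5))),
        )
        emp_mean, emp_cov = euler_oracle_moments(tree, state, n_rep=20_000, seed=1)
        W = regime_weights(tree, state.shifts, state.alpha)
        ana_mean = W @ state.thetas()
        from cladescan.ou_shifts import _ou_cov_factor

        ana_cov = state.sigma2 * _ou_cov_factor(
            tree.vcv().matrix, tree.tip_depths(), state.alpha
        )
        # Monte-Carlo error ~ sd/sqrt(20000) ~ 0.006 on means
        assert np.allclose(emp_mean, ana_mean, atol=0.03)
        assert np.allclose(emp_cov, ana_cov, atol=0.03)

    def test_dense_mvn_consistency(self):
        tree = Phylogeny.from_newick(SIX_TIP)
        rng = np.random.default_rng(2)
        y = rng.normal(size=6)
        mass = rng.normal(size=6)
        state = OUState(
            alpha=1.7, sigma2=0.9, beta=0.3, theta0=-0.1,
            shifts=ShiftConfiguration((Shift("C|D", 0.4, 1.0),)),
        )
        W = regime_weights(tree, state.shifts, state.alpha)
        from cladescan.ou_shifts import _ou_cov_factor

        mean = W @ state.thetas() + 0.3 * mass
        cov = 0.9 * _ou_cov_factor(tree.vcv().matrix, tree.tip_depths(), 1.7)
        expected = multivariate_normal.logpdf(y, mean=mean, cov=cov)
        assert ou_loglik(state, y, mass, tree) == pytest.approx(expected, abs=1e-8)


class TestDiagnostics:
    def test_identical_chains_r_near_one(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=2_000)
        assert gelman_r([c, c]) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_large_r(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 1.0, size=1_000)
        b = rng.normal(10.0, 1.0, size=1_000)
        r = gelman_r([a, b])
        # direct B/W computation
        W = (a.var(ddof=1) + b.var(ddof=1)) / 2
        Bn = np.var([a.mean(), b.mean()], ddof=1)
        assert r == pytest.approx(math.sqrt((999 / 1000) * W / W + Bn / W), rel=1e-12)
        assert r > 2

    def test_three_chains(self):
        rng = np.random.default_rng(5)
        chains = [rng.normal(size=500) for _ in range(3)]
        assert gelman_r(chains) == pytest.approx(1.0, abs=0.05)

    def test_constant_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_r([np.ones(100), np.ones(100)])

    def test_ess_white_noise(self):
        rng = np.random.default_rng(6)
        ess = effective_size(rng.normal(size=1_000))
        assert 800 <= ess <= 1_200

    def test_ess_ar1(self):
        # AR(1) phi=0.9: autocorrelation time = (1+phi)/(1-phi) = 19
        rng = np.random.default_rng(7)
        x = np.empty(5_000)
        x[0] = 0.0
        eps = rng.normal(size=5_000)
        for t in range(1, 5_000):
            x[t] = 0.9 * x[t - 1] + eps[t]
        ess = effective_size(x)
        assert ess < 5_000 / 5

    def test_ess_near_constant_bounded(self):
        x = np.ones(100)
        x += np.linspace(0, 1e-9, 100)
        ess = effective_size(x)
        assert 0 < ess <= 100


class TestSampler:
    def test_chain_bookkeeping(self):
        tree = Phylogeny.from_newick(SIX_TIP)
        rng = np.random.default_rng(8)
        y = rng.normal(size=6)
        cfg = OUConfig(steps=2_002, burn_in=2, thin=1, chains=2, seed=1)
        chains = fit_ou_rjmcmc(y, np.zeros(6), tree, config=cfg)
        assert len(chains) == 2
        assert all(len(c) == 2_000 for c in chains)

    def test_prior_recovery_constant_likelihood(self):
        """With the likelihood forced constant, sampled k follows the Poisson
        prior (detailed-balance smoke test for the reversible jump)."""
        tree = random_tree(15, seed=3)
        y = np.zeros(15)
        ks = []
        for seed in range(20):
            cfg = OUConfig(steps=20_000, burn_in=2_000, thin=100, chains=1,
                           seed=seed, likelihood="constant")
            ch = fit_ou_rjmcmc(y, y, tree, config=cfg)[0]
            ks.extend(s.shifts.k for s in ch.states)
        ks = np.array(ks)
        edges = [0, 1, 2, 3]
        obs = [np.sum(ks == e) for e in edges] + [np.sum(ks > 3)]
        pk = [poisson.pmf(e, 1.0) for e in edges] + [poisson.sf(3, 1.0)]
        stat, p = chisquare(obs, np.array(pk) / sum(pk) * len(ks))
        assert p > 0.01

    def test_planted_shift_recovered(self):
        """A large optimum shift on a long terminal branch is placed on the
        correct branch with posterior frequency > 0.5."""
        tree = random_tree(35, seed=21)
        target = max(tree.tip_labels, key=tree.terminal_branch_length)
        bid = tree.branch_ids()[tree.tip_node(target)]
        from cladescan.synthetic_data import simulate_bm

        mass = np.asarray(simulate_bm(tree, sigma2=4.0, root=3.0, seed=77))
        truth = OUState(alpha=10.0, sigma2=5.0, beta=1.0, theta0=0.0,
                        shifts=ShiftConfiguration((Shift(bid, 0.0, 4.0 * 2.5),)))
        hits = top_hits = 0
        for rep in range(3):
            y = np.asarray(simulate_ou(tree, truth, mass=mass, seed=500 + rep))
            cfg = OUConfig(steps=60_000, burn_in=6_000, thin=100, chains=1,
                           seed=900 + rep)
            ch = fit_ou_rjmcmc(y, mass, tree, config=cfg)[0]
            df = shift_frequencies(ch.states, tree)
            top_hits += df["proportion"].idxmax() == bid
            hits += df.loc[bid, "proportion"] > 0.5
        assert top_hits >= 2
        assert hits >= 2

    def test_zero_shift_posterior_k_near_prior(self):
        """Weak data: posterior mean k stays near the Poisson prior mean."""
        tree = random_tree(20, seed=9)
        truth = OUState(alpha=1.0, sigma2=2.0, beta=0.0, theta0=0.0)
        means = []
        for rep in range(4):
            y = np.asarray(simulate_ou(tree, truth, seed=40 + rep))
            cfg = OUConfig(steps=20_000, burn_in=2_000, thin=100, chains=1,
                           seed=50 + rep)
            ch = fit_ou_rjmcmc(y, np.zeros(20), tree, config=cfg)[0]
            means.append(np.mean([s.shifts.k for s in ch.states]))
        # prior mean 1; allow generous Monte-Carlo slack
        assert abs(np.mean(means) - 1.0) < 1.0

    def test_shift_count_matches_k(self):
        tree = random_tree(12, seed=10)
        rng = np.random.default_rng(11)
        y = rng.normal(size=12)
        cfg = OUConfig(steps=10_000, burn_in=1_000, thin=100, chains=1, seed=12)
        ch = fit_ou_rjmcmc(y, np.zeros(12), tree, config=cfg)[0]
        for s in ch.states:
            assert len(s.shifts.shifts) == s.shifts.k
        df = shift_frequencies(ch.states, tree)
        assert ((df["proportion"] >= 0) & (df["proportion"] <= 1)).all()


class TestSummaries:
    def test_hand_built_chain(self):
        tree = Phylogeny.from_newick(SIX_TIP)
        mk = lambda sh: OUState(1.0, 1.0, 0.0, 0.0, ShiftConfiguration(sh))
        states = [
            mk((Shift("A", 0.1, 0.3),)),
            mk((Shift("A", 0.2, 0.5),)),
            mk(()),
            mk(()),
            mk((Shift("E|F", 0.5, -1.0),)),
        ]
        s = summarize_shifts(states, tree, "A")
        assert s.proportion == pytest.approx(0.4)
        assert s.mean_shift == pytest.approx(0.4)
        assert s.sd_shift == pytest.approx(0.1 * math.sqrt(2))
        assert s.prop_positive == pytest.approx(1.0)
        assert s.rank == 1

    def test_never_shifted_branch(self):
        tree = Phylogeny.from_newick(SIX_TIP)
        states = [OUState(1.0, 1.0, 0.0, 0.0) for _ in range(5)]
        s = summarize_shifts(states, tree, "B")
        assert s.proportion == 0.0
        assert s.mean_shift is None and s.prop_positive is None

    def test_magnitude_relative_to_parent_regime(self):
        tree = Phylogeny.from_newick(SIX_TIP)
        # shift on A|B to 2.0, nested shift on A to 2.5: A's magnitude is 0.5
        st = OUState(1.0, 1.0, 0.0, 0.0, ShiftConfiguration(
            (Shift("A|B", 0.5, 2.0), Shift("A", 0.5, 2.5))
        ))
        df = shift_frequencies([st], tree)
        assert df.loc["A", "mean_shift"] == pytest.approx(0.5)
        assert df.loc["A|B", "mean_shift"] == pytest.approx(2.0)


class TestShiftDecision:
    @pytest.mark.parametrize(
        "prop,pp,shifted,direction",
        [
            (0.60, 1.00, True, "up"),      # strongly supported increase
            (0.27, 0.03, True, "down"),    # supported decrease
            (0.19, 1.00, False, "none"),   # below the 20% support floor
            (0.30, 0.80, False, "none"),   # directionally inconsistent
        ],
    )
    def test_decision_rule(self, prop, pp, shifted, direction):
        s = ShiftSummary("b", prop, 0.1 if shifted else 0.0, 0.05, pp, 1)
        out = shift_decision(s)
        assert out["shifted"] is shifted
        assert out["direction"] == direction


def test_combine_chains_truncates_toward_r_one():
    rng = np.random.default_rng(13)
    base = OUState(1.0, 1.0, 0.0, 0.0)
    # chain b starts far away and converges: truncation should improve R
    ll_a = rng.normal(0, 1, size=200)
    ll_b = np.concatenate([rng.normal(8, 1, size=40), rng.normal(0, 1, size=160)])
    from cladescan import OUChain

    cfg = OUConfig(steps=100, burn_in=0, thin=1, seed=0)
    mk = lambda lls: OUChain(states=[base] * len(lls), loglik=lls, config=cfg,
                             seed=0)
    states, diag = combine_chains([mk(ll_a), mk(ll_b)])
    assert diag.truncation >= 0.2
    assert diag.gelman_r < gelman_r([ll_a, ll_b])
    assert diag.n_combined == 2 * (200 - int(diag.truncation * 200))
    assert diag.ess <= diag.n_combined
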