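"""Synthetic trees and trait data with known ground truth.

Emulates the structure of the real study table: ~50 primate-like species,
one log10 body-mass covariate, per-trait missingness, trait values generated
by Brownian motion (optionally with a rate multiplier on one designated
branch) or by a multi-optimum OU process (optionally with a planted optimum
shift).  Also provides the false-positive / false-negative validation study:
constant-rate BM datasets versus datasets with a rate multiplier on the
target's terminal branch, each pushed through the phylogenetic-prediction
stage to measure how often the target is flagged as an outlier.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.linalg import cholesky

from . import ou_shifts
from .ou_shifts import OUState, _regime_weights_nodes, _ou_cov_factor
from .phylo_predict import MCMCConfig, fit_rjmcmc, outlier_probability
from .trait_data import MASS, TraitTable
from .treeio import Phylogeny, TreeSet

__all__ = [
    "SimulationSpec",
    "random_tree",
    "choose_target_tip",
    "simulate_bm",
    "simulate_ou",
    "make_study",
    "rate_multiplier_study",
]


@dataclass
class SimulationSpec:
    """Ground-truth description of one synthetic study table.

    Defaults mirror the real study's scale: 50 species, one mass covariate
    on log10 scale, BM traits with unit rate and zero root state.
    """

    n_species: int = 50
    n_traits: int = 1
    model: str = "BM"                  # "BM" or "OU"
    sigma2: float = 1.0
    root: float = 0.0
    beta: float = 0.0                  # mass -> trait regression slope
    mass_root: float = 3.0             # log10 grams, primate-scale
    mass_sigma2: float = 0.25
    missingness: float = 0.0
    multipliers: dict[str, float] = field(default_factory=dict)  # branch id -> rate factor
    ou_state: OUState | None = None
    tree: Phylogeny | None = None
    target: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missingness < 1.0):
            raise ValueError("missingness must lie in [0, 1)")
        if any(v <= 0 for v in self.multipliers.values()):
            raise ValueError("rate multipliers must be positive")
        if self.model not in {"BM", "OU"}:
            raise ValueError("model must be 'BM' or 'OU'")


def random_tree(
    n_tips: int,
    seed: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    scale_height: float | None = 1.0,
) -> Phylogeny:
    """A random birth-death tree, optionally rescaled to a given height."""
    pyrng = _pyrandom.Random(int(seed))
    dt = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_tips,
        rng=pyrng,
    )
    dt.seed_node.edge.length = None
    # the simulation stops exactly at the n-th speciation, leaving two
    # zero-length terminal branches (a singular covariance); extend every tip
    # by the waiting time to the next event so the tree is sampled at a
    # random time while n lineages are extant
    extra = pyrng.expovariate(n_tips * (birth_rate + death_rate))
    for leaf in dt.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    ph = Phylogeny(dt)
    if scale_height is not None:
        factor = scale_height / ph.height
        for e in dt.preorder_edge_iter():
            if e.length is not None:
                e.length *= factor
        ph = Phylogeny(dt)
    return ph


def choose_target_tip(tree: Phylogeny, height_frac: float = 0.1) -> str:
    """Tip whose terminal branch length is closest to ``height_frac`` of the
    tree height — emulating a focal lineage with a distinct terminal branch
    (as the human branch is within primates)."""
    want = height_frac * tree.height
    best, best_d = None, float("inf")
    for lab in tree.tip_labels:
        d = abs(tree.terminal_branch_length(lab) - want)
        if d < best_d:
            best, best_d = lab, d
    return best  # type: ignore[return-value]


def _branch_mult_vector(tree: Phylogeny, multipliers: Mapping[str, float]) -> np.ndarray:
    mult = np.ones(tree.n_nodes)
    if multipliers:
        bindex = tree.branch_index()
        tipmap = {lab: tree.tip_node(lab) for lab in tree.tip_labels}
        for bid, f in multipliers.items():
            if bid in bindex:
                mult[bindex[bid]] = f
            elif bid in tipmap:  # convenience: tip label = its terminal branch
                mult[tipmap[bid]] = f
            else:
                raise KeyError(f"multiplier references unknown branch: {bid!r}")
    return mult


def _path_matrix(tree: Phylogeny) -> np.ndarray:
    """tips x nodes indicator of branch membership on the root-to-tip path."""
    A = np.zeros((tree.n_tips, tree.n_nodes))
    for i, tip in enumerate(tree.tip_indices):
        for nd in tree.path_to_root(int(tip)):
            A[i, nd] = 1.0
    return A


def simulate_bm(
    tree: Phylogeny,
    sigma2: float = 1.0,
    root: float = 0.0,
    multipliers: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    size: int | None = None,
) -> pd.DataFrame | pd.Series:
    """Brownian-motion tip values: independent normal increments per branch
    with variance ``sigma2 * length * multiplier``, summed along root paths.

    With ``size`` set, returns a DataFrame of ``size`` independent datasets
    (rows) over tips (columns); otherwise a Series over tips.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mult = _branch_mult_vector(tree, multipliers or {})
    sd = np.sqrt(sigma2 * tree.length * mult)
    nrep = 1 if size is None else size
    eps = rng.normal(size=(nrep, tree.n_nodes)) * sd
    tips = root + eps @ _path_matrix(tree).T
    df = pd.DataFrame(tips, columns=list(tree.tip_labels))
    if size is None:
        return df.iloc[0]
    return df


def simulate_ou(
    tree: Phylogeny,
    state: OUState,
    mass: np.ndarray | pd.Series | None = None,
    seed: int | np.random.Generator = 0,
    size: int | None = None,
) -> pd.DataFrame | pd.Series:
    """Exact draw(s) from the multivariate normal implied by the OU model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mass is None:
        mass = np.zeros(tree.n_tips)
    mass = np.asarray(pd.Series(mass).reindex(tree.tip_labels) if isinstance(mass, pd.Series)
                      else mass, dtype=float)
    W = ou_shifts.regime_weights(tree, state.shifts, state.alpha)
    mu = W @ state.thetas() + state.beta * mass
    K = _ou_cov_factor(tree.vcv().matrix, tree.tip_depths(), state.alpha)
    L = cholesky(state.sigma2 * K, lower=True)
    nrep = 1 if size is None else size
    tips = mu + rng.normal(size=(nrep, tree.n_tips)) @ L.T
    df = pd.DataFrame(tips, columns=list(tree.tip_labels))
    if size is None:
        return df.iloc[0]
    return df


def make_study(spec: SimulationSpec) -> tuple[TraitTable, dict]:
    """A complete synthetic study table plus its ground-truth record."""
    root_seq = np.random.SeedSequence(spec.seed)
    s_tree, s_mass, s_trait, s_miss = root_seq.spawn(4)
    tree = spec.tree or random_tree(spec.n_species, seed=int(s_tree.generate_state(1)[0] % 2**31))
    target = spec.target or choose_target_tip(tree)

    mass = simulate_bm(tree, sigma2=spec.mass_sigma2, root=spec.mass_root,
                       seed=np.random.default_rng(s_mass))
    rng_t = np.random.default_rng(s_trait)
    rng_m = np.random.default_rng(s_miss)
    data = pd.DataFrame({MASS: mass})
    mask: dict[str, list[str]] = {}
    for j in range(spec.n_traits):
        name = f"trait_{j + 1}"
        if spec.model == "BM":
            noise = simulate_bm(tree, sigma2=spec.sigma2, root=spec.root,
                                multipliers=spec.multipliers, seed=rng_t)
            vals = noise + spec.beta * mass
        else:
            if spec.ou_state is None:
                raise ValueError("OU model requires spec.ou_state")
            vals = simulate_ou(tree, spec.ou_state, mass=mass, seed=rng_t)
        miss = rng_m.random(tree.n_tips) < spec.missingness
        # never blank the target row or mass
        miss[list(tree.tip_labels).index(target)] = False
        vals = vals.copy()
        vals[miss] = np.nan
        mask[name] = [lab for lab, m in zip(tree.tip_labels, miss) if m]
        data[name] = vals
    data = data.sort_index()
    table = TraitTable(data, target=target,
                       audit={"synthetic": True, "seed": spec.seed})
    truth = {
        "spec": spec,
        "tree": tree,
        "target": target,
        "beta": spec.beta,
        "sigma2": spec.sigma2,
        "root": spec.root,
        "multipliers": dict(spec.multipliers),
        "ou_state": spec.ou_state,
        "missing": mask,
    }
    return table, truth


def rate_multiplier_study(
    tree: Phylogeny,
    target: str,
    n_null: int = 100,
    n_alt: int = 150,
    rate_range: tuple[float, float] = (1.0, 4.0),
    predictor_config: MCMCConfig | None = None,
    seed: int = 0,
    sigma2: float = 1.0,
    beta: float = 0.0,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """The false-positive / false-negative validation study.

    ``n_null`` datasets evolve under constant-rate BM; ``n_alt`` datasets
    draw a rate multiplier uniformly from ``rate_range`` and apply it to the
    variance of the target's terminal branch.  Every dataset is pushed
    through the prediction stage and the target is scored as an outlier when
    its simulated value falls outside the central ``1 - alpha_level``
    predictive interval.  Returns one row per dataset: arm, rate, two-sided
    probability, outlier flag.
    """
    cfg = predictor_config or MCMCConfig(steps=20_100, burn_in=100, thin=100, seed=0)
    root_seq = np.random.SeedSequence(seed)
    s_mass, s_arms = root_seq.spawn(2)
    mass = simulate_bm(tree, sigma2=0.25, root=3.0, seed=np.random.default_rng(s_mass))
    trees = TreeSet([tree], provenance="simulation")
    target_branch = tree.branch_ids()[tree.tip_node(target)]

    rows = []
    ds_seeds = s_arms.spawn(n_null + n_alt)
    for i in range(n_null + n_alt):
        rng = np.random.default_rng(ds_seeds[i])
        if i < n_null:
            arm, rate = "null", 1.0
        else:
            arm = "alt"
            rate = float(rng.uniform(*rate_range))
        mult = {} if rate == 1.0 else {target_branch: rate}
        trait = simulate_bm(tree, sigma2=sigma2, root=0.0, multipliers=mult, seed=rng)
        trait = trait + beta * mass
        table = TraitTable(
            pd.DataFrame({MASS: mass, "trait": trait}).sort_index(), target=target
        )
        cfg_i = MCMCConfig(**{**cfg.__dict__, "seed": int(rng.integers(2**31))})
        chain = fit_rjmcmc(table, trees, "trait", target, cfg_i)
        p = outlier_probability(chain.draws, chain.observed)
        rows.append({"arm": arm, "rate": rate, "probability": p,
                     "outlier": p < alpha_level})
    return pd.DataFrame(rows)


def detection_curve(study: pd.DataFrame, bins: np.ndarray | None = None) -> pd.DataFrame:
    """Detection proportion per rate bin from a rate_multiplier_study table."""
    alt = study[study["arm"] == "alt"]
    if bins is None:
        bins = np.linspace(1.0, 4.0, 7)
    grp = alt.groupby(pd.cut(alt["rate"], bins), observed=True)["outlier"]
    return pd.DataFrame({"n": grp.size(), "detected": grp.mean()})
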