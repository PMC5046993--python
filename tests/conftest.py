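import numpy as np
import pandas as pd
import pytest

from cladescan import Phylogeny, TraitTable, TreeSet
from cladescan.synthetic_data import random_tree, simulate_bm


@pytest.fixture
def three_taxon_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_taxon_tree():
    return Phylogeny.from_newick("(((A:0.4,B:0.4):0.3,C:0.7):0.3,(D:0.6,E:0.6):0.4);")


@pytest.fixture(scope="session")
def study_tree():
    """A 50-tip primate-scale tree used by the heavier recovery studies."""
    return random_tree(50, seed=42)


def make_table(tree, *, beta=0.0, sigma2=1.0, seed=0, target=None, trait="trait"):
    """A single-trait table simulated under BM + mass effect on ``tree``."""
    rng = np.random.default_rng(seed)
    mass = simulate_bm(tree, sigma2=0.25, root=3.0, seed=rng)
    y = simulate_bm(tree, sigma2=sigma2, root=0.0, seed=rng) + beta * mass
    df = pd.DataFrame({"mass": mass, trait: y}).sort_index()
    return TraitTable(df, target=target)


@pytest.fixture
def tiny_records():
    """Raw records exercising every filter of the table builder."""
    rows = []
    # trait 'a': 12 qualifying female species
    for i in range(12):
        rows.append((f"sp{i:02d}", "a", "female", 10.0 + i, 15))
        rows.append((f"sp{i:02d}", "mass", "female", 1000.0 + 10 * i, 20))
    # trait 'b': only 9 species pass the animal filter (one cell at n=9)
    for i in range(9):
        rows.append((f"sp{i:02d}", "b", "female", 5.0 + i, 12))
    rows.append(("sp09", "b", "female", 20.0, 9))
    # male and unlabeled rows that strict mode must drop
    rows.append(("sp00", "a", "male", 99.0, 50))
    rows.append(("sp01", "a", "", 99.0, 50))
    return pd.DataFrame(rows, columns=["species", "trait", "sex", "value", "n"])
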