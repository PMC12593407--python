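import numpy as np
import pytest

from atlkit.ensemble import LEAF, Ensemble, ForestMember, Tree
from atlkit.fixtures import example_catalog, small_catalog
from atlkit.reagent_space import (
    Additive,
    Ligand,
    ReagentCatalog,
    Solvent,
    Substrate,
    build_schema,
)


@pytest.fixture(scope="session")
def fixture_catalog():
    """Packaged catalog with the (5, 29, 14, 9) class sizes."""
    return example_catalog()


@pytest.fixture(scope="session")
def bench_catalog():
    """Reduced catalog used by simulation benchmarks."""
    return small_catalog()


@pytest.fixture
def toy_catalog():
    """Hand-sized catalog: 5 precatalysts, 2 ligands (2-dim), 7 additives
    spanning 4 cations / 5 anions, 3 solvents (3-dim), substrates 1-dim."""
    return ReagentCatalog(
        precatalysts=["P1", "P2", "P3", "P4", "P5"],
        ligands=[Ligand("L1", (0.1, 0.2)), Ligand("L2", (0.9, -0.5))],
        additives=[
            Additive("none", None, None),
            Additive("MgCl2", "Mg", "Cl"),
            Additive("MgBr2", "Mg", "Br"),
            Additive("NaI", "Na", "I"),
            Additive("LiF", "Li", "F"),
            Additive("KOTf", "K", "OTf"),
            Additive("NaBr", "Na", "Br"),
        ],
        solvents=[
            Solvent("S1", (1.0, 0.0, 2.0)),
            Solvent("S2", (0.5, 1.5, -1.0)),
            Solvent("S3", (-0.3, 0.7, 0.2)),
        ],
        substrates=[
            Substrate("Am1", "amine", (0.4,)),
            Substrate("Ac1", "acid", (-1.2,)),
        ],
    )


@pytest.fixture
def toy_schema(toy_catalog):
    return build_schema(toy_catalog, ("Am1", "Ac1"))


def stump(feature: int, threshold: float, p_left: float, p_right: float) -> Tree:
    """Depth-one tree: x[feature] <= threshold -> p_left else p_right."""
    return Tree(
        feature=(feature, LEAF, LEAF),
        threshold=(threshold, 0.0, 0.0),
        left=(1, -1, -1),
        right=(2, -1, -1),
        prob_pos=(0.0, p_left, p_right),
    )


def leaf_tree(p: float) -> Tree:
    return Tree(feature=(LEAF,), threshold=(0.0,), left=(-1,), right=(-1,), prob_pos=(p,))


def make_ensemble(trees_per_member, n_features, generation=0):
    """Build an ensemble from a list of tree-lists."""
    members = [
        ForestMember(generation=generation, seed=i, trees=tuple(ts))
        for i, ts in enumerate(trees_per_member)
    ]
    return Ensemble(members=members, n_features=n_features)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
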