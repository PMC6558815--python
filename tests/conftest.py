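import numpy as np
import pytest

from paleotrait.contmodels import ContModelSpec, ContParams
from paleotrait.synth import SynthConfig, simulate_tree, simulate_trait_table
from paleotrait.treekit import DatedTree, rescale_unit_height


@pytest.fixture
def three_tip_tree() -> DatedTree:
    return DatedTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def cherry_tree() -> DatedTree:
    return DatedTree.from_newick("(A:1,B:1);")


@pytest.fixture
def balanced4_tree() -> DatedTree:
    return DatedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def bd_tree_128():
    """Unit-height pure-birth tree with 128 extant tips."""
    cfg = SynthConfig(n_extant=128, death_rate=0.0, seed=202,
                      trait_model=ContModelSpec("BM"),
                      trait_params=ContParams(theta0=0.0, sigma2=1.0))
    tree, _, _ = simulate_tree(cfg)
    return rescale_unit_height(tree)


@pytest.fixture(scope="session")
def fossil_tree_100():
    """Unit-height birth-death tree, ~100 extant plus sampled fossils."""
    cfg = SynthConfig(n_extant=100, death_rate=0.4, fossil_keep_prob=0.4, seed=5,
                      trait_model=ContModelSpec("BM"),
                      trait_params=ContParams(theta0=0.0, sigma2=1.0))
    tree, ranges, _ = simulate_tree(cfg)
    return rescale_unit_height(tree), ranges


@pytest.fixture(scope="session")
def study_scale_fixture():
    """EB-generated dataset shaped like the empirical one (~440+60 tips)."""
    cfg = SynthConfig(
        n_extant=440, death_rate=0.5, fossil_keep_prob=0.12, strat_window=0.4,
        trait_model=ContModelSpec("EB"),
        trait_params=ContParams(theta0=8.0, sigma2=60.0, beta=-5.0),
        range_noise=0.2, seed=21,
    )
    tree, ranges, _ = simulate_tree(cfg)
    tree = rescale_unit_height(tree)
    records, truth = simulate_trait_table(tree, cfg, ranges)
    return tree, records, truth


def labels_of(tree: DatedTree) -> tuple[str, ...]:
    return tuple(tree.tip_labels)


def trait_vector(tree: DatedTree, values) -> "object":
    from paleotrait.traitio import TraitVector

    return TraitVector(values=np.asarray(values, dtype=float), variant="mean",
                       labels=tuple(tree.tip_labels))
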