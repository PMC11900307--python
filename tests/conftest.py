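import numpy as np
import pytest

from herbnet.catalog import HerbCatalog, SeedSet
from herbnet.msnet import MultiscaleNetwork
from herbnet.synthetic import SyntheticConfig, generate_network


@pytest.fixture
def two_node_network() -> MultiscaleNetwork:
    """P1 -- P2, no functions: the hand-solvable walk."""
    net = MultiscaleNetwork()
    net.add_pp_edge("P1", "P2")
    return net


@pytest.fixture
def path_network() -> MultiscaleNetwork:
    """P1-P2-P3 chain, F1 annotating P1, F2 the parent of F1."""
    net = MultiscaleNetwork()
    net.add_pp_edge("P1", "P2")
    net.add_pp_edge("P2", "P3")
    net.add_pf_edge("P1", "F1")
    net.add_ff_edge("F1", "F2")
    return net


@pytest.fixture
def small_catalog() -> HerbCatalog:
    return HerbCatalog(
        compounds_of={
            "HerbA": {"C1", "C2", "C3"},
            "HerbB": {"C1", "C4"},
            "HerbC": {"C5", "C6", "C7"},
        },
        targets_of={
            "C1": {"P1", "P2"},
            "C2": {"P1"},
            "C3": {"P3"},
            "C4": {"P2"},
            "C5": {"P3"},
            # C6, C7 untargeted
        },
    )


def random_small_network(seed: int) -> MultiscaleNetwork:
    """A <=30-node three-layer network for oracle comparisons."""
    cfg = SyntheticConfig(
        seed=seed, n_proteins=18, n_functions=8, hierarchy_depth=2,
        annotations_per_protein=0.8, disease_module_size=4, n_herbs=2,
    )
    return generate_network(cfg)


def random_seed_set(
    network: MultiscaleNetwork, seed: int, size: int = 3, entity: str | None = None
) -> SeedSet:
    rng = np.random.default_rng(seed)
    genes = rng.choice(sorted(network.proteins), size=size, replace=False)
    return SeedSet(entity or f"seed{seed}", tuple(sorted(str(g) for g in genes)))
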