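import numpy as np
import pytest

from herbnet.catalog import SeedSet
from herbnet.diffusion import (
    ConvergenceError,
    DiffusionProfile,
    RWRParams,
    WalkerTrappedError,
    batch_profiles,
    diffusion_profile,
    mc_profile,
    transition_distribution,
    transition_matrix,
)
from herbnet.msnet import MultiscaleNetwork

from conftest import random_seed_set, random_small_network


def fixed_point_residual(network, profile, seeds):
    """L1 residual of p against r*s + (1-r)*(T'p + dangling*s)."""
    params = profile.params
    T, dangling = transition_matrix(network, params)
    index = network.node_index
    s = np.zeros(len(index))
    for g, w in seeds.weight_map().items():
        s[index[g]] = w
    p = profile.values
    dm = p[dangling].sum() if dangling.any() else 0.0
    rhs = params.restart_prob * s + (1 - params.restart_prob) * (T.T @ p + dm * s)
    return np.abs(p - rhs).sum()


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"restart_prob": 0.0},
            {"restart_prob": 1.5},
            {"w_pp": -1.0},
            {"w_pp": 0, "w_pf": 0, "w_fp": 0, "w_f_up": 0, "w_f_down": 0},
            {"tol": 0.0},
            {"max_iter": 0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            RWRParams(**kwargs)


class TestTransitionDistribution:
    def test_uniform_weights(self, path_network):
        # P1 has protein neighbor P2 and function neighbor F1
        dist = transition_distribution(path_network, "P1", RWRParams())
        assert dist == pytest.approx({"P2": 0.5, "F1": 0.5})

    def test_biased_weights(self):
        net = MultiscaleNetwork()
        net.add_pp_edge("P1", "P2")
        net.add_pp_edge("P1", "P3")
        net.add_pf_edge("P1", "F1")
        dist = transition_distribution(net, "P1", RWRParams(w_pf=2.0))
        assert dist == pytest.approx({"F1": 0.5, "P2": 0.25, "P3": 0.25})

    def test_isolated_node_empty_map(self):
        net = MultiscaleNetwork(proteins={"P1"})
        assert transition_distribution(net, "P1", RWRParams()) == {}

    def test_all_zero_weights_trap(self, path_network):
        params = RWRParams(w_pp=0.0, w_pf=0.0, w_f_up=1.0)
        with pytest.raises(WalkerTrappedError):
            transition_distribution(path_network, "P1", params)


class TestDiffusionProfile:
    def test_restart_only_limit_equals_seed(self, path_network):
        seeds = SeedSet("s", ("P1", "P2"))
        prof = diffusion_profile(path_network, seeds, RWRParams(restart_prob=1.0))
        assert prof["P1"] == pytest.approx(0.5)
        assert prof["P2"] == pytest.approx(0.5)
        assert prof["P3"] == 0.0

    def test_two_node_analytic_fixed_point(self, two_node_network):
        # hand-solved: p1 = 0.5 + 0.5 p2, p2 = 0.5 p1 -> (2/3, 1/3)
        prof = diffusion_profile(
            two_node_network, SeedSet("s", ("P1",)),
            RWRParams(restart_prob=0.5, tol=1e-12),
        )
        assert prof["P1"] == pytest.approx(2 / 3, abs=1e-9)
        assert prof["P2"] == pytest.approx(1 / 3, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_profile_is_distribution(self, seed):
        net = random_small_network(seed)
        prof = diffusion_profile(net, random_seed_set(net, seed))
        assert prof.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert (prof.values >= 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_fixed_point_residual(self, seed):
        net = random_small_network(seed)
        seeds = random_seed_set(net, seed)
        prof = diffusion_profile(net, seeds)
        assert fixed_point_residual(net, prof, seeds) < 10 * prof.params.tol

    def test_seed_mass_nondecreasing_in_restart_prob(self, path_network):
        seeds = SeedSet("s", ("P2",))
        masses = []
        for r in (0.5, 0.9, 0.99):
            prof = diffusion_profile(path_network, seeds, RWRParams(restart_prob=r))
            masses.append(prof["P2"])
        assert masses == sorted(masses)
        assert masses[-1] > 0.9

    def test_dangling_mass_restarts(self):
        net = MultiscaleNetwork(proteins={"P1", "P2", "Px"}, pp_edges={("P1", "P2")})
        prof = diffusion_profile(net, SeedSet("s", ("Px",)))
        # the walker leaves Px only by restart, so all mass stays there
        assert prof["Px"] == pytest.approx(1.0, abs=1e-6)

    def test_nonconvergence_error(self, path_network):
        params = RWRParams(restart_prob=0.01, tol=1e-15, max_iter=2)
        with pytest.raises(ConvergenceError):
            diffusion_profile(path_network, SeedSet("s", ("P1",)), params)

    def test_permutation_equivariance(self):
        net = random_small_network(5)
        seeds = random_seed_set(net, 5)
        prof = diffusion_profile(net, seeds)
        relabel = {n: f"Z{n}" for n in net.nodes}
        net2 = MultiscaleNetwork(
            proteins={relabel[p] for p in net.proteins},
            functions={relabel[f] for f in net.functions},
            pp_edges={tuple(sorted((relabel[u], relabel[v]))) for u, v in net.pp_edges},
            pf_edges={(relabel[p], relabel[f]) for p, f in net.pf_edges},
            ff_edges={(relabel[c], relabel[p]) for c, p in net.ff_edges},
        )
        seeds2 = SeedSet("seed", tuple(sorted(relabel[g] for g in seeds.genes)))
        prof2 = diffusion_profile(net2, seeds2)
        for n in net.nodes:
            assert prof2[relabel[n]] == pytest.approx(prof[n], abs=1e-9)

    def test_seed_weights_respected(self, two_node_network):
        seeds = SeedSet("s", ("P1", "P2"), weights=np.array([1.0, 0.0]))
        prof = diffusion_profile(two_node_network, seeds, RWRParams(restart_prob=1.0))
        assert prof["P1"] == pytest.approx(1.0)


class TestMonteCarloOracle:
    def test_deterministic_given_seed(self, two_node_network):
        seeds = SeedSet("s", ("P1",))
        a = mc_profile(two_node_network, seeds, n_steps=2000, rng_seed=42)
        b = mc_profile(two_node_network, seeds, n_steps=2000, rng_seed=42)
        assert np.array_equal(a.values, b.values)

    def test_restart_only_visits_only_seeds(self, path_network):
        seeds = SeedSet("s", ("P1", "P3"))
        prof = mc_profile(path_network, seeds, RWRParams(restart_prob=1.0),
                          n_steps=5000, rng_seed=0)
        support = {n for n, v in prof.as_dict().items() if v > 0}
        assert support == {"P1", "P3"}

    def test_agrees_with_power_iteration_two_node(self, two_node_network):
        seeds = SeedSet("s", ("P1",))
        mc = mc_profile(two_node_network, seeds, n_steps=1_000_000, rng_seed=7)
        assert abs(mc["P1"] - 2 / 3) + abs(mc["P2"] - 1 / 3) < 0.01

    @pytest.mark.parametrize("seed", [0, 1])
    def test_agrees_on_random_network(self, seed):
        net = random_small_network(seed)
        seeds = random_seed_set(net, seed)
        p = diffusion_profile(net, seeds)
        m = mc_profile(net, seeds, n_steps=200_000, rng_seed=seed)
        assert np.abs(p.values - m.values).sum() <= 0.02


class TestBatchAndSerialization:
    def test_batch_matches_individual(self, path_network):
        seed_sets = [SeedSet("a", ("P1",)), SeedSet("b", ("P2", "P3"))]
        batch = batch_profiles(path_network, seed_sets)
        singles = [diffusion_profile(path_network, s) for s in seed_sets]
        assert [b.entity for b in batch] == ["a", "b"]
        for b, s in zip(batch, singles):
            assert np.allclose(b.values, s.values)

    def test_tsv_round_trip_exact(self, tmp_path, path_network):
        prof = diffusion_profile(path_network, SeedSet("s", ("P1",)))
        path = tmp_path / "profile.tsv"
        prof.to_tsv(path)
        back = DiffusionProfile.from_tsv(path, entity="s")
        assert back.nodes == prof.nodes
        assert np.array_equal(back.values, prof.values)
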