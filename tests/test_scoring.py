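import math
from itertools import combinations

import numpy as np
import pytest

from herbnet.catalog import DiseaseGeneSet, HerbCatalog
from herbnet.diffusion import DiffusionProfile, RWRParams
from herbnet.scoring import (
    correlation_score,
    fold_enrichment,
    hypergeom_upper,
    prioritize,
    prioritize_compounds,
)
from herbnet.synthetic import (
    SyntheticConfig,
    generate_catalog,
    generate_network,
    plant_disease,
)


def profile(values, entity="x"):
    nodes = tuple(f"N{i}" for i in range(len(values)))
    return DiffusionProfile(entity=entity, nodes=nodes, values=np.array(values),
                            params=RWRParams())


def enumerate_upper_tail(k, n, K, N):
    """Oracle: enumerate all C(N, n) draws and count overlaps >= k."""
    marked = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked & set(draw)) >= k:
            hits += 1
    return hits / total


class TestCorrelationScore:
    def test_self_correlation_is_one(self):
        p = profile([0.5, 0.3, 0.2])
        assert correlation_score(p, p) == pytest.approx(1.0)

    def test_two_point_anticorrelation(self):
        assert correlation_score(profile([0.2, 0.8]), profile([0.8, 0.2])) == pytest.approx(-1.0)

    def test_hand_evaluated_pearson(self):
        # Pearson of (0.5,0.3,0.2) vs (0.2,0.3,0.5) = -39/42
        r = correlation_score(profile([0.5, 0.3, 0.2]), profile([0.2, 0.3, 0.5]))
        assert r == pytest.approx(-39 / 42)

    def test_spearman_monotone(self):
        r = correlation_score(profile([0.5, 0.3, 0.2]), profile([0.6, 0.25, 0.15]),
                              method="spearman")
        assert r == pytest.approx(1.0)

    def test_degenerate_profile_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            correlation_score(profile([0.5, 0.5]), profile([0.2, 0.8]))

    def test_mismatched_index_rejected(self):
        a = profile([0.5, 0.5, 0.0])
        with pytest.raises(ValueError):
            correlation_score(a, profile([0.2, 0.8]))


class TestHypergeomUpper:
    def test_zero_overlap_certain(self):
        assert hypergeom_upper(0, 5, 3, 10) == 1.0

    def test_enumerated_45_draws(self):
        # N=10, K=5, n=2, k=2: C(5,2)/C(10,2) = 10/45
        assert hypergeom_upper(2, 2, 5, 10) == pytest.approx(10 / 45)

    def test_enumerated_20_draws(self):
        # N=6, K=3, n=3, k=3: 1/C(6,3) = 1/20
        assert hypergeom_upper(3, 3, 3, 6) == pytest.approx(0.05)

    def test_inconsistent_counts_rejected(self):
        for bad in [(3, 2, 5, 10), (1, 2, 5, 4), (-1, 2, 5, 10)]:
            with pytest.raises(ValueError):
                hypergeom_upper(*bad)

    @pytest.mark.parametrize("N", [5, 8, 9])
    def test_matches_exhaustive_enumeration(self, N):
        for K in range(N + 1):
            for n in range(1, N + 1):
                for k in range(min(n, K) + 1):
                    assert hypergeom_upper(k, n, K, N) == pytest.approx(
                        enumerate_upper_tail(k, n, K, N), abs=1e-12
                    )

    def test_monotone_nonincreasing_in_k(self):
        ps = [hypergeom_upper(k, 10, 20, 100) for k in range(11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestFoldEnrichment:
    def test_no_enrichment_is_one(self):
        assert fold_enrichment(1, 2, 5, 10) == pytest.approx(1.0)

    def test_arithmetic(self):
        assert fold_enrichment(2, 2, 5, 10) == pytest.approx(2.0)
        assert fold_enrichment(0, 5, 5, 10) == 0.0

    @pytest.mark.parametrize("k,n,K,N", [(3, 7, 11, 40), (0, 4, 9, 30), (5, 5, 5, 50)])
    def test_algebraic_identity(self, k, n, K, N):
        assert fold_enrichment(k, n, K, N) * (K / N) * n == pytest.approx(k, abs=1e-12)

    def test_positive_denominators_required(self):
        with pytest.raises(ValueError):
            fold_enrichment(0, 0, 5, 10)


@pytest.fixture(scope="module")
def benchmark():
    cfg = SyntheticConfig(seed=11)
    net = generate_network(cfg)
    disease = plant_disease(net, cfg)
    catalog, planted = generate_catalog(net, disease, cfg)
    return net, disease, catalog, planted


class TestPrioritize:
    def test_planted_herb_ranks_first(self, benchmark):
        net, disease, catalog, planted = benchmark
        records = prioritize(catalog, disease, net)
        assert records[0].entity == planted
        assert records[0].rank == 1

    def test_invariant_to_herb_input_order(self, benchmark):
        net, disease, catalog, _ = benchmark
        shuffled = HerbCatalog(
            compounds_of=dict(reversed(list(catalog.compounds_of.items()))),
            targets_of=catalog.targets_of,
        )
        a = prioritize(catalog, disease, net)
        b = prioritize(shuffled, disease, net)
        assert [(r.entity, r.correlation) for r in a] == [
            (r.entity, r.correlation) for r in b
        ]

    def test_single_herb_ranks_first(self, benchmark):
        net, disease, catalog, _ = benchmark
        herb = sorted(catalog.herbs)[3]
        solo = HerbCatalog(
            compounds_of={herb: catalog.compounds_of[herb]},
            targets_of=catalog.targets_of,
        )
        records = prioritize(solo, disease, net)
        assert len(records) == 1 and records[0].rank == 1

    def test_alpha_one_flags_everything_significant(self, benchmark):
        net, disease, catalog, _ = benchmark
        records = prioritize(catalog, disease, net, alpha=1.0)
        assert all(r.significant for r in records)

    def test_insignificant_records_kept(self, benchmark):
        net, disease, catalog, _ = benchmark
        records = prioritize(catalog, disease, net, alpha=1e-30)
        assert len(records) == len(catalog.herbs)
        assert not any(r.significant for r in records)

    def test_overlap_from_top_n_caps_denominator(self, benchmark):
        net, disease, catalog, _ = benchmark
        capped = prioritize(catalog, disease, net, overlap_from_top_n=5)
        assert all(r.overlap_n <= 5 for r in capped)


class TestPrioritizeCompounds:
    def test_returns_at_most_top_m(self, benchmark):
        net, disease, catalog, planted = benchmark
        records = prioritize_compounds(catalog, planted, disease, net, top_m=3)
        assert len(records) == 3
        assert records[0].correlation >= records[-1].correlation

    def test_fewer_compounds_than_m(self, benchmark):
        net, disease, catalog, planted = benchmark
        two = sorted(catalog.compounds_of[planted])[:2]
        cat2 = HerbCatalog(
            compounds_of={planted: set(two)}, targets_of=catalog.targets_of
        )
        assert len(prioritize_compounds(cat2, planted, disease, net, top_m=5)) == 2

    def test_untargeted_compound_skipped(self, benchmark):
        net, disease, catalog, planted = benchmark
        cat2 = HerbCatalog(
            compounds_of={planted: catalog.compounds_of[planted] | {"CXXX"}},
            targets_of=catalog.targets_of,
        )
        records = prioritize_compounds(cat2, planted, disease, net, top_m=10)
        assert "CXXX" not in {r.entity for r in records}

    def test_top_m_one_is_argmax(self, benchmark):
        net, disease, catalog, planted = benchmark
        all_recs = prioritize_compounds(catalog, planted, disease, net, top_m=99)
        top1 = prioritize_compounds(catalog, planted, disease, net, top_m=1)
        assert top1[0].entity == all_recs[0].entity

    def test_unknown_herb(self, benchmark):
        net, disease, catalog, _ = benchmark
        with pytest.raises(KeyError):
            prioritize_compounds(catalog, "nope", disease, net)
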