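"""Hypergeometric overlap tests, the metagene network, Rand index and clustering."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from rppamet import (
    DataError,
    GeneSetCollection,
    Metagene,
    Partition,
    build_network,
    correlation_partition,
    enrich,
    hypergeom_upper_p,
    rand_index,
)


def exact_upper_tail(Na, Nb, n, N):
    """P(X >= n) by exact integer arithmetic over all surviving terms."""
    total = Fraction(0)
    for i in range(n, min(Na, Nb) + 1):
        total += Fraction(comb(Na, i) * comb(N - Na, Nb - i), comb(N, Nb))
    return float(total)


def pairwise_rand_oracle(labels_a, labels_b):
    """Fraction of concordant unordered pairs, enumerated one by one."""
    n = len(labels_a)
    agree = total = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        agree += same_a == same_b
        total += 1
    return agree / total


class TestHypergeom:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper_p(5, 5, 0, 20) == 1.0

    def test_full_overlap_single_term(self):
        assert hypergeom_upper_p(5, 5, 5, 10) == pytest.approx(1 / comb(10, 5))

    def test_matches_exact_enumeration_over_small_configs(self, rng):
        for _ in range(200):
            N = int(rng.integers(1, 26))
            Na = int(rng.integers(0, N + 1))
            Nb = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, min(Na, Nb) + 1))
            assert hypergeom_upper_p(Na, Nb, n, N) == pytest.approx(
                exact_upper_tail(Na, Nb, n, N), rel=1e-10, abs=1e-300)

    def test_non_increasing_in_overlap(self):
        ps = [hypergeom_upper_p(10, 12, n, 40) for n in range(11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_p(5, 5, 6, 20)
        with pytest.raises(ValueError):
            hypergeom_upper_p(30, 5, 2, 20)


def _mg(name, genes):
    return Metagene(name, {g: 1 for g in genes})


UNIVERSE = [f"G{i:04d}" for i in range(1000)]


class TestBuildNetwork:
    def test_disjoint_metagenes_share_no_edge(self):
        net = build_network([_mg("A", UNIVERSE[:20]), _mg("B", UNIVERSE[20:40])],
                            universe=UNIVERSE)
        assert net.edges == []

    def test_identical_metagenes_are_linked(self):
        net = build_network([_mg("A", UNIVERSE[:20]), _mg("B", UNIVERSE[:20])],
                            universe=UNIVERSE)
        assert len(net.edges) == 1
        a, b, n_overlap, q = net.edges[0]
        assert n_overlap == 20 and q < 1e-20

    def test_min_overlap_rule_binds_despite_tiny_p(self):
        # 4 shared genes out of 4 vs 4: p is astronomically small, still no edge
        net = build_network([_mg("A", UNIVERSE[:4]), _mg("B", UNIVERSE[:4])],
                            universe=UNIVERSE, min_overlap=5)
        assert net.tests[0].p < 1e-10
        assert net.edges == []

    def test_edge_set_invariant_to_input_order(self, rng):
        mgs = [_mg(f"M{k}", rng.choice(UNIVERSE, 30, replace=False)) for k in range(5)]
        fwd = build_network(mgs, universe=UNIVERSE)
        rev = build_network(mgs[::-1], universe=UNIVERSE)
        assert fwd.edges == rev.edges

    def test_member_outside_universe_rejected(self):
        with pytest.raises(DataError, match="outside the universe"):
            build_network([_mg("A", ["NOT_A_GENE"] + UNIVERSE[:10])], universe=UNIVERSE)

    def test_graphml_and_sif_export(self, tmp_path):
        net = build_network([_mg("A", UNIVERSE[:20]), _mg("B", UNIVERSE[:20]),
                             _mg("C", UNIVERSE[500:520])], universe=UNIVERSE)
        net.to_graphml(tmp_path / "n.graphml")
        net.to_sif(tmp_path / "n.sif")
        sif = (tmp_path / "n.sif").read_text().strip().splitlines()
        assert "A\tintersects\tB" in sif
        assert "C" in sif  # isolated node still listed

    def test_components_cluster_labels(self):
        net = build_network([_mg("A", UNIVERSE[:20]), _mg("B", UNIVERSE[:20]),
                             _mg("C", UNIVERSE[500:520])], universe=UNIVERSE)
        labels = net.cluster()
        assert labels["A"] == labels["B"] != labels["C"]


class TestEnrich:
    def test_self_class_is_top_hit(self):
        mg = _mg("M", UNIVERSE[:15])
        coll = GeneSetCollection({
            "SELF": UNIVERSE[:15],
            "OTHER": UNIVERSE[100:130],
            "MIXED": UNIVERSE[10:40],
        })
        tests = enrich(mg, coll, UNIVERSE)
        assert tests[0].set_b_name == "SELF"
        assert tests[0].p == min(t.p for t in tests)

    def test_disjoint_class_p_is_one(self):
        mg = _mg("M", UNIVERSE[:15])
        tests = enrich(mg, GeneSetCollection({"FAR": UNIVERSE[500:540]}), UNIVERSE)
        assert tests[0].p == 1.0
        assert tests[0].n_overlap == 0

    def test_random_sets_rarely_enrich(self):
        hits = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            mg = _mg("M", r.choice(UNIVERSE, 30, replace=False))
            coll = GeneSetCollection({
                f"C{k}": list(r.choice(UNIVERSE, 25, replace=False))
                for k in range(50)
            })
            if any(t.q <= 0.05 for t in enrich(mg, coll, UNIVERSE)):
                hits += 1
        assert hits <= 4


class TestRandIndex:
    def test_identical_partitions(self):
        a = Partition(list("abcd"), [1, 1, 2, 2])
        assert rand_index(a, a) == 1.0

    def test_relabeling_invariance(self):
        items = list("abcdef")
        a = Partition(items, [1, 1, 2, 2, 3, 3])
        b = Partition(items, [3, 3, 1, 1, 2, 2])
        assert rand_index(a, b) == 1.0

    def test_hand_enumerated_example(self):
        items = ["1", "2", "3", "4"]
        a = Partition(items, [1, 1, 2, 2])
        b = Partition(items, [1, 2, 1, 2])
        assert rand_index(a, b) == pytest.approx(2 / 6)

    def test_symmetry_and_oracle_on_random_partitions(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 13))
            items = [f"i{k}" for k in range(n)]
            la = rng.integers(1, 4, n)
            lb = rng.integers(1, 4, n)
            a, b = Partition(items, la), Partition(items, lb)
            ri = rand_index(a, b)
            assert ri == pytest.approx(pairwise_rand_oracle(la, lb))
            assert ri == pytest.approx(rand_index(b, a))

    def test_item_order_does_not_matter(self, rng):
        items = [f"i{k}" for k in range(8)]
        la, lb = rng.integers(1, 3, 8), rng.integers(1, 3, 8)
        a = Partition(items, la)
        perm = rng.permutation(8)
        b = Partition([items[i] for i in perm], lb[perm])
        assert rand_index(a, b) == pytest.approx(
            pairwise_rand_oracle(la, lb))

    def test_mismatched_item_sets_rejected(self):
        with pytest.raises(DataError):
            rand_index(Partition(["a"], [1]), Partition(["b"], [1]))


class TestCorrelationPartition:
    def _blocks(self, rng, per_block=5, features=60):
        rows, index = [], []
        for b in range(3):
            driver = rng.standard_normal(features)
            for i in range(per_block):
                rows.append(driver + rng.normal(0, 0.2, features))
                index.append(f"B{b}_{i}")
        return pd.DataFrame(rows, index=index)

    def test_planted_blocks_recovered(self, rng):
        profiles = self._blocks(rng)
        part = correlation_partition(profiles, k=3)
        truth = Partition(list(profiles.index),
                          [int(i.split("_")[0][1]) + 1 for i in profiles.index])
        assert rand_index(part, truth) == 1.0

    def test_k_equals_n_is_singletons(self, rng):
        profiles = self._blocks(rng, per_block=2)
        part = correlation_partition(profiles, k=len(profiles))
        assert part.n_classes == len(profiles)
        assert rand_index(part, part) == 1.0

    def test_duplicated_entities_cluster_together(self, rng):
        base = rng.standard_normal((4, 30))
        profiles = pd.DataFrame(
            np.vstack([base, base[0] + rng.normal(0, 1e-6, 30)]),
            index=["a", "b", "c", "d", "a_copy"])
        part = correlation_partition(profiles, k=3)
        assert part.label_of("a") == part.label_of("a_copy")

    def test_zero_variance_entity_excluded_with_warning(self, rng, caplog):
        profiles = self._blocks(rng, per_block=2)
        profiles.loc["FLAT"] = 1.0
        with caplog.at_level("WARNING", logger="rppamet.network"):
            part = correlation_partition(profiles, k=3)
        assert "FLAT" not in part.item_ids
        assert any("zero-variance" in rec.message for rec in caplog.records)

    def test_too_few_entities_rejected(self, rng):
        with pytest.raises(DataError):
            correlation_partition(pd.DataFrame(rng.standard_normal((2, 10))), k=3)
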