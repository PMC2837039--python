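"""Interaction and pathway-sharing statistics with permutation nulls."""

import numpy as np
import pytest

from persistome import InteractionRecord, PathwayRecord, ValidationError
from persistome.networks import (
    count_class_interactions,
    interactions_per_protein,
    pathway_sharing_test,
    pathways_per_cluster,
    permutation_test_interactions,
)


def _edges(pairs):
    return [InteractionRecord.make(a, b) for a, b in pairs]


class TestCountClassInteractions:
    labels = {"a": "R", "b": "S", "c": "W"}

    def test_triangle_enumeration(self):
        counts = count_class_interactions(
            _edges([("a", "b"), ("b", "c"), ("c", "a")]), self.labels
        )
        assert counts[("R", "S")] == 1
        assert counts[("S", "W")] == 1
        assert counts[("R", "W")] == 1
        assert counts[("R", "R")] == 0

    def test_self_edge_toggle(self):
        edges = _edges([("a", "a"), ("a", "b")])
        without = count_class_interactions(edges, self.labels, include_self=False)
        with_self = count_class_interactions(edges, self.labels, include_self=True)
        assert without[("R", "R")] == 0
        assert with_self[("R", "R")] == 1

    def test_single_class_has_no_cross_counts(self):
        labels = {"a": "S", "b": "S", "c": "S"}
        counts = count_class_interactions(_edges([("a", "b"), ("b", "c")]), labels)
        assert counts == {("S", "S"): 2}

    def test_empty_label_map_is_error(self):
        with pytest.raises(ValidationError):
            count_class_interactions([], {})

    def test_counts_conserve_total_edges(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(30)]
        labels = {n: "RSW"[int(rng.integers(0, 3))] for n in nodes}
        pairs = set()
        while len(pairs) < 60:
            i, j = rng.integers(0, 30, size=2)
            if i != j:
                pairs.add(tuple(sorted((nodes[i], nodes[j]))))
        counts = count_class_interactions(_edges(sorted(pairs)), labels)
        assert sum(counts.values()) == 60


class TestPermutationTest:
    def test_identical_labels_give_invariant_null(self):
        labels = {f"n{i}": "S" for i in range(6)}
        edges = _edges([("n0", "n1"), ("n2", "n3"), ("n4", "n5")])
        res = permutation_test_interactions(edges, labels, n_perm=200, seed=0)
        assert res[("S", "S")].observed == 3
        assert res[("S", "S")].null_sd == 0.0
        assert res[("S", "S")].p_value == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        nodes = [f"n{i}" for i in range(40)]
        labels = {n: "RSW"[int(rng.integers(0, 3))] for n in nodes}
        pairs = {tuple(sorted(rng.choice(nodes, 2, replace=False)))
                 for _ in range(80)}
        edges = _edges(sorted(pairs))
        r1 = permutation_test_interactions(edges, labels, n_perm=500, seed=99)
        r2 = permutation_test_interactions(edges, labels, n_perm=500, seed=99)
        assert all(
            r1[k].p_value == r2[k].p_value and r1[k].null_mean == r2[k].null_mean
            for k in r1
        )

    def test_planted_excess_is_detected(self):
        """A 5x excess of within-S edges yields p < 0.01 for S-S."""
        rng = np.random.default_rng(5)
        nodes = {f"s{i}": "S" for i in range(30)}
        nodes.update({f"w{i}": "W" for i in range(30)})
        pairs = set()
        s_nodes = [n for n in nodes if n.startswith("s")]
        w_nodes = [n for n in nodes if n.startswith("w")]
        while len(pairs) < 100:
            pairs.add(tuple(sorted(rng.choice(s_nodes, 2, replace=False))))
        while len(pairs) < 140:
            a, b = rng.choice(s_nodes), rng.choice(w_nodes)
            pairs.add(tuple(sorted((a, b))))
        res = permutation_test_interactions(
            _edges(sorted(pairs)), nodes, n_perm=2000, seed=6
        )
        assert res[("S", "S")].p_value < 0.01

    def test_corrected_p_never_zero(self):
        labels = {f"n{i}": ("S" if i < 5 else "W") for i in range(10)}
        edges = _edges([(f"n{i}", f"n{j}") for i in range(5) for j in range(i)])
        res = permutation_test_interactions(edges, labels, n_perm=200, seed=1)
        for r in res.values():
            assert r.p_value_corrected > 0.0


class TestPartners:
    def test_star_graph_partner_counts(self):
        labels = {"hub": "W", "l1": "S", "l2": "S", "l3": "R", "l4": "R"}
        edges = _edges([("hub", leaf) for leaf in ("l1", "l2", "l3", "l4")])
        means = interactions_per_protein(edges, labels)
        assert means["W"] == 4.0
        assert means["S"] == 1.0 and means["R"] == 1.0

    def test_duplicate_edges_deduplicated(self):
        labels = {"a": "S", "b": "W"}
        edges = _edges([("a", "b"), ("b", "a"), ("a", "b")])
        means = interactions_per_protein(edges, labels)
        assert means == {"S": 1.0, "W": 1.0}

    def test_excluding_a_class_removes_its_nodes_and_edges(self):
        labels = {"hub": "W", "r1": "R", "s1": "S"}
        edges = _edges([("hub", "r1"), ("hub", "s1")])
        means = interactions_per_protein(edges, labels, exclude_class="R")
        assert "R" not in means
        assert means["W"] == 1.0  # the r1 partner no longer counts


class TestPathways:
    def test_sharing_pair_enumeration(self):
        memberships = [
            PathwayRecord("s1", "p1"), PathwayRecord("s2", "p1"),
            PathwayRecord("w1", "p2"),
        ]
        labels = {"s1": "S", "s2": "S", "w1": "W"}
        res = pathway_sharing_test(memberships, labels, n_perm=100, seed=0)
        assert res[("S", "S")].observed == 1
        assert all(r.observed == 0 for k, r in res.items() if k != ("S", "S"))

    def test_planted_within_class_sharing_detected(self):
        rng = np.random.default_rng(7)
        memberships, labels = [], {}
        for i in range(10):  # S clusters share pathways in groups of 4
            cid = f"s{i}"
            labels[cid] = "S"
            memberships.append(PathwayRecord(cid, f"p{i // 4}"))
        for i in range(12):  # W clusters spread over many pathways
            cid = f"w{i}"
            labels[cid] = "W"
            memberships.append(PathwayRecord(cid, f"q{int(rng.integers(0, 3))}"))
        res = pathway_sharing_test(memberships, labels, n_perm=2000, seed=8)
        assert res[("S", "S")].p_value < 0.05

    def test_pathways_per_cluster_histogram(self):
        memberships = [
            PathwayRecord("w1", "p1"), PathwayRecord("w1", "p2"),
            PathwayRecord("w1", "p3"), PathwayRecord("s1", "p1"),
        ]
        labels = {"w1": "W", "s1": "S", "r1": "R"}
        out = pathways_per_cluster(memberships, labels)
        assert out["W"]["histogram"] == {3: 1}
        assert out["S"]["mean"] == 1.0
        assert out["R"]["n"] == 0

    def test_empty_membership_is_error(self):
        with pytest.raises(ValidationError):
            pathway_sharing_test([], {"a": "S"}, n_perm=100, seed=0)


def test_planted_interaction_preferences_recovered(default_world):
    """The generator's class-biased edge rates show up as a strong excess of
    ribosomal/weak-operon edges and a deficit of cross strong/weak edges,
    relative to the label-permutation null; weak-operon proteins end up with
    more interaction partners than strong-operon proteins."""
    world, truth = default_world
    labels = {
        f: t.cls for f, t in truth.families.items() if t.category != "background"
    }
    res = permutation_test_interactions(
        world.interactions, labels, n_perm=2000, seed=9
    )
    assert res[("R", "W")].observed > res[("R", "W")].null_mean
    assert res[("R", "W")].p_value < 0.05
    assert res[("S", "W")].observed < res[("S", "W")].null_mean
    assert res[("W", "W")].observed < res[("W", "W")].null_mean
    partners = interactions_per_protein(world.interactions, labels)
    assert partners["W"] > partners["S"]
    partners_no_r = interactions_per_protein(
        world.interactions, labels, exclude_class="R"
    )
    assert partners_no_r["W"] > partners_no_r["S"]


def test_planted_pathway_count_ordering_recovered(default_world):
    """Weak-operon clusters carry more pathway memberships than strong ones."""
    world, truth = default_world
    labels = {
        f: t.cls for f, t in truth.families.items() if t.category != "background"
    }
    out = pathways_per_cluster(world.pathways, labels)
    assert out["W"]["mean"] > out["S"]["mean"]
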