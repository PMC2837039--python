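"""Breakpoint distances, calibrated rearrangement estimates, NJ trees,
order profiles and the conserved-proximity graph."""

import numpy as np
import pytest

from persistome import DistanceMatrix, ValidationError
from persistome.gene_order import (
    EdeCurve,
    GeneOrder,
    breakpoint_distance,
    build_distance_graph,
    build_gene_orders,
    ede_calibrate,
    ede_distance,
    nj_newick,
    nj_tree,
    order_profile,
    order_vs_sequence_correlation,
    random_inversions,
)


def _order(signed, circular=True, genome_id="G"):
    return GeneOrder(
        genome_id,
        [(f"c{abs(x)}", 1 if x > 0 else -1) for x in signed],
        circular=circular,
    )


class TestBreakpointDistance:
    def test_identity_is_zero(self):
        a = _order([1, 2, 3, 4, 5])
        assert breakpoint_distance(a, a) == 0

    def test_single_inversion_breaks_two_adjacencies(self):
        a = _order([1, 2, 3, 4, 5])
        b = _order([1, -3, -2, 4, 5])
        assert breakpoint_distance(a, b) == 2

    def test_full_circular_reversal_is_zero(self):
        a = _order([1, 2, 3, 4, 5])
        b = _order([-5, -4, -3, -2, -1])
        assert breakpoint_distance(a, b) == 0

    def test_too_few_shared_markers(self):
        with pytest.raises(ValidationError):
            breakpoint_distance(_order([1]), _order([1]))

    def test_metric_properties_on_random_circular_orders(self):
        """Identity, symmetry and triangle inequality on the shared set."""
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = int(rng.integers(4, 21))
            base = list(range(1, n + 1))
            orders = []
            for _ in range(3):
                perm = random_inversions(base, int(rng.integers(0, n)), rng)
                orders.append(_order(perm))
            a, b, c = orders
            d_ab = breakpoint_distance(a, b)
            assert breakpoint_distance(b, a) == d_ab
            assert breakpoint_distance(a, a) == 0
            assert d_ab <= breakpoint_distance(a, c) + breakpoint_distance(c, b)


@pytest.fixture(scope="module")
def curve():
    return ede_calibrate(n=50, reps=200, seed=1)


class TestEdeEstimator:

    def test_zero_distance_estimates_zero(self, curve):
        assert curve.estimate(0.0) == (0.0, False)

    def test_curve_is_monotone_from_zero(self, curve):
        assert curve.expected_d[0] == 0.0
        assert np.all(np.diff(curve.expected_d) >= 0)

    def test_recovers_three_planted_inversions(self, curve):
        """Mean estimate over 50 trials within +-1 of the planted k=3."""
        rng = np.random.default_rng(2)
        base = list(range(1, 51))
        identity = _order(base)
        estimates = []
        for _ in range(50):
            perturbed = random_inversions(base, 3, rng)
            est, saturated = ede_distance(_order(perturbed), identity, curve)
            assert not saturated
            estimates.append(est)
        assert abs(np.mean(estimates) - 3) <= 1.0

    def test_saturation_is_flagged(self, curve):
        est, saturated = curve.estimate(1e9)
        assert saturated and est == curve.k_grid[-1]

    def test_estimates_increase_with_planted_k(self, curve):
        rng = np.random.default_rng(3)
        base = list(range(1, 51))
        identity = _order(base)
        means = []
        for k in (1, 4, 8):
            vals = [
                ede_distance(_order(random_inversions(base, k, rng)), identity,
                             curve)[0]
                for _ in range(30)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestNeighbourJoining:
    def test_three_taxon_branch_lengths(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            [[0, 2, 4], [2, 0, 4], [4, 4, 0]])
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4):2) -> additive pairwise distances
        values = {
            ("A", "B"): 3, ("A", "C"): 7, ("A", "D"): 8,
            ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 7,
        }
        labels = ["A", "B", "C", "D"]
        mat = np.zeros((4, 4))
        for (x, y), d in values.items():
            i, j = labels.index(x), labels.index(y)
            mat[i, j] = mat[j, i] = d
        tree = nj_tree(DistanceMatrix(labels, mat))
        tip_dist = tree.tip_tip_distances()
        for (x, y), d in values.items():
            assert abs(tip_dist[x, y] - d) < 1e-9

    def test_newick_output_terminates(self):
        dm = DistanceMatrix(["A", "B", "C"], [[0, 2, 4], [2, 0, 4], [4, 4, 0]])
        assert nj_newick(dm).endswith(";")


def test_order_profile_reference_is_monotone(default_world):
    world, _ = default_world
    from persistome.pipeline import PipelineConfig, run_pipeline

    result = run_pipeline(
        world, PipelineConfig(seed=0, stages=("resolve", "classify"))
    )
    ref = sorted(world.genomes)[0]
    profile = order_profile(ref, result.world, result.final_ids)
    ref_row = [p for p in profile[ref] if p is not None]
    assert len(ref_row) == len(profile[ref])  # reference has every gene
    assert all(b >= a for a, b in zip(ref_row, ref_row[1:]))
    # some other genome misses some genes -> gaps appear as None
    n_gaps = sum(
        row.count(None) for g, row in profile.items() if g != ref
    )
    assert n_gaps > 0


def test_order_profile_unknown_reference(default_world):
    world, _ = default_world
    with pytest.raises(ValidationError):
        order_profile("NOPE", world, [])


def test_distance_graph_recovers_planted_operon_blocks(clean_world):
    """Each planted operon block forms exactly one connected component."""
    world, truth = clean_world
    from persistome.pipeline import PipelineConfig, run_pipeline

    result = run_pipeline(
        world, PipelineConfig(seed=0, stages=("resolve", "classify"))
    )
    final = set(result.final_ids)
    edges, components = build_distance_graph(result.world, sorted(final))
    comp_of = {}
    for i, comp in enumerate(components):
        for cid in comp:
            comp_of[cid] = i
    for block_id, members in truth.blocks.items():
        members = [m for m in members if m in final]
        if len(members) < 2:
            continue
        comps = {comp_of[m] for m in members}
        assert len(comps) == 1, f"block {block_id} split across components"
        assert components[comps.pop()] == set(members), (
            f"block {block_id} merged with foreign clusters"
        )
    for edge in edges:
        assert 0 <= edge.support <= edge.co_present


def test_correlation_identity_and_degenerate():
    dm = DistanceMatrix(["A", "B", "C"], [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
    r, n = order_vs_sequence_correlation(dm, dm)
    assert r == pytest.approx(1.0) and n == 3
    const = DistanceMatrix(["A", "B", "C"], np.zeros((3, 3)))
    with pytest.warns(UserWarning):
        r, _ = order_vs_sequence_correlation(dm, const)
    assert np.isnan(r)
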