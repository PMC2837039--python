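"""Operon-preference profiles and contingency analyses."""

import numpy as np
import pytest

from persistome import (
    Category,
    GeneRecord,
    Genome,
    OperonCall,
    OrthologCluster,
    Replicon,
    Strand,
    ValidationError,
    World,
)
from persistome.operons import (
    OperonProfile,
    category_distribution,
    category_operon_fractions,
    copy_number_operon_test,
    operon_profile,
    pair_composition_test,
)
from persistome.pipeline import PipelineConfig, run_pipeline


def _profiled_cluster(n_in: int, n_total: int):
    members = {f"G{i:03d}": [f"g{i}"] for i in range(n_total)}
    cluster = OrthologCluster("FAMX", members)
    calls = {
        f"g{i}": OperonCall(f"G{i:03d}", f"g{i}", in_operon=(i < n_in))
        for i in range(n_total)
    }
    return cluster, calls


@pytest.mark.parametrize(
    "n_in,n_total,strength",
    [(85, 100, "strong"), (80, 100, "strong"), (79, 100, "weak")],
)
def test_strength_threshold_is_at_least_80_percent(n_in, n_total, strength):
    cluster, calls = _profiled_cluster(n_in, n_total)
    profile = operon_profile(cluster, calls)
    assert profile.strength == strength
    assert profile.fraction == pytest.approx(n_in / n_total)


def test_missing_calls_drop_out_of_denominator():
    cluster, calls = _profiled_cluster(8, 10)
    del calls["g9"]  # no call for one member
    profile = operon_profile(cluster, calls)
    assert profile.n_present == 9
    assert profile.fraction == pytest.approx(8 / 9)


def test_no_calls_is_error():
    cluster, _ = _profiled_cluster(0, 5)
    with pytest.raises(ValidationError):
        operon_profile(cluster, {})


def _make_profiles(spec):
    """spec: {cluster_id: (n_in, n_present, category)}"""
    profiles, categories = {}, {}
    for cid, (n_in, n_present, cat) in spec.items():
        profiles[cid] = OperonProfile(
            cid, n_present, n_in, n_in / n_present,
            "strong" if n_in / n_present >= 0.8 else "weak",
        )
        categories[cid] = cat
    return profiles, categories


def test_copy_number_test_odds_ratio():
    profiles, categories = _make_profiles({
        "s": (20, 30, Category.SINGLETON),
        "d": (10, 30, Category.DUPLICATE),
    })
    res = copy_number_operon_test(profiles, categories)
    assert res.table.tolist() == [[20, 10], [10, 20]]
    assert res.odds_ratio == pytest.approx(4.0)


def test_copy_number_test_independence():
    profiles, categories = _make_profiles({
        "s": (10, 20, Category.SINGLETON),
        "d": (10, 20, Category.DUPLICATE),
    })
    res = copy_number_operon_test(profiles, categories)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_copy_number_test_degenerate_margin_flagged():
    profiles, categories = _make_profiles({
        "s": (1, 1, Category.SINGLETON),
        "d": (0, 1, Category.DUPLICATE),
    })
    res = copy_number_operon_test(profiles, categories)
    assert res.degenerate and np.isinf(res.odds_ratio)


def _pair_world(operon_layout):
    """operon_layout: list of lists of categories, one inner list per operon."""
    world = World()
    world.genomes["G0"] = Genome("G0", 1_000_000)
    categories = {}
    final = set()
    pos = 100
    for op_idx, cats in enumerate(operon_layout):
        for j, cat in enumerate(cats):
            cid = f"C{op_idx}_{j}"
            gid = f"g{op_idx}_{j}"
            world.genes[gid] = GeneRecord(
                "G0", gid, Replicon.CHROMOSOME, pos, pos + 299, Strand.PLUS, 100
            )
            pos += 400
            world.clusters[cid] = OrthologCluster(cid, {"G0": [gid]})
            world.operon_calls[gid] = OperonCall(
                "G0", gid, True, operon_id=f"op{op_idx}"
            )
            categories[cid] = cat
            final.add(cid)
        pos += 5000
    return world, categories, final


def test_pair_composition_adjacency_enumeration():
    """Operon labelled (S, S, D) yields one identical and one mixed pair."""
    world, categories, final = _pair_world(
        [[Category.SINGLETON, Category.SINGLETON, Category.DUPLICATE]]
    )
    res = pair_composition_test(world, categories, final)
    assert res.table.tolist() == [[1, 1], [0, 0]]


def test_pair_composition_all_singletons_has_no_mixed_pairs():
    world, categories, final = _pair_world(
        [[Category.SINGLETON] * 4, [Category.SINGLETON] * 3]
    )
    res = pair_composition_test(world, categories, final)
    assert res.table.tolist() == [[5, 0], [0, 0]]


def test_pair_composition_without_operons_warns():
    world, categories, final = _pair_world([[Category.SINGLETON]])
    with pytest.warns(UserWarning):
        assert pair_composition_test(world, categories, final) is None


def test_pair_composition_calibrated_under_independent_labels():
    """With labels assigned independently of operon structure, the pair test
    odds ratio is ~1: the 95% CI covers 1 in >= 90% of simulations."""
    rng = np.random.default_rng(21)
    covered = 0
    n_sim = 60
    for _ in range(n_sim):
        layout = []
        for _ in range(40):
            size = int(rng.integers(2, 6))
            layout.append([
                Category.SINGLETON if rng.random() < 0.5 else Category.DUPLICATE
                for _ in range(size)
            ])
        world, categories, final = _pair_world(layout)
        res = pair_composition_test(world, categories, final)
        a, b = res.table[0]
        c, d = res.table[1]
        if min(a, b, c, d) == 0:
            covered += 1  # too sparse to exclude OR = 1
            continue
        log_or = np.log(res.odds_ratio)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        covered += abs(log_or) < 1.96 * se
    assert covered / n_sim >= 0.90


def test_category_distribution_sums_and_generic_exclusion():
    cog_map = {f"c{i}": cat for i, cat in enumerate(
        ["J"] * 5 + ["L"] * 3 + ["R"] * 2 + ["S"] * 1 + ["K"] * 1
    )}
    dist = category_distribution(list(cog_map), cog_map)
    assert sum(v["percent"] for v in dist.values()) == pytest.approx(100.0)
    assert dist["R"]["normalized_percent"] is None
    assert dist["S"]["normalized_percent"] is None
    norm_total = sum(
        v["normalized_percent"] for v in dist.values()
        if v["normalized_percent"] is not None
    )
    assert norm_total == pytest.approx(100.0)


def test_category_operon_fractions_single_category():
    profiles, _ = _make_profiles({"c1": (8, 10, Category.SINGLETON),
                                  "c2": (6, 10, Category.SINGLETON)})
    fractions = category_operon_fractions(profiles, {"c1": "J", "c2": "J"})
    assert fractions == {"J": pytest.approx(0.7)}


def test_planted_operon_strength_recovered(default_world):
    """Planted retention 0.95 vs 0.5 maps to strong vs weak labels for
    >= 95% of clusters."""
    world, truth = default_world
    result = run_pipeline(
        world, PipelineConfig(seed=0, stages=("resolve", "classify", "operon"))
    )
    planted = truth.strength_labels()
    checked = agree = 0
    for cid, label in result.strength_labels.items():
        if cid in planted:
            checked += 1
            agree += label == planted[cid]
    assert checked >= 80
    assert agree / checked >= 0.95
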