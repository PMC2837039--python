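"""Rate proxies, Scoredist distances, and group comparisons."""

import numpy as np
import pytest
from scipy import stats as scipy_stats

from persistome import HitRecord, OrthologCluster, ValidationError
from persistome.evolution import (
    cluster_rate,
    compare_groups,
    concatenated_distance_matrix,
    group_summary,
    normalized_bitscore,
    scoredist,
)


def _pair_hits(scores: dict[tuple[str, str], float], aln_len=100):
    hits = {}
    for (a, b), norm in scores.items():
        hits.setdefault(a, []).append(
            HitRecord(a, b, 1e-20, norm * aln_len, aln_len)
        )
    return hits


def test_cluster_rate_is_mean_over_pairs():
    cluster = OrthologCluster(
        "FAMX", {"G0": ["a"], "G1": ["b"], "G2": ["c"]}
    )
    hits = _pair_hits({("a", "b"): 0.6, ("a", "c"): 0.8, ("b", "c"): 1.0})
    rate = cluster_rate(cluster, hits)
    assert rate.mean_norm_bitscore == pytest.approx(0.8)
    assert rate.n_pairs == 3
    assert normalized_bitscore(hits["a"][0]) == pytest.approx(0.6)


def test_cluster_with_single_member_warns_and_returns_none():
    cluster = OrthologCluster("FAMX", {"G0": ["a"]})
    with pytest.warns(UserWarning):
        assert cluster_rate(cluster, {}) is None


def test_group_summary_median_and_exclusion():
    rates = {"c1": 0.5, "c2": 0.7, "c3": 0.9, "r1": 0.97, "r2": 0.99}
    labels = {"c1": "S", "c2": "S", "c3": "S", "r1": "R", "r2": "R"}
    full = group_summary(rates, labels)
    assert full == {"R": pytest.approx(0.98), "S": pytest.approx(0.7)}
    # excluding the ribosome-like label only removes that group's rows
    without = group_summary(rates, labels, exclude=("R",))
    assert without == {"S": pytest.approx(0.7)}


class TestScoredist:
    def test_identical_sequences_give_zero(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        d, capped = scoredist(seq, seq)
        assert d == 0.0 and not capped

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(8)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            n = int(rng.integers(30, 80))
            a = "".join(rng.choice(aa, size=n))
            b = "".join(rng.choice(aa, size=n))
            assert scoredist(a, b) == scoredist(b, a)

    def test_unrelated_sequences_are_capped(self):
        rng = np.random.default_rng(9)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aa, size=200))
        b = "".join(rng.choice(aa, size=200))
        d, capped = scoredist(a, b, cap=1000.0)
        assert capped and d == 1000.0

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValidationError):
            scoredist("AAA", "AA")

    def test_gap_columns_are_ignored(self):
        d_plain, _ = scoredist("MKTAYI", "MKTAYI")
        d_gapped, _ = scoredist("MKTA-YI", "MKTAGYI")
        assert d_plain == d_gapped == 0.0

    def test_distance_grows_with_substitutions_in_expectation(self):
        rng = np.random.default_rng(10)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(aa, size=150))
        means = []
        for n_sub in (5, 20, 50):
            vals = []
            for _ in range(15):
                mutated = list(base)
                for idx in rng.choice(150, size=n_sub, replace=False):
                    mutated[idx] = str(rng.choice(aa))
                vals.append(scoredist(base, "".join(mutated))[0])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


def test_concatenated_matrix_zero_and_symmetric():
    alignments = {
        "FAM1": {"G0": "MKTAYI", "G1": "MKTAYI", "G2": "MKTAYI"},
        "FAM2": {"G0": "HFSRQL", "G1": "HFSRQL", "G2": "HFSRQL"},
    }
    dm = concatenated_distance_matrix(alignments, ["G0", "G1", "G2"])
    assert np.allclose(dm.values, 0.0)


def test_concatenated_matrix_tracks_planted_divergence(tiny_world):
    """Clock-like planted divergence: matrix entries rank-correlate with the
    sum of the two genomes' planted divergence times (Spearman rho > 0.9)."""
    world, truth = tiny_world
    alignments = {}
    for cid, cluster in world.clusters.items():
        rows = {}
        for g, members in cluster.members.items():
            gid = truth.true_ortholog[cid].get(g)
            if gid in world.sequences:
                rows[g] = world.sequences[gid]
        if len(rows) >= 2:
            alignments[cid] = rows
    genomes = sorted(world.genomes)
    dm = concatenated_distance_matrix(alignments, genomes)
    observed, planted = [], []
    for i, gi in enumerate(genomes):
        for j in range(i + 1, len(genomes)):
            gj = genomes[j]
            if np.isfinite(dm[gi, gj]):
                observed.append(dm[gi, gj])
                planted.append(truth.divergence[gi] + truth.divergence[gj])
    rho = scipy_stats.spearmanr(observed, planted).statistic
    assert rho > 0.9


class TestCompareGroups:
    def test_rank_sum_type_one_error_is_calibrated(self):
        """Identical distributions: rejection rate at alpha=0.05 stays in
        [0.03, 0.07] over 1000 simulations."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(0.7, 0.15, size=30)
            b = rng.normal(0.7, 0.15, size=30)
            values = {f"a{i}": v for i, v in enumerate(a)}
            values.update({f"b{i}": v for i, v in enumerate(b)})
            labels = {k: k[0].upper() for k in values}
            comp = compare_groups(values, labels, "A", "B")
            rejections += comp.p_value < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_power_for_planted_shift(self):
        """+0.3 bits shift at n=50/50 is detected (p < 0.01) in >= 95% of
        simulations."""
        rng = np.random.default_rng(13)
        detected = 0
        n_sim = 200
        for _ in range(n_sim):
            a = rng.normal(0.65, 0.15, size=50)
            b = rng.normal(0.95, 0.15, size=50)
            values = {f"a{i}": v for i, v in enumerate(a)}
            values.update({f"b{i}": v for i, v in enumerate(b)})
            labels = {k: k[0].upper() for k in values}
            detected += compare_groups(values, labels, "A", "B").p_value < 0.01
        assert detected / n_sim >= 0.95

    def test_empty_group_is_error(self):
        values = {"a1": 0.1, "a2": 0.2, "a3": 0.3}
        labels = {"a1": "A", "a2": "A", "a3": "A"}
        with pytest.raises(ValidationError):
            compare_groups(values, labels, "A", "B")


def test_planted_class_rates_order_recovered(default_world):
    """Weak-operon families are planted more conserved than strong-operon
    families; cluster rates and the rank-sum test recover that."""
    world, truth = default_world
    values, labels = {}, {}
    for fam, fam_truth in truth.families.items():
        if fam_truth.cls not in ("S", "W") or fam_truth.category == "background":
            continue
        cluster = world.clusters.get(fam)
        if cluster is None:
            continue
        rate = cluster_rate(cluster, world.hits)
        if rate is None:
            continue
        values[fam] = rate.mean_norm_bitscore
        labels[fam] = fam_truth.cls
    comp = compare_groups(values, labels, "S", "W", metric="median")
    assert comp.group_stats["W"] > comp.group_stats["S"]
    assert comp.p_value < 0.01
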