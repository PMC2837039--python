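"""Evolutionary-rate proxies and sequence distances.

The rate proxy is the pairwise homology-search bit score normalised by
alignment length (bits per aligned column, higher = more conserved = slower
evolution), averaged over all resolved-ortholog pairs of a cluster. Group
comparisons use the median of these cluster means and a two-sided
Mann-Whitney rank-sum test.

Sequence distances follow the Scoredist construction: the BLOSUM62 alignment
score sigma is normalised between the expected random score sigma_r (from the
two sequences' residue compositions) and the mean self-score sigma_UL, and
the distance is d = -ln(sigma_n) * 100 * 1.337, capped when sigma_n <= 0.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices
from scipy import stats

from .model import (
    DistanceMatrix,
    HitRecord,
    OrthologCluster,
    ValidationError,
    World,
)

__all__ = [
    "ClusterRate",
    "normalized_bitscore",
    "cluster_rate",
    "group_summary",
    "scoredist",
    "concatenated_distance_matrix",
    "compare_groups",
    "GroupComparison",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
SCOREDIST_SCALE = 100.0 * 1.337
DEFAULT_DISTANCE_CAP = 1000.0


def normalized_bitscore(hit: HitRecord) -> float:
    """Bits per aligned column."""
    if hit.aln_len < 1:
        raise ValidationError("aln_len must be >= 1")
    return hit.bit_score / hit.aln_len


@dataclass
class ClusterRate:
    cluster_id: str
    mean_norm_bitscore: float
    n_pairs: int
    median_protein_len: float


def _pair_score(
    hits: dict[str, list[HitRecord]], gene_a: str, gene_b: str
) -> Optional[float]:
    """Normalised bit score for an unordered gene pair (mean over directions)."""
    values = []
    for q, s in ((gene_a, gene_b), (gene_b, gene_a)):
        for hit in hits.get(q, []):
            if hit.subject_gene_id == s:
                values.append(normalized_bitscore(hit))
                break
    if not values:
        return None
    return float(np.mean(values))


def cluster_rate(
    cluster: OrthologCluster,
    hits: dict[str, list[HitRecord]],
    world: Optional[World] = None,
) -> Optional[ClusterRate]:
    """Mean normalised bit score over all resolved-ortholog pairs.

    Pairs without a hit in either direction are skipped (and counted out of
    n_pairs). Returns None for clusters with fewer than 2 scorable members.
    """
    resolved = cluster.resolved_ortholog or {
        g: m[0] for g, m in cluster.members.items() if len(m) == 1
    }
    genes = sorted(resolved.values())
    scores = []
    for a, b in itertools.combinations(genes, 2):
        s = _pair_score(hits, a, b)
        if s is not None:
            scores.append(s)
    if len(genes) < 2 or not scores:
        warnings.warn(
            f"cluster {cluster.cluster_id}: fewer than 2 scored members", stacklevel=2
        )
        return None
    if world is not None:
        lengths = [world.genes[g].protein_len_aa for g in genes]
        median_len = float(np.median(lengths))
    else:
        median_len = float("nan")
    return ClusterRate(
        cluster_id=cluster.cluster_id,
        mean_norm_bitscore=float(np.mean(scores)),
        n_pairs=len(scores),
        median_protein_len=median_len,
    )


def group_summary(
    rates: dict[str, float], labels: dict[str, str], exclude: tuple[str, ...] = ()
) -> dict[str, float]:
    """Per-group median of cluster values; groups in ``exclude`` are dropped."""
    groups: dict[str, list[float]] = {}
    for cluster_id, value in rates.items():
        label = labels.get(cluster_id)
        if label is None or label in exclude:
            continue
        groups.setdefault(label, []).append(value)
    return {label: float(np.median(vals)) for label, vals in sorted(groups.items())}


def _blosum_score(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def scoredist(
    aligned_a: str,
    aligned_b: str,
    cap: float = DEFAULT_DISTANCE_CAP,
) -> tuple[float, bool]:
    """Scoredist evolutionary distance between two aligned sequences.

    Returns (distance, capped?). Columns where either sequence has a gap are
    ignored. Identical sequences give exactly 0.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValidationError(
            f"aligned length mismatch: {len(aligned_a)} vs {len(aligned_b)}"
        )
    pairs = [
        (x, y)
        for x, y in zip(aligned_a.upper(), aligned_b.upper())
        if x not in "-." and y not in "-."
    ]
    if not pairs:
        raise ValidationError("no aligned (gap-free) columns")
    length = len(pairs)
    sigma = sum(_blosum_score(x, y) for x, y in pairs)
    res_a = [x for x, _ in pairs]
    res_b = [y for _, y in pairs]
    # Expected random score for this composition and length: average pair
    # score over all cross pairings, times the number of columns.
    counts_a: dict[str, int] = {}
    counts_b: dict[str, int] = {}
    for x in res_a:
        counts_a[x] = counts_a.get(x, 0) + 1
    for y in res_b:
        counts_b[y] = counts_b.get(y, 0) + 1
    cross = sum(
        na * nb * _blosum_score(a, b)
        for a, na in counts_a.items()
        for b, nb in counts_b.items()
    )
    sigma_r = cross / length
    sigma_ul = 0.5 * (
        sum(_blosum_score(x, x) for x in res_a)
        + sum(_blosum_score(y, y) for y in res_b)
    )
    denom = sigma_ul - sigma_r
    if denom <= 0:
        return cap, True
    sigma_n = (sigma - sigma_r) / denom
    if sigma_n <= 0:
        return cap, True
    d = -np.log(sigma_n) * SCOREDIST_SCALE
    d = max(0.0, float(d))
    if d >= cap:
        return cap, True
    return d, False


def concatenated_distance_matrix(
    alignments: dict[str, dict[str, str]],
    genomes: list[str],
    cap: float = DEFAULT_DISTANCE_CAP,
) -> DistanceMatrix:
    """Scoredist over the concatenation of shared per-cluster aligned rows.

    ``alignments`` maps cluster_id -> {genome_id -> aligned row}. A genome
    pair needs at least 2 shared clusters; otherwise its entry is NaN.
    """
    labels = sorted(genomes)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            parts_a, parts_b = [], []
            shared = 0
            for rows in alignments.values():
                ra = rows.get(labels[i])
                rb = rows.get(labels[j])
                if ra is None or rb is None:
                    continue
                shared += 1
                parts_a.append(ra)
                parts_b.append(rb)
            if shared < 2:
                values[i, j] = values[j, i] = float("nan")
                continue
            d, _ = scoredist("".join(parts_a), "".join(parts_b), cap=cap)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


@dataclass
class GroupComparison:
    group_stats: dict[str, float]  # per-group median or mean
    statistic: float
    p_value: float
    metric: str
    test: str


def compare_groups(
    values: dict[str, float],
    labels: dict[str, str],
    group_a: str,
    group_b: str,
    metric: str = "median",
    test: str = "ranksum",
) -> GroupComparison:
    """Two-group comparison of per-cluster values.

    metric: "median" (bit scores) or "mean" (protein lengths);
    test: "ranksum" (two-sided Mann-Whitney) or "ttest".
    """
    a = [v for cid, v in values.items() if labels.get(cid) == group_a]
    b = [v for cid, v in values.items() if labels.get(cid) == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"need >= 2 clusters per group (got {len(a)} / {len(b)})"
        )
    agg = np.median if metric == "median" else np.mean
    if test == "ranksum":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ttest":
        stat, p = stats.ttest_ind(a, b)
    else:
        raise ValidationError(f"unknown test {test!r}")
    return GroupComparison(
        group_stats={group_a: float(agg(a)), group_b: float(agg(b))},
        statistic=float(stat),
        p_value=float(p),
        metric=metric,
        test=test,
    )
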