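"""Operon-preference classification and contingency analyses.

A cluster is a *strong* operon gene when its resolved orthologs sit inside an
operon in at least 80% of the genomes where the gene is present and has a
call; otherwise *weak*. Ribosomal-protein clusters are flagged separately.
Two Fisher exact tests probe (a) whether singletons sit in operons more often
than duplicates and (b) whether adjacent within-operon gene pairs prefer
identical copy-number categories over mixed ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .model import Category, OperonCall, OrthologCluster, ValidationError, World

__all__ = [
    "OperonProfile",
    "operon_profile",
    "ContingencyResult",
    "copy_number_operon_test",
    "pair_composition_test",
    "category_operon_fractions",
    "category_distribution",
]

STRONG_THRESHOLD = 0.80


@dataclass
class OperonProfile:
    cluster_id: str
    n_present: int
    n_in_operon: int
    fraction: float
    strength: str  # "strong" | "weak"
    ribo_flag: bool = False


def operon_profile(
    cluster: OrthologCluster,
    operon_calls: dict[str, OperonCall],
    strong_threshold: float = STRONG_THRESHOLD,
    ribosomal_ids: Optional[set[str]] = None,
) -> OperonProfile:
    """Fraction of genomes where the resolved ortholog is in an operon.

    The denominator is the number of genomes where the gene is present *and*
    has an operon call; members without a call are logged out of the
    denominator rather than counted as non-operon.
    """
    resolved = cluster.resolved_ortholog or {
        g: m[0] for g, m in cluster.members.items() if len(m) == 1
    }
    n_present = 0
    n_in = 0
    for gene_id in resolved.values():
        call = operon_calls.get(gene_id)
        if call is None:
            continue
        n_present += 1
        if call.in_operon:
            n_in += 1
    if n_present == 0:
        raise ValidationError(
            f"cluster {cluster.cluster_id}: no members with an operon call"
        )
    fraction = n_in / n_present
    strength = "strong" if fraction >= strong_threshold else "weak"
    ribo = cluster.cluster_id in (ribosomal_ids or set())
    return OperonProfile(cluster.cluster_id, n_present, n_in, fraction, strength, ribo)


@dataclass
class ContingencyResult:
    table: np.ndarray  # 2x2 counts
    odds_ratio: float  # sample ad/bc
    odds_ratio_cmle: float  # conditional-MLE estimate from the exact test
    p_value: float
    degenerate: bool = False  # a zero margin made the OR infinite/zero


def _fisher(table: np.ndarray) -> ContingencyResult:
    a, b = table[0]
    c, d = table[1]
    degenerate = (b * c == 0) or (a * d == 0)
    sample_or = float("inf") if b * c == 0 else (a * d) / (b * c)
    res = stats.fisher_exact(table, alternative="two-sided")
    return ContingencyResult(
        table=table,
        odds_ratio=sample_or,
        odds_ratio_cmle=float(res.statistic),
        p_value=float(res.pvalue),
        degenerate=degenerate,
    )


def copy_number_operon_test(
    profiles: dict[str, OperonProfile],
    categories: dict[str, Category],
) -> ContingencyResult:
    """Occurrence-level 2x2: (singleton vs duplicate) x (operon vs not).

    Each gene occurrence (one resolved ortholog in one genome with a call)
    contributes one count. OR > 1 means singletons favour operons.
    """
    table = np.zeros((2, 2), dtype=int)
    for cluster_id, profile in profiles.items():
        cat = categories.get(cluster_id)
        if cat is Category.SINGLETON:
            row = 0
        elif cat is Category.DUPLICATE:
            row = 1
        else:
            continue  # fused / mixed / excluded clusters are left out
        table[row, 0] += profile.n_in_operon
        table[row, 1] += profile.n_present - profile.n_in_operon
    return _fisher(table)


def pair_composition_test(
    world: World,
    categories: dict[str, Category],
    final_ids: set[str],
) -> Optional[ContingencyResult]:
    """Identical vs mixed adjacent gene pairs inside operons.

    Within each operon (operon_id grouping), persistent genes are ordered by
    position and each adjacent ordered pair is tabulated by the copy-number
    categories of its two genes: [[SS, SD], [DS, DD]]. OR > 1 means operons
    prefer category-identical pairs over the expectation from the marginal
    composition. Returns None (with a warning) when no operon holds two or
    more persistent genes.
    """
    gene_category: dict[str, Category] = {}
    for cluster_id in final_ids:
        cat = categories.get(cluster_id)
        if cat not in (Category.SINGLETON, Category.DUPLICATE):
            continue
        cluster = world.clusters[cluster_id]
        resolved = cluster.resolved_ortholog or {
            g: m[0] for g, m in cluster.members.items() if len(m) == 1
        }
        for gene_id in resolved.values():
            gene_category[gene_id] = cat
    operon_groups: dict[tuple[str, str], list[str]] = {}
    for gene_id, call in world.operon_calls.items():
        if not call.in_operon or call.operon_id is None:
            continue
        if gene_id not in gene_category:
            continue
        operon_groups.setdefault((call.genome_id, call.operon_id), []).append(gene_id)
    table = np.zeros((2, 2), dtype=int)
    found = False
    for (_, _), genes in sorted(operon_groups.items()):
        if len(genes) < 2:
            continue
        found = True
        genes = sorted(genes, key=lambda g: world.genes[g].start_bp)
        for ga, gb in zip(genes, genes[1:]):
            i = 0 if gene_category[ga] is Category.SINGLETON else 1
            j = 0 if gene_category[gb] is Category.SINGLETON else 1
            table[i, j] += 1
    if not found:
        import warnings

        warnings.warn("no operon contains two or more persistent genes", stacklevel=2)
        return None
    return _fisher(table)


def category_operon_fractions(
    profiles: dict[str, OperonProfile],
    cog_map: dict[str, str],
) -> dict[str, float]:
    """Mean operon fraction per functional (COG) category."""
    groups: dict[str, list[float]] = {}
    for cluster_id, profile in profiles.items():
        cat = cog_map.get(cluster_id, "unknown")
        groups.setdefault(cat, []).append(profile.fraction)
    return {cat: float(np.mean(v)) for cat, v in sorted(groups.items())}


def category_distribution(
    cluster_ids: list[str],
    cog_map: dict[str, str],
    generic_categories: tuple[str, ...] = ("R", "S"),
) -> dict[str, dict[str, Optional[float]]]:
    """Percent of clusters per functional category, plus a normalised column
    that excludes the generic categories (shown as None, mirroring their
    conventional exclusion)."""
    counts: dict[str, int] = {}
    for cluster_id in cluster_ids:
        cat = cog_map.get(cluster_id, "unknown")
        counts[cat] = counts.get(cat, 0) + 1
    total = sum(counts.values())
    non_generic_total = sum(
        n for cat, n in counts.items() if cat not in generic_categories
    )
    out: dict[str, dict[str, Optional[float]]] = {}
    for cat, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        norm = (
            None
            if cat in generic_categories or non_generic_total == 0
            else n / non_generic_total * 100.0
        )
        out[cat] = {"percent": n / total * 100.0, "normalized_percent": norm}
    return out
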