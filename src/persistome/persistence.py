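"""Persistence and copy-number/fusion classification of ortholog clusters.

A cluster is *persistent* when its family occurs in at least 90% of the
genomes (ceil rule: with 113 genomes the cutoff is 102). Clusters are further
split into singletons (one counted copy per genome after collapsing recent
duplicates, i.e. paralogs >80% identical to the kept copy) and duplicates,
and into fused / mixed / plain by the fraction of member proteins that look
like two-family domain fusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    Category,
    GeneRecord,
    HitRecord,
    OrthologCluster,
    Replicon,
    ValidationError,
    World,
)

__all__ = [
    "ClassificationThresholds",
    "persistence_fraction",
    "classify_copy_number",
    "classify_fusion",
    "finalize_set",
    "FinalSet",
]


@dataclass(frozen=True)
class ClassificationThresholds:
    persistence_min: float = 0.90
    recent_dup_identity: float = 80.0  # percent identity
    fused_min: float = 0.50
    mixed_min: float = 0.10
    fusion_overlap_max: float = 0.20  # max overlap fraction of shorter alignment
    fusion_evalue_max: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.mixed_min < self.fused_min <= 1):
            raise ValidationError("need 0 < mixed_min < fused_min <= 1")
        if not (0 < self.persistence_min <= 1):
            raise ValidationError("persistence_min must be in (0, 1]")


def persistence_fraction(
    cluster: OrthologCluster,
    n_genomes: int,
    persistence_min: float = 0.90,
) -> tuple[float, bool]:
    """(fraction of genomes containing the family, persistent?).

    Persistent iff the family occurs in at least ceil(persistence_min * N)
    genomes.
    """
    present = len(cluster.genomes_present())
    if present == 0:
        raise ValidationError(f"cluster {cluster.cluster_id} is empty")
    fraction = present / n_genomes
    persistent = present >= math.ceil(persistence_min * n_genomes)
    return fraction, persistent


def classify_copy_number(
    cluster: OrthologCluster,
    identities: dict[frozenset, float],
    recent_dup_identity: float = 80.0,
) -> Category:
    """Singleton vs duplicate, collapsing recent duplications.

    ``identities`` maps frozenset({gene_a, gene_b}) to percent identity for
    within-genome copy pairs. A genome whose extra copies are all more than
    ``recent_dup_identity`` percent identical to the kept copy counts as
    single-copy: the duplication is recent and the copy may well be lost
    again.
    """
    resolved = cluster.resolved_ortholog or {}
    for genome_id, members in cluster.members.items():
        if len(members) <= 1:
            continue
        kept = resolved.get(genome_id, members[0])
        for copy in members:
            if copy == kept:
                continue
            key = frozenset((kept, copy))
            if key not in identities:
                raise ValidationError(
                    f"missing within-genome identity for pair {kept}--{copy}"
                )
            if identities[key] <= recent_dup_identity:
                return Category.DUPLICATE
    return Category.SINGLETON


def _interval_overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap length divided by the shorter interval length (0 if disjoint)."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    if hi < lo:
        return 0.0
    shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return (hi - lo + 1) / shorter


def classify_fusion(
    cluster: OrthologCluster,
    hits: dict[str, list[HitRecord]],
    cluster_of_gene: dict[str, str],
    persistent_ids: set[str],
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> tuple[Category, dict[str, bool]]:
    """Fused / mixed / plain, plus the per-protein fused flags.

    A protein is flagged fused when its hit list contains high-scoring
    alignments to members of at least two distinct persistent clusters (other
    than its own) occupying essentially disjoint stretches of the query
    (overlap < 20% of the shorter aligned region). Absent evidence means
    plain — this detector only ever adds evidence, never subtracts.
    """
    flags: dict[str, bool] = {}
    for gene_id in cluster.all_gene_ids():
        best_per_cluster: dict[str, HitRecord] = {}
        for hit in hits.get(gene_id, []):
            if hit.e_value > thresholds.fusion_evalue_max:
                continue
            if hit.q_start <= 0 or hit.q_end <= 0:
                continue  # no query coordinates -> unusable for domain logic
            target = cluster_of_gene.get(hit.subject_gene_id)
            if target is None or target == cluster.cluster_id:
                continue
            if target not in persistent_ids:
                continue
            prev = best_per_cluster.get(target)
            if prev is None or hit.bit_score > prev.bit_score:
                best_per_cluster[target] = hit
        fused = False
        entries = list(best_per_cluster.values())
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                a = (entries[i].q_start, entries[i].q_end)
                b = (entries[j].q_start, entries[j].q_end)
                if _interval_overlap_fraction(a, b) < thresholds.fusion_overlap_max:
                    fused = True
        flags[gene_id] = fused
    n = len(flags)
    frac = sum(flags.values()) / n if n else 0.0
    if frac > thresholds.fused_min:
        category = Category.FUSED
    elif frac > thresholds.mixed_min:
        category = Category.MIXED
    else:
        category = None  # plain: copy-number category applies
    return category, flags


@dataclass
class FinalSet:
    clusters: dict[str, OrthologCluster]
    counts: dict[str, int] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)  # cluster_id -> reason


def finalize_set(
    world: World,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    candidate_ids: Optional[list[str]] = None,
) -> FinalSet:
    """Assemble the final persistent set.

    Drops clusters excluded by ambiguous ortholog resolution, removes
    plasmid-borne members, re-evaluates persistence after that removal and
    drops clusters that fall below the cutoff. Category counts are reported.
    """
    n_genomes = len(world.genomes)
    final: dict[str, OrthologCluster] = {}
    dropped: dict[str, str] = {}
    ids = candidate_ids if candidate_ids is not None else list(world.clusters)
    for cluster_id in ids:
        cluster = world.clusters[cluster_id]
        if cluster.category is Category.EXCLUDED:
            dropped[cluster_id] = cluster.excluded_reason or "excluded"
            continue
        pruned_members: dict[str, list[str]] = {}
        for genome_id, members in cluster.members.items():
            chromosomal = [
                m for m in members
                if world.genes[m].replicon is Replicon.CHROMOSOME
            ]
            if chromosomal:
                pruned_members[genome_id] = chromosomal
        pruned = OrthologCluster(
            cluster_id=cluster.cluster_id,
            members=pruned_members,
            category=cluster.category,
            resolved_ortholog=(
                {
                    g: gene
                    for g, gene in (cluster.resolved_ortholog or {}).items()
                    if g in pruned_members and gene in pruned_members[g]
                }
                or None
            ),
        )
        if not pruned_members:
            dropped[cluster_id] = "no chromosomal members"
            continue
        fraction, persistent = persistence_fraction(
            pruned, n_genomes, thresholds.persistence_min
        )
        pruned.persistence_fraction = fraction
        if not persistent:
            dropped[cluster_id] = (
                f"below persistence cutoff after plasmid removal "
                f"({len(pruned.genomes_present())}/{n_genomes})"
            )
            continue
        final[cluster_id] = pruned
    counts: dict[str, int] = {}
    for cluster in final.values():
        key = cluster.category.value if cluster.category else "unclassified"
        counts[key] = counts.get(key, 0) + 1
    return FinalSet(clusters=final, counts=counts, dropped=dropped)
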