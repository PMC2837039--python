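"""Ortholog-vs-paralog resolution by rank scoring.

When a genome carries several copies of a gene family, the true ortholog is
expected to be, on average, more similar to the single-copy orthologs from
the other genomes than its paralogs are. Each single-copy member of the
cluster contributes its homology-search hit list: within that list the family
copies are ranked by order of appearance (1 = first), a copy missing from the
list scores one worse than the worst possible rank, and the ranks are summed
across lists. The copy with the lowest total S wins, provided the margin to
the runner-up is at least 10% of the smallest achievable total S_min (= the
number of contributing lists). Otherwise the genome — and by default the
whole cluster — is declared ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .model import HitRecord, OrthologCluster, Category, sort_hits

__all__ = [
    "RankScoreResult",
    "rank_scores",
    "resolve_duplicates",
    "UnscorableError",
    "NotDuplicatedError",
]


class UnscorableError(ValueError):
    """No single-copy member contributes a usable hit list."""


class NotDuplicatedError(ValueError):
    """The genome does not carry >= 2 copies in this cluster."""


@dataclass
class RankScoreResult:
    genome_id: str
    scores: dict[str, int]  # gene_id -> total rank score S
    s_min: int  # number of contributing lists (all-rank-1 total)
    chosen: Optional[str] = None
    gap: Optional[int] = None
    status: Optional[str] = None  # "resolved" | "ambiguous"

    def decide(self, gap_fraction: float = 0.1) -> "RankScoreResult":
        """Apply the margin rule: resolved iff gap >= ceil(gap_fraction * S_min)."""
        ordered = sorted(self.scores.items(), key=lambda kv: (kv[1], kv[0]))
        best_gene, best_s = ordered[0]
        second_s = ordered[1][1]
        self.gap = second_s - best_s
        threshold = math.ceil(gap_fraction * self.s_min)
        if self.gap >= threshold:
            self.chosen = best_gene
            self.status = "resolved"
        else:
            self.chosen = None
            self.status = "ambiguous"
        return self


def rank_scores(
    cluster: OrthologCluster,
    hits: dict[str, list[HitRecord]],
    genome_id: str,
) -> RankScoreResult:
    """Total rank score per copy of ``cluster`` in ``genome_id``.

    Contributing lists come from every *other* genome with exactly one member
    in the cluster and a nonempty hit list. Within each list, only the k
    copies are considered, in first-appearance order after sorting by
    ascending e-value (ties by descending bit score); rank 1, 2, ...; a copy
    absent from the list receives rank k + 1.
    """
    copies = cluster.members.get(genome_id, [])
    k = len(copies)
    if k < 2:
        raise NotDuplicatedError(
            f"cluster {cluster.cluster_id}: genome {genome_id} has {k} copies"
        )
    copy_set = set(copies)
    scores = {c: 0 for c in copies}
    n_lists = 0
    for other_genome, members in cluster.members.items():
        if other_genome == genome_id or len(members) != 1:
            continue
        query = members[0]
        hit_list = hits.get(query)
        if not hit_list:
            continue
        seen: list[str] = []
        for hit in sort_hits(hit_list):
            if hit.subject_gene_id in copy_set and hit.subject_gene_id not in seen:
                seen.append(hit.subject_gene_id)
        if not seen:
            continue  # list carries no information about the copies
        n_lists += 1
        ranks = {gene: r for r, gene in enumerate(seen, start=1)}
        for copy in copies:
            scores[copy] += ranks.get(copy, k + 1)
    if n_lists == 0:
        raise UnscorableError(
            f"cluster {cluster.cluster_id}: no contributing hit lists for {genome_id}"
        )
    return RankScoreResult(genome_id=genome_id, scores=scores, s_min=n_lists)


def resolve_duplicates(
    cluster: OrthologCluster,
    hits: dict[str, list[HitRecord]],
    gap_fraction: float = 0.1,
    exclude_whole_cluster: bool = True,
) -> OrthologCluster:
    """Resolve every duplicated genome of ``cluster`` in place.

    Fills ``resolved_ortholog`` (single-copy genomes map to their only
    member). If any duplicated genome is ambiguous the whole cluster is
    marked ``excluded`` unless ``exclude_whole_cluster`` is False, in which
    case only the ambiguous genomes are dropped from the resolved map.
    """
    resolved: dict[str, str] = {
        g: members[0] for g, members in cluster.members.items() if len(members) == 1
    }
    ambiguous: list[str] = []
    for genome_id in cluster.duplicated_genomes():
        result = rank_scores(cluster, hits, genome_id).decide(gap_fraction)
        if result.status == "resolved":
            resolved[genome_id] = result.chosen  # type: ignore[assignment]
        else:
            ambiguous.append(genome_id)
    if ambiguous and exclude_whole_cluster:
        cluster.category = Category.EXCLUDED
        cluster.excluded_reason = (
            "ambiguous rank scores in: " + ",".join(sorted(ambiguous))
        )
        cluster.resolved_ortholog = None
    else:
        cluster.resolved_ortholog = resolved
    return cluster
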