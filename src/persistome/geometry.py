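"""Positional transforms and genome-scale spatial statistics.

All coordinates are 1-based inclusive. Replication in bacteria is
bidirectional, so a gene transcribed on the minus strand of the deposited
sequence is (to first order) on the lagging strand; its position is reported
as genome size minus its start coordinate so that leading- and lagging-strand
genes live on a comparable axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .model import GeneRecord, Genome, Strand, Topology, ValidationError, World

__all__ = [
    "effective_start",
    "persistent_range",
    "pair_distance",
    "med_mad_spacing",
    "SpacingStat",
]


def effective_start(gene: GeneRecord, genome: Genome) -> int:
    """Strand-corrected start position in bp.

    Plus-strand (leading) genes keep their start; minus-strand (lagging)
    genes are mapped to ``size_bp - start_bp``.
    """
    if gene.start_bp > genome.size_bp:
        raise ValidationError(
            f"gene {gene.gene_id}: start {gene.start_bp} > genome size {genome.size_bp}"
        )
    if gene.strand is Strand.PLUS:
        return gene.start_bp
    return genome.size_bp - gene.start_bp


def persistent_range(genome: Genome, genes: Iterable[GeneRecord]) -> float:
    """Percent of the genome spanned by the given genes.

    Linear replicons use last start minus first start. Circular replicons use
    the complement of the largest gap between consecutive sorted starts, i.e.
    the shortest window containing every gene.
    """
    starts = sorted(effective_start(g, genome) for g in genes)
    if not starts:
        raise ValidationError("persistent_range requires at least one gene")
    L = genome.size_bp
    if genome.topology is Topology.LINEAR:
        return (starts[-1] - starts[0]) / L * 100.0
    gaps = [b - a for a, b in zip(starts, starts[1:])]
    gaps.append(L - starts[-1] + starts[0])  # wrap-around gap
    return (L - max(gaps)) / L * 100.0


def _span(gene: GeneRecord, L: int) -> tuple[int, int]:
    """Gene interval as (start, end) with end possibly > L for wrapped genes."""
    if gene.wraps_origin:
        return gene.start_bp, gene.end_bp + L
    return gene.start_bp, gene.end_bp


def pair_distance(gene_a: GeneRecord, gene_b: GeneRecord, genome: Genome) -> int:
    """Intergenic distance in bp: bases strictly between the two genes.

    Overlapping or adjacent genes give 0. On circular replicons the shorter
    of the two arcs is taken.
    """
    if gene_a.genome_id != gene_b.genome_id or gene_a.replicon != gene_b.replicon:
        raise ValidationError(
            f"incomparable: {gene_a.gene_id} and {gene_b.gene_id} "
            "are not on the same replicon"
        )
    L = genome.size_bp
    sa, ea = _span(gene_a, L)
    sb, eb = _span(gene_b, L)
    if genome.topology is Topology.LINEAR:
        if sb > ea:
            return sb - ea - 1
        if sa > eb:
            return sa - eb - 1
        return 0
    # Circular: gap from the end of one to the start of the other, both ways.
    gap_ab = (sb - ea - 1) % L
    gap_ba = (sa - eb - 1) % L
    # Overlap check on the circle: if either gap "wraps past" the other gene
    # the intervals intersect. Intervals intersect iff the two gaps together
    # exceed the free space.
    len_a = ea - sa + 1
    len_b = eb - sb + 1
    free = L - len_a - len_b
    if free < 0 or gap_ab + gap_ba > free:
        return 0
    return min(gap_ab, gap_ba)


@dataclass
class SpacingStat:
    cluster_a: str
    cluster_b: str
    distances: list[int]
    med: Optional[float]
    mad: Optional[float]
    support: int
    verdict: str  # "regular" | "irregular" | "insufficient"


def med_mad_spacing(
    cluster_a_id: str,
    cluster_b_id: str,
    world: World,
    regular_ratio: float = 0.1,
) -> SpacingStat:
    """Median / median-absolute-deviation of the pair distance across genomes.

    A pair is flagged "regular" when MAD <= regular_ratio * MED, i.e. the
    spacing is nearly constant wherever both genes occur. Fewer than 3
    informative genomes yields "insufficient".
    """
    ca = world.clusters[cluster_a_id]
    cb = world.clusters[cluster_b_id]
    ra = ca.resolved_ortholog or {g: m[0] for g, m in ca.members.items() if len(m) == 1}
    rb = cb.resolved_ortholog or {g: m[0] for g, m in cb.members.items() if len(m) == 1}
    distances: list[int] = []
    for genome_id in sorted(set(ra) & set(rb)):
        gene_a = world.genes[ra[genome_id]]
        gene_b = world.genes[rb[genome_id]]
        if gene_a.replicon != gene_b.replicon:
            continue
        distances.append(pair_distance(gene_a, gene_b, world.genomes[genome_id]))
    support = len(distances)
    if support < 3:
        return SpacingStat(cluster_a_id, cluster_b_id, distances, None, None, support,
                           "insufficient")
    med = float(np.median(distances))
    mad = float(np.median(np.abs(np.asarray(distances) - med)))
    verdict = "regular" if mad <= regular_ratio * med else "irregular"
    return SpacingStat(cluster_a_id, cluster_b_id, distances, med, mad, support, verdict)
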