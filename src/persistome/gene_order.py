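"""Gene-order conservation: pair-distance graph, order profiles, breakpoint
and calibrated rearrangement distances, neighbour-joining trees.

The rearrangement estimator follows the empirically-calibrated construction:
random inversions are applied to an identity signed circular permutation, the
mean observed breakpoint distance is recorded as a function of the true
inversion count k, and the resulting monotone curve is inverted to map an
observed distance back to an estimated k. Observed distances beyond the
curve's saturation are clamped and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import networkx as nx
import numpy as np
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from .model import DistanceMatrix, Replicon, ValidationError, World

__all__ = [
    "GeneOrder",
    "PairSupportEdge",
    "EdeCurve",
    "build_gene_orders",
    "build_distance_graph",
    "order_profile",
    "breakpoint_distance",
    "random_inversions",
    "ede_calibrate",
    "ede_distance",
    "ede_distance_matrix",
    "nj_tree",
    "order_vs_sequence_correlation",
]


@dataclass
class GeneOrder:
    genome_id: str
    order: list[tuple[str, int]]  # (cluster_id, sign in {+1, -1})
    circular: bool = True

    def __post_init__(self) -> None:
        ids = [c for c, _ in self.order]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"gene order of {self.genome_id} repeats a cluster")


@dataclass
class PairSupportEdge:
    cluster_a: str
    cluster_b: str
    support: int
    co_present: int

    @property
    def passes(self) -> bool:  # set by build_distance_graph via min_frac
        return self._passes

    _passes: bool = field(default=False, repr=False)


def build_gene_orders(
    world: World, cluster_ids: Optional[list[str]] = None
) -> dict[str, GeneOrder]:
    """Per-genome signed order of resolved persistent orthologs (chromosome only)."""
    ids = cluster_ids if cluster_ids is not None else list(world.clusters)
    orders: dict[str, GeneOrder] = {}
    for genome_id, genome in world.genomes.items():
        entries: list[tuple[int, str, int]] = []
        for cluster_id in ids:
            cluster = world.clusters[cluster_id]
            resolved = cluster.resolved_ortholog or {
                g: m[0] for g, m in cluster.members.items() if len(m) == 1
            }
            gene_id = resolved.get(genome_id)
            if gene_id is None:
                continue
            gene = world.genes[gene_id]
            if gene.replicon is not Replicon.CHROMOSOME:
                continue
            sign = 1 if gene.strand.value == "+" else -1
            entries.append((gene.start_bp, cluster_id, sign))
        entries.sort()
        orders[genome_id] = GeneOrder(
            genome_id=genome_id,
            order=[(c, s) for _, c, s in entries],
            circular=(genome.topology.value == "circular"),
        )
    return orders


def build_distance_graph(
    world: World,
    cluster_ids: list[str],
    d_max: int = 500,
    min_frac: float = 0.5,
    denominator: str = "co_present",
) -> tuple[list[PairSupportEdge], list[set[str]]]:
    """Conserved-proximity graph over persistent clusters.

    An edge joins two clusters when, in at least ``min_frac`` of the genomes
    (denominator: genomes containing both, or all genomes), their resolved
    orthologs lie within ``d_max`` intergenic bp. Connected components of the
    passing edges are the conserved gene clusters (operon-like blocks).
    """
    from .geometry import pair_distance

    resolved_maps = {}
    for cid in cluster_ids:
        cluster = world.clusters[cid]
        resolved_maps[cid] = cluster.resolved_ortholog or {
            g: m[0] for g, m in cluster.members.items() if len(m) == 1
        }
    support: dict[tuple[str, str], int] = {}
    presence: dict[str, set[str]] = {
        cid: set(rm) for cid, rm in resolved_maps.items()
    }
    # Scan each genome once: sort genes by position, compare near neighbours.
    for genome_id, genome in world.genomes.items():
        located = []
        for cid in cluster_ids:
            gene_id = resolved_maps[cid].get(genome_id)
            if gene_id is None:
                continue
            gene = world.genes[gene_id]
            if gene.replicon is not Replicon.CHROMOSOME:
                continue
            located.append((gene.start_bp, cid, gene))
        located.sort()
        n = len(located)
        L = genome.size_bp
        candidates: set[tuple[int, int]] = set()
        for i in range(n):
            gene_i = located[i][2]
            end_i = gene_i.end_bp + (L if gene_i.wraps_origin else 0)
            for j in range(i + 1, n):
                if located[j][0] - end_i - 1 > d_max:
                    break
                candidates.add((i, j))
        if genome.topology.value == "circular" and n > 1:
            # pairs spanning the origin: late genes vs early genes
            for i in range(n - 1, 0, -1):
                gene_i = located[i][2]
                end_i = gene_i.end_bp + (L if gene_i.wraps_origin else 0)
                if located[0][0] + L - end_i - 1 > d_max:
                    break
                for j in range(i):
                    if located[j][0] + L - end_i - 1 > d_max:
                        break
                    candidates.add((j, i))
        for i, j in candidates:
            d = pair_distance(located[i][2], located[j][2], genome)
            if d <= d_max:
                key = tuple(sorted((located[i][1], located[j][1])))
                support[key] = support.get(key, 0) + 1
    edges: list[PairSupportEdge] = []
    graph = nx.Graph()
    graph.add_nodes_from(cluster_ids)
    n_genomes = len(world.genomes)
    for (ca, cb), sup in sorted(support.items()):
        co = len(presence[ca] & presence[cb])
        denom = co if denominator == "co_present" else n_genomes
        edge = PairSupportEdge(ca, cb, sup, co)
        edge._passes = denom > 0 and sup / denom >= min_frac
        edges.append(edge)
        if edge._passes:
            graph.add_edge(ca, cb)
    components = [set(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), sorted(c)[0]))
    return edges, components


def order_profile(
    reference_genome: str, world: World, cluster_ids: list[str]
) -> dict[str, list[Optional[float]]]:
    """Relative positions (start/L) of persistent genes in reference order.

    Rows are genomes; columns follow the reference genome's gene order.
    Genes missing from a genome appear as None gaps.
    """
    if reference_genome not in world.genomes:
        raise ValidationError(f"unknown reference genome {reference_genome}")
    orders = build_gene_orders(world, cluster_ids)
    ref_order = [c for c, _ in orders[reference_genome].order]
    resolved_maps = {}
    for cid in cluster_ids:
        cluster = world.clusters[cid]
        resolved_maps[cid] = cluster.resolved_ortholog or {
            g: m[0] for g, m in cluster.members.items() if len(m) == 1
        }
    profile: dict[str, list[Optional[float]]] = {}
    for genome_id, genome in world.genomes.items():
        row: list[Optional[float]] = []
        for cid in ref_order:
            gene_id = resolved_maps[cid].get(genome_id)
            if gene_id is None:
                row.append(None)
            else:
                row.append(world.genes[gene_id].start_bp / genome.size_bp)
        profile[genome_id] = row
    return profile


def _adjacency_set(order: list[int], circular: bool) -> set[tuple[int, int]]:
    """Canonical signed adjacencies; (a,b) and (-b,-a) are the same adjacency."""
    pairs = list(zip(order, order[1:]))
    if circular and len(order) > 1:
        pairs.append((order[-1], order[0]))
    return {min((a, b), (-b, -a)) for a, b in pairs}


def breakpoint_distance(order_a: GeneOrder, order_b: GeneOrder) -> int:
    """Number of signed adjacencies of A (restricted to shared clusters)
    absent from B. Reversal of a whole circular order gives 0."""
    shared = {c for c, _ in order_a.order} & {c for c, _ in order_b.order}
    if len(shared) < 2:
        raise ValidationError("breakpoint distance needs >= 2 shared clusters")
    index = {c: i + 1 for i, c in enumerate(sorted(shared))}
    signed_a = [s * index[c] for c, s in order_a.order if c in shared]
    signed_b = [s * index[c] for c, s in order_b.order if c in shared]
    circular = order_a.circular and order_b.circular
    adj_a = _adjacency_set(signed_a, circular)
    adj_b = _adjacency_set(signed_b, circular)
    return len(adj_a - adj_b)


def random_inversions(
    order: list[int], k: int, rng: np.random.Generator
) -> list[int]:
    """Apply k random segment inversions (reverse + negate) to a signed order."""
    order = list(order)
    n = len(order)
    for _ in range(k):
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n))
        i, j = min(i, j), max(i, j)
        order[i : j + 1] = [-x for x in reversed(order[i : j + 1])]
    return order


@dataclass
class EdeCurve:
    n: int
    k_grid: np.ndarray
    expected_d: np.ndarray  # monotone nondecreasing, expected_d[0] == 0

    def estimate(self, observed: float) -> tuple[float, bool]:
        """Invert the curve; (estimate, saturated?)."""
        d = self.expected_d
        if observed <= 0:
            return 0.0, False
        if observed >= d[-1]:
            return float(self.k_grid[-1]), True
        # first index where expected_d exceeds observed, linear interpolation
        hi = int(np.searchsorted(d, observed, side="left"))
        lo = hi - 1
        while d[hi] == d[lo] and hi + 1 < len(d):
            hi += 1
        if d[hi] == d[lo]:
            return float(self.k_grid[lo]), False
        t = (observed - d[lo]) / (d[hi] - d[lo])
        return float(self.k_grid[lo] + t * (self.k_grid[hi] - self.k_grid[lo])), False


def ede_calibrate(
    n: int,
    reps: int = 200,
    seed: int = 0,
    k_grid: Optional[list[int]] = None,
    base_distance: Optional[Callable[[list[int], bool], int]] = None,
) -> EdeCurve:
    """Expected observed distance as a function of true inversion count.

    ``base_distance`` maps a perturbed signed circular order to an observed
    distance from the identity (default: breakpoint distance); the hook lets
    callers swap in another base rearrangement measure.
    """
    if n < 10:
        raise ValidationError("calibration needs >= 10 markers")
    if reps < 100:
        raise ValidationError("calibration needs >= 100 replicates")
    if k_grid is None:
        dense = list(range(0, min(2 * n, 40)))
        sparse = list(range(min(2 * n, 40), 3 * n + 1, max(1, n // 10)))
        k_grid = sorted(set(dense + sparse))
    rng = np.random.default_rng(seed)
    identity = list(range(1, n + 1))
    ident_order = GeneOrder("identity", [(str(i), 1) for i in identity])
    names = [str(i) for i in identity]

    def observed(perturbed: list[int]) -> int:
        if base_distance is not None:
            return base_distance(perturbed, True)
        order = GeneOrder(
            "q", [(names[abs(x) - 1], 1 if x > 0 else -1) for x in perturbed]
        )
        return breakpoint_distance(order, ident_order)

    means = []
    for k in k_grid:
        if k == 0:
            means.append(0.0)
            continue
        total = 0
        for _ in range(reps):
            total += observed(random_inversions(identity, k, rng))
        means.append(total / reps)
    expected = np.maximum.accumulate(np.asarray(means, dtype=float))
    return EdeCurve(n=n, k_grid=np.asarray(k_grid, dtype=float), expected_d=expected)


def ede_distance(
    order_a: GeneOrder, order_b: GeneOrder, curve: EdeCurve
) -> tuple[float, bool]:
    """Estimated true inversion count between two gene orders."""
    return curve.estimate(float(breakpoint_distance(order_a, order_b)))


def ede_distance_matrix(
    orders: dict[str, GeneOrder], curve: EdeCurve
) -> DistanceMatrix:
    """Symmetrized estimator matrix over all genome pairs."""
    labels = sorted(orders)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij, _ = ede_distance(orders[labels[i]], orders[labels[j]], curve)
            dji, _ = ede_distance(orders[labels[j]], orders[labels[i]], curve)
            values[i, j] = values[j, i] = (dij + dji) / 2
    return DistanceMatrix(labels, values)


def nj_tree(dist: DistanceMatrix):
    """Neighbour-joining tree (skbio TreeNode) from a distance matrix.

    Negative branch lengths are clamped to zero with the difference moved to
    the sibling branch (the standard adjustment).
    """
    if len(dist) < 3:
        raise ValidationError("neighbour joining needs >= 3 labels")
    return skbio_nj(SkbioDM(dist.values, dist.labels), neg_as_zero=True)


def nj_newick(dist: DistanceMatrix) -> str:
    tree = nj_tree(dist)
    newick = str(tree).strip()
    if not newick.endswith(";"):
        newick += ";"
    return newick


def order_vs_sequence_correlation(
    order_matrix: DistanceMatrix, seq_matrix: DistanceMatrix
) -> tuple[float, int]:
    """Pearson correlation between two distance matrices' upper triangles."""
    if order_matrix.labels != seq_matrix.labels:
        raise ValidationError("label sets differ")
    _, a = order_matrix.upper_triangle()
    _, b = seq_matrix.upper_triangle()
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        import warnings

        warnings.warn("correlation undefined (constant matrix)", stacklevel=2)
        return float("nan"), int(len(a))
    r = float(np.corrcoef(a, b)[0, 1])
    return r, int(len(a))
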