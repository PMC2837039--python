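"""Class-wise interaction counting and pathway sharing with permutation nulls.

Clusters carry one of three operon-preference classes — R (ribosomal), S
(strong operon), W (weak operon). Observed counts of interactions (or of
shared-pathway cluster pairs) per unordered class pair are compared against a
null in which class labels are shuffled over the nodes while the graph
topology and the class sizes are preserved. One-sided overrepresentation
p-values are reported as the raw fraction of null counts >= observed (so 0
and 1 are attainable); a (k+1)/(n+1)-corrected value is emitted alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import InteractionRecord, PathwayRecord, ValidationError

__all__ = [
    "ClassCountResult",
    "count_class_interactions",
    "permutation_test_interactions",
    "interactions_per_protein",
    "pathway_sharing_test",
    "pathways_per_cluster",
]


@dataclass
class ClassCountResult:
    class_pair: tuple[str, str]
    observed: int
    null_mean: float
    null_sd: float
    p_value: float  # raw k / n_perm
    p_value_corrected: float  # (k + 1) / (n_perm + 1)


def _dedupe(edges: list[InteractionRecord]) -> list[InteractionRecord]:
    return sorted(set(InteractionRecord.make(e.protein_a, e.protein_b) for e in edges),
                  key=lambda e: (e.protein_a, e.protein_b))


def count_class_interactions(
    edges: list[InteractionRecord],
    labels: dict[str, str],
    include_self: bool = False,
) -> dict[tuple[str, str], int]:
    """Edge count per unordered class pair.

    Edges with an unlabelled endpoint are dropped; self edges (a protein with
    itself) are counted only when ``include_self`` is set.
    """
    if not labels:
        raise ValidationError("empty label map")
    counts: dict[tuple[str, str], int] = {}
    classes = sorted(set(labels.values()))
    for ca, cb in itertools.combinations_with_replacement(classes, 2):
        counts[(ca, cb)] = 0
    for edge in _dedupe(edges):
        if edge.is_self and not include_self:
            continue
        la = labels.get(edge.protein_a)
        lb = labels.get(edge.protein_b)
        if la is None or lb is None:
            continue
        counts[tuple(sorted((la, lb)))] += 1
    return counts


def _edge_index_arrays(
    edges: list[InteractionRecord],
    labels: dict[str, str],
    include_self: bool,
) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    nodes = sorted(labels)
    node_index = {n: i for i, n in enumerate(nodes)}
    ia, ib = [], []
    for edge in _dedupe(edges):
        if edge.is_self and not include_self:
            continue
        if edge.protein_a in node_index and edge.protein_b in node_index:
            ia.append(node_index[edge.protein_a])
            ib.append(node_index[edge.protein_b])
    classes = sorted(set(labels.values()))
    return nodes, np.asarray(ia, dtype=int), np.asarray(ib, dtype=int), classes


def permutation_test_interactions(
    edges: list[InteractionRecord],
    labels: dict[str, str],
    n_perm: int = 10000,
    seed: int = 0,
    include_self: bool = False,
) -> dict[tuple[str, str], ClassCountResult]:
    """Permutation null for class-pair interaction counts.

    Class labels are permuted over the nodes (class sizes preserved, topology
    fixed); counts are recomputed per permutation.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    nodes, ia, ib, classes = _edge_index_arrays(edges, labels, include_self)
    k = len(classes)
    class_code = {c: i for i, c in enumerate(classes)}
    codes = np.asarray([class_code[labels[n]] for n in nodes], dtype=int)
    rng = np.random.default_rng(seed)

    def pair_counts(lab: np.ndarray) -> np.ndarray:
        la, lb = lab[ia], lab[ib]
        lo = np.minimum(la, lb)
        hi = np.maximum(la, lb)
        flat = lo * k + hi
        return np.bincount(flat, minlength=k * k)

    observed = pair_counts(codes)
    null = np.empty((n_perm, k * k), dtype=int)
    for p in range(n_perm):
        null[p] = pair_counts(rng.permutation(codes))
    results: dict[tuple[str, str], ClassCountResult] = {}
    for i in range(k):
        for j in range(i, k):
            flat = i * k + j
            obs = int(observed[flat])
            col = null[:, flat]
            ge = int(np.sum(col >= obs))
            results[(classes[i], classes[j])] = ClassCountResult(
                class_pair=(classes[i], classes[j]),
                observed=obs,
                null_mean=float(col.mean()),
                null_sd=float(col.std()),
                p_value=ge / n_perm,
                p_value_corrected=(ge + 1) / (n_perm + 1),
            )
    return results


def interactions_per_protein(
    edges: list[InteractionRecord],
    labels: dict[str, str],
    exclude_class: str | None = None,
) -> dict[str, float]:
    """Mean number of distinct interaction partners per node, by class.

    ``exclude_class`` removes that class's nodes (and all their edges) before
    counting — the with/without-ribosomal-proteins variant.
    """
    active = {
        n: c for n, c in labels.items() if exclude_class is None or c != exclude_class
    }
    partners: dict[str, set[str]] = {n: set() for n in active}
    for edge in _dedupe(edges):
        a, b = edge.protein_a, edge.protein_b
        if a not in active or b not in active or a == b:
            continue
        partners[a].add(b)
        partners[b].add(a)
    sums: dict[str, list[int]] = {}
    for node, cls in active.items():
        sums.setdefault(cls, []).append(len(partners[node]))
    return {cls: float(np.mean(v)) for cls, v in sorted(sums.items())}


def _sharing_pairs(
    memberships: list[PathwayRecord],
) -> tuple[list[str], list[tuple[str, str]]]:
    """Clusters in the pair universe and the unordered sharing pairs.

    A cluster enters the universe only if it shares at least one pathway with
    some other cluster.
    """
    by_pathway: dict[str, set[str]] = {}
    for rec in memberships:
        by_pathway.setdefault(rec.pathway_id, set()).add(rec.cluster_id)
    pairs: set[tuple[str, str]] = set()
    for members in by_pathway.values():
        for a, b in itertools.combinations(sorted(members), 2):
            pairs.add((a, b))
    universe = sorted({c for pair in pairs for c in pair})
    return universe, sorted(pairs)


def pathway_sharing_test(
    memberships: list[PathwayRecord],
    labels: dict[str, str],
    n_perm: int = 10000,
    seed: int = 0,
) -> dict[tuple[str, str], ClassCountResult]:
    """Class-pair counts of pathway-sharing cluster pairs, with permutation p.

    The pair universe is restricted to clusters sharing >= 1 pathway with at
    least one other cluster; labels are shuffled over that universe.
    """
    if not memberships:
        raise ValidationError("empty pathway membership list")
    universe, pairs = _sharing_pairs(memberships)
    universe = [c for c in universe if c in labels]
    pairs = [(a, b) for a, b in pairs if a in labels and b in labels]
    if len(universe) < 2:
        raise ValidationError("fewer than 2 labelled clusters share a pathway")
    index = {c: i for i, c in enumerate(universe)}
    ia = np.asarray([index[a] for a, _ in pairs], dtype=int)
    ib = np.asarray([index[b] for _, b in pairs], dtype=int)
    classes = sorted(set(labels[c] for c in universe))
    k = len(classes)
    class_code = {c: i for i, c in enumerate(classes)}
    codes = np.asarray([class_code[labels[c]] for c in universe], dtype=int)
    rng = np.random.default_rng(seed)

    def pair_counts(lab: np.ndarray) -> np.ndarray:
        lo = np.minimum(lab[ia], lab[ib])
        hi = np.maximum(lab[ia], lab[ib])
        return np.bincount(lo * k + hi, minlength=k * k)

    observed = pair_counts(codes)
    null = np.empty((n_perm, k * k), dtype=int)
    for p in range(n_perm):
        null[p] = pair_counts(rng.permutation(codes))
    results: dict[tuple[str, str], ClassCountResult] = {}
    for i in range(k):
        for j in range(i, k):
            flat = i * k + j
            obs = int(observed[flat])
            col = null[:, flat]
            ge = int(np.sum(col >= obs))
            results[(classes[i], classes[j])] = ClassCountResult(
                class_pair=(classes[i], classes[j]),
                observed=obs,
                null_mean=float(col.mean()),
                null_sd=float(col.std()),
                p_value=ge / n_perm,
                p_value_corrected=(ge + 1) / (n_perm + 1),
            )
    return results


def pathways_per_cluster(
    memberships: list[PathwayRecord],
    labels: dict[str, str],
) -> dict[str, dict]:
    """Per-class histogram and mean of pathway counts per cluster."""
    counts: dict[str, int] = {}
    for rec in memberships:
        counts[rec.cluster_id] = counts.get(rec.cluster_id, 0) + 1
    out: dict[str, dict] = {}
    for cls in sorted(set(labels.values())):
        values = [n for c, n in counts.items() if labels.get(c) == cls]
        hist: dict[int, int] = {}
        for v in values:
            hist[v] = hist.get(v, 0) + 1
        out[cls] = {
            "histogram": dict(sorted(hist.items())),
            "mean": float(np.mean(values)) if values else float("nan"),
            "n": len(values),
        }
    return out
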