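"""End-to-end orchestration of all analysis stages.

Stage order: resolve -> classify -> geometry -> order -> operon -> rates ->
network. A single global seed fans out to per-stage seeds by stable hashing
(CRC32 of the stage name), so toggling one stage never perturbs another's
randomness. Every report is stamped with the seed and a hash of the config.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import geometry, gene_order, networks, operons, ortholog, persistence
from . import evolution
from .io import write_report
from .model import Category, ValidationError, World
from .ortholog import UnscorableError

logger = logging.getLogger("persistome")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (seed ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    persistence_min: float = 0.90
    recent_dup_identity: float = 80.0
    gap_fraction: float = 0.10
    operon_strong: float = 0.80
    d_max: int = 500
    min_frac: float = 0.50
    edge_denominator: str = "co_present"  # or "all"
    regular_ratio: float = 0.10
    spacing_max_pairs: int = 2000
    n_perm: int = 10000
    ede_reps: int = 200
    scoredist_cap: float = 1000.0
    exclude_fused_mixed: bool = True
    seed: int = 0
    stages: tuple[str, ...] = (
        "resolve", "classify", "geometry", "order", "operon", "rates", "network",
    )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    config: PipelineConfig
    world: Optional[World] = None  # working copy with resolved/pruned clusters
    final_ids: list[str] = field(default_factory=list)
    categories: dict[str, Category] = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)  # cluster -> OperonProfile
    strength_labels: dict[str, str] = field(default_factory=dict)
    class_labels: dict[str, str] = field(default_factory=dict)  # R/S/W
    ribosomal_ids: set[str] = field(default_factory=set)
    rates: dict = field(default_factory=dict)  # cluster -> ClusterRate
    tables: dict = field(default_factory=dict)  # report payloads
    ede_matrix: Optional[object] = None
    report_paths: dict = field(default_factory=dict)


def _within_genome_identities(world: World) -> dict[frozenset, float]:
    identities: dict[frozenset, float] = {}
    for query, hit_list in world.hits.items():
        q = world.genes.get(query)
        if q is None:
            continue
        for hit in hit_list:
            s = world.genes.get(hit.subject_gene_id)
            if s is None or s.genome_id != q.genome_id or query == hit.subject_gene_id:
                continue
            key = frozenset((query, hit.subject_gene_id))
            identities[key] = max(identities.get(key, 0.0), hit.pct_identity)
    return identities


def run_pipeline(
    world: World,
    config: PipelineConfig = PipelineConfig(),
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    # Work on a copy of the cluster set: stages refine resolution and prune
    # members, and the caller's world must stay untouched.
    world = dataclasses.replace(world, clusters=copy.deepcopy(world.clusters))
    result = PipelineResult(config=config, world=world)
    n_genomes = len(world.genomes)
    thresholds = persistence.ClassificationThresholds(
        persistence_min=config.persistence_min,
        recent_dup_identity=config.recent_dup_identity,
    )
    timings: dict[str, float] = {}

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    # ---- resolve ----------------------------------------------------------
    t0 = time.perf_counter()
    if stage_enabled("resolve"):
        for cluster in world.clusters.values():
            if not cluster.duplicated_genomes():
                cluster.resolved_ortholog = {
                    g: m[0] for g, m in cluster.members.items() if len(m) == 1
                }
                continue
            try:
                ortholog.resolve_duplicates(
                    cluster, world.hits, gap_fraction=config.gap_fraction
                )
            except UnscorableError as exc:
                cluster.category = Category.EXCLUDED
                cluster.excluded_reason = str(exc)
        timings["resolve"] = time.perf_counter() - t0
        logger.info("resolve: %d clusters", len(world.clusters))

    # ---- classify ---------------------------------------------------------
    t0 = time.perf_counter()
    if stage_enabled("classify"):
        # persistence pre-filter
        candidates = []
        for cid, cluster in world.clusters.items():
            frac, persistent = persistence.persistence_fraction(
                cluster, n_genomes, config.persistence_min
            )
            cluster.persistence_fraction = frac
            if persistent:
                candidates.append(cid)
        persistent_ids = set(candidates)
        cluster_of_gene = {
            gene: cid
            for cid, cluster in world.clusters.items()
            for gene in cluster.all_gene_ids()
        }
        identities = _within_genome_identities(world)
        for cid in candidates:
            cluster = world.clusters[cid]
            if cluster.category is Category.EXCLUDED:
                continue
            fusion_cat, _ = persistence.classify_fusion(
                cluster, world.hits, cluster_of_gene, persistent_ids, thresholds
            )
            if fusion_cat is not None:
                cluster.category = fusion_cat
            else:
                cluster.category = persistence.classify_copy_number(
                    cluster, identities, config.recent_dup_identity
                )
        final = persistence.finalize_set(world, thresholds, candidates)
        result.final_ids = sorted(final.clusters)
        result.categories = {
            cid: final.clusters[cid].category for cid in result.final_ids
        }
        # carry pruned members/resolution into the working cluster set
        for cid, pruned in final.clusters.items():
            world.clusters[cid].members = pruned.members
            world.clusters[cid].resolved_ortholog = pruned.resolved_ortholog
            world.clusters[cid].persistence_fraction = pruned.persistence_fraction
        result.tables["classification"] = (
            ["cluster_id", "persistence_fraction", "category", "n_genomes",
             "excluded_reason"],
            [
                [
                    cid,
                    world.clusters[cid].persistence_fraction,
                    world.clusters[cid].category.value
                    if world.clusters[cid].category
                    else "-",
                    len(world.clusters[cid].genomes_present()),
                    "-",
                ]
                for cid in result.final_ids
            ]
            + [[cid, "-", "dropped", "-", reason] for cid, reason in
               sorted(final.dropped.items())],
        )
        result.tables["n_final_clusters"] = len(result.final_ids)
        result.tables["category_counts"] = final.counts
        timings["classify"] = time.perf_counter() - t0
        logger.info("classify: %d final clusters", len(result.final_ids))

    stat_ids = [
        cid
        for cid in result.final_ids
        if not (
            config.exclude_fused_mixed
            and result.categories.get(cid) in (Category.FUSED, Category.MIXED)
        )
    ]

    # ---- geometry ---------------------------------------------------------
    t0 = time.perf_counter()
    if stage_enabled("geometry") and result.final_ids:
        rows = []
        for genome_id, genome in sorted(world.genomes.items()):
            genes = []
            for cid in result.final_ids:
                resolved = world.clusters[cid].resolved_ortholog or {}
                gid = resolved.get(genome_id)
                if gid is not None and world.genes[gid].replicon.value == "chromosome":
                    genes.append(world.genes[gid])
            if not genes:
                continue
            rows.append(
                [genome_id, len(genes), geometry.persistent_range(genome, genes)]
            )
        result.tables["range"] = (["genome_id", "n_persistent", "range_percent"], rows)
        rng = np.random.default_rng(stage_seed(config.seed, "geometry"))
        ids = stat_ids
        all_pairs = [
            (ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))
        ]
        if len(all_pairs) > config.spacing_max_pairs:
            take = rng.choice(len(all_pairs), config.spacing_max_pairs, replace=False)
            pairs = [all_pairs[int(t)] for t in sorted(take)]
        else:
            pairs = all_pairs
        n_regular = 0
        n_tested = 0
        for ca, cb in pairs:
            stat = geometry.med_mad_spacing(ca, cb, world, config.regular_ratio)
            if stat.verdict != "insufficient":
                n_tested += 1
                n_regular += stat.verdict == "regular"
        result.tables["spacing"] = {
            "pairs_tested": n_tested,
            "regular_pairs": n_regular,
        }
        timings["geometry"] = time.perf_counter() - t0

    # ---- order ------------------------------------------------------------
    if stage_enabled("order") and len(stat_ids) >= 10:
        t0 = time.perf_counter()
        orders = gene_order.build_gene_orders(world, stat_ids)
        edges, components = gene_order.build_distance_graph(
            world, stat_ids, config.d_max, config.min_frac, config.edge_denominator
        )
        result.tables["edges"] = (
            ["cluster_a", "cluster_b", "support", "co_present", "passes"],
            [[e.cluster_a, e.cluster_b, e.support, e.co_present, e.passes]
             for e in edges],
        )
        result.tables["components"] = (
            ["component", "size", "members"],
            [[i, len(c), ",".join(sorted(c))] for i, c in enumerate(components)],
        )
        n_markers = int(np.median([len(o.order) for o in orders.values()]))
        curve = gene_order.ede_calibrate(
            max(10, n_markers),
            reps=config.ede_reps,
            seed=stage_seed(config.seed, "ede"),
        )
        result.ede_matrix = gene_order.ede_distance_matrix(orders, curve)
        result.tables["ede_newick"] = gene_order.nj_newick(result.ede_matrix)
        if world.sequences:
            alignments: dict[str, dict[str, str]] = {}
            for cid in stat_ids:
                resolved = world.clusters[cid].resolved_ortholog or {}
                rows_al = {
                    g: world.sequences[gid]
                    for g, gid in resolved.items()
                    if gid in world.sequences
                }
                if len(rows_al) >= 2:
                    alignments[cid] = rows_al
            if alignments:
                seq_matrix = evolution.concatenated_distance_matrix(
                    alignments, sorted(world.genomes), cap=config.scoredist_cap
                )
                r, n_pairs = gene_order.order_vs_sequence_correlation(
                    result.ede_matrix, seq_matrix
                )
                result.tables["order_vs_sequence_r"] = {"r": r, "n_pairs": n_pairs}
                result.tables["sequence_newick"] = gene_order.nj_newick(seq_matrix)
        timings["order"] = time.perf_counter() - t0

    # ---- operon -----------------------------------------------------------
    if stage_enabled("operon") and result.final_ids:
        t0 = time.perf_counter()
        result.ribosomal_ids = {
            cid for cid in result.final_ids if world.cog_map.get(cid) == "J"
        }
        profiles = {}
        for cid in result.final_ids:
            try:
                profiles[cid] = operons.operon_profile(
                    world.clusters[cid],
                    world.operon_calls,
                    config.operon_strong,
                    result.ribosomal_ids,
                )
            except ValidationError:
                continue
        result.profiles = profiles
        result.strength_labels = {
            cid: p.strength for cid, p in profiles.items()
        }
        result.class_labels = {
            cid: (
                "R"
                if cid in result.ribosomal_ids
                else ("S" if p.strength == "strong" else "W")
            )
            for cid, p in profiles.items()
            if cid in stat_ids or cid in result.ribosomal_ids
        }
        result.tables["profiles"] = (
            ["cluster_id", "n_present", "n_in_operon", "fraction", "strength",
             "ribosomal"],
            [[p.cluster_id, p.n_present, p.n_in_operon, p.fraction, p.strength,
              p.ribo_flag] for p in profiles.values()],
        )
        occ_in = sum(p.n_in_operon for p in profiles.values())
        occ_all = sum(p.n_present for p in profiles.values())
        result.tables["operon_participation_percent"] = 100.0 * occ_in / max(1, occ_all)
        stat_profiles = {cid: profiles[cid] for cid in stat_ids if cid in profiles}
        fisher = operons.copy_number_operon_test(stat_profiles, result.categories)
        result.tables["copy_number_operon"] = {
            "table": fisher.table.tolist(),
            "odds_ratio": fisher.odds_ratio,
            "odds_ratio_cmle": fisher.odds_ratio_cmle,
            "p_value": fisher.p_value,
        }
        pair_res = operons.pair_composition_test(
            world, result.categories, set(stat_ids)
        )
        if pair_res is not None:
            result.tables["pair_composition"] = {
                "table": pair_res.table.tolist(),
                "odds_ratio": pair_res.odds_ratio,
                "odds_ratio_cmle": pair_res.odds_ratio_cmle,
                "p_value": pair_res.p_value,
            }
        result.tables["cog_operon_fraction"] = operons.category_operon_fractions(
            profiles, world.cog_map
        )
        dist = operons.category_distribution(result.final_ids, world.cog_map)
        result.tables["cog_distribution"] = (
            ["cog_class", "percent", "normalized_percent"],
            [[cat, v["percent"], v["normalized_percent"]] for cat, v in dist.items()],
        )
        timings["operon"] = time.perf_counter() - t0

    # ---- rates ------------------------------------------------------------
    if stage_enabled("rates") and result.profiles:
        t0 = time.perf_counter()
        rates = {}
        for cid in result.final_ids:
            rate = evolution.cluster_rate(world.clusters[cid], world.hits, world)
            if rate is not None:
                rates[cid] = rate
        result.rates = rates
        score_values = {c: r.mean_norm_bitscore for c, r in rates.items()}
        length_values = {c: r.median_protein_len for c, r in rates.items()}
        labels = result.class_labels
        result.tables["rates"] = (
            ["cluster_id", "mean_norm_bitscore", "n_pairs", "median_len", "group"],
            [[c, r.mean_norm_bitscore, r.n_pairs, r.median_protein_len,
              labels.get(c, "-")] for c, r in sorted(rates.items())],
        )
        result.tables["group_median_bitscore"] = evolution.group_summary(
            score_values, labels
        )
        nonribo = {c: v for c, v in score_values.items()
                   if labels.get(c) in ("S", "W")}
        if sum(1 for c in nonribo if labels[c] == "S") >= 2 and sum(
            1 for c in nonribo if labels[c] == "W"
        ) >= 2:
            comp = evolution.compare_groups(nonribo, labels, "S", "W", "median")
            result.tables["rate_strong_vs_weak"] = {
                "medians": comp.group_stats, "p_value": comp.p_value,
            }
            lengths_nonribo = {
                c: v for c, v in length_values.items() if labels.get(c) in ("S", "W")
            }
            comp_len = evolution.compare_groups(
                lengths_nonribo, labels, "S", "W", "mean"
            )
            result.tables["length_strong_vs_weak"] = {
                "means": comp_len.group_stats, "p_value": comp_len.p_value,
            }
        timings["rates"] = time.perf_counter() - t0

    # ---- network ----------------------------------------------------------
    if stage_enabled("network") and result.class_labels:
        t0 = time.perf_counter()
        labels = result.class_labels
        for include_self, tag in ((False, "no_self"), (True, "with_self")):
            perm = networks.permutation_test_interactions(
                world.interactions,
                labels,
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"interactions_{tag}"),
                include_self=include_self,
            )
            result.tables[f"interaction_classes_{tag}"] = (
                ["class_a", "class_b", "observed", "null_mean", "null_sd",
                 "p_value", "p_value_corrected"],
                [[r.class_pair[0], r.class_pair[1], r.observed, r.null_mean,
                  r.null_sd, r.p_value, r.p_value_corrected]
                 for r in perm.values()],
            )
        result.tables["partners_per_class"] = networks.interactions_per_protein(
            world.interactions, labels
        )
        result.tables["partners_per_class_no_ribo"] = (
            networks.interactions_per_protein(world.interactions, labels, "R")
        )
        if world.pathways:
            try:
                sharing = networks.pathway_sharing_test(
                    world.pathways,
                    labels,
                    n_perm=config.n_perm,
                    seed=stage_seed(config.seed, "pathways"),
                )
                result.tables["pathway_sharing"] = (
                    ["class_a", "class_b", "observed", "null_mean", "null_sd",
                     "p_value", "p_value_corrected"],
                    [[r.class_pair[0], r.class_pair[1], r.observed, r.null_mean,
                      r.null_sd, r.p_value, r.p_value_corrected]
                     for r in sharing.values()],
                )
            except ValidationError:
                pass
            result.tables["pathways_per_cluster"] = networks.pathways_per_cluster(
                world.pathways, labels
            )
        timings["network"] = time.perf_counter() - t0

    # wall-clock timings go to the log only, keeping reports reproducible
    result.tables["run_info"] = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_genomes": n_genomes,
        "n_clusters_in": len(world.clusters),
    }
    for name, seconds in timings.items():
        logger.info("stage %s: %.2fs", name, seconds)

    if out_dir is not None:
        result.report_paths = write_report(result.tables, out_dir)
    return result
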