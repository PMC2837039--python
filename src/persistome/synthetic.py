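"""Synthetic multi-genome worlds with planted ground truth.

The generator emulates the statistical structure of a large bacterial
comparative-genomics input bundle: near-universal gene families with dropout,
paralogous duplications (a fraction recent and highly identical), fused
proteins spanning two families, contiguous same-strand operon blocks with
heterogeneous per-family operon retention, per-family similarity levels
(normalised bit scores), class-biased protein-protein interactions and
pathway memberships, and a small plasmid component. Pairwise similarity
scores are generated directly rather than simulated from sequences; an
optional mode additionally emits mutated protein sequences (ungapped
alignments) for the sequence-distance stages.

Family classes
--------------
R : ribosomal-like — very high similarity, short proteins, strong operons.
S : strong operon — in an operon in ~95% of genomes, faster evolving,
    shorter proteins.
W : weak operon — in an operon in ~50% of genomes (or never, for solo
    genes), slower evolving, longer proteins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .model import (
    GeneRecord,
    Genome,
    HitRecord,
    InteractionRecord,
    OperonCall,
    OrthologCluster,
    PathwayRecord,
    Replicon,
    Strand,
    Topology,
    ValidationError,
    World,
)

__all__ = [
    "WorldSpec",
    "GroundTruth",
    "FamilyTruth",
    "generate_world",
    "emit_files",
    "ConfigurationError",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# COG functional classes with rough weights for non-ribosomal families.
COG_CLASSES = list("LFMOKHUICDEGQTRS")
COG_WEIGHTS = np.array([13, 8, 7, 5, 5, 4, 4, 3, 3, 2, 2, 2, 1, 1, 2, 2], dtype=float)


class ConfigurationError(ValueError):
    """The requested world cannot be laid out (e.g. genes exceed genome size)."""


@dataclass
class WorldSpec:
    """Parameters of a synthetic world. Probabilities are per genome/family."""

    n_genomes: int = 24
    genome_size_bp: int = 1_600_000
    circular_fraction: float = 109 / 113
    plasmid_fraction: float = 0.25
    plasmid_size_bp: int = 120_000
    plasmid_gene_prob: float = 0.01  # present family member lands on the plasmid

    n_families: int = 120
    n_background_families: int = 20
    presence_prob: float = 0.96
    background_presence_prob: float = 0.40

    # class mix (R, S, W), roughly the ribosomal / strong / weak split
    class_fractions: tuple[float, float, float] = (0.21, 0.34, 0.45)
    # ribosomal-like families are rarely duplicated; weak-operon ones often are
    duplicate_fraction_by_class: tuple[float, float, float] = (0.13, 0.50, 0.55)
    dup_genome_prob: float = 0.30
    recent_dup_fraction: float = 0.15
    recent_identity_range: tuple[float, float] = (85.0, 97.0)
    old_identity_range: tuple[float, float] = (35.0, 70.0)
    ortholog_rank_first_prob: float = 0.90

    n_fused_families: int = 2
    n_mixed_families: int = 2

    # operon layout
    block_size_range: tuple[int, int] = (2, 6)
    weak_in_block_prob: float = 0.70
    p_op_by_class: tuple[float, float, float] = (0.95, 0.95, 0.50)
    intra_block_gap: tuple[int, int] = (20, 200)
    # units are spread over the whole replicon; gaps between them are scaled
    # to fill the genome but never drop below this floor (so operon blocks
    # stay separated by far more than the clustering cutoff)
    min_inter_unit_gap: int = 600

    # similarity (mean normalised bit score per class) and noise
    s_by_class: tuple[float, float, float] = (0.97, 0.65, 0.79)
    s_family_sd: float = 0.06
    s_pair_noise_sd: float = 0.05
    s_divergence_decay: float = 0.25

    # protein lengths per class (aa)
    len_by_class: tuple[float, float, float] = (130.0, 335.0, 497.0)
    len_family_cv: float = 0.25
    len_genome_sd: float = 5.0
    min_protein_len: int = 60

    # gene-order divergence
    divergence_range: tuple[float, float] = (0.05, 0.50)
    inversions_per_divergence: float = 30.0

    # interactions: edge probability per class pair = rate * density.
    # Rates mirror the per-pair edge densities observed in curated
    # interaction data for this kind of gene set: weak-operon proteins
    # interact heavily with ribosomal proteins and in total have more
    # partners than strong-operon proteins.
    interaction_density: float = 0.02
    interaction_rates: dict = field(
        default_factory=lambda: {
            ("R", "R"): 3.0,
            ("R", "S"): 3.55,
            ("R", "W"): 6.8,
            ("S", "S"): 1.0,
            ("S", "W"): 1.0,
            ("W", "W"): 1.5,
        }
    )
    self_interaction_rate: tuple[float, float, float] = (0.07, 0.90, 0.85)

    # pathways: strong-operon clusters co-occur in tight pathway groups;
    # weak-operon clusters carry more memberships spread over many pathways
    s_pathway_group_size: int = 8
    s_extra_pathway_mean: float = 0.2
    w_pathway_mean_extra: float = 1.5
    w_pathway_pool_factor: float = 3.0

    full_pairwise_hits: bool = True
    emit_sequences: bool = False
    seq_len: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 3:
            raise ConfigurationError("n_genomes must be >= 3")
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        for p in (
            self.presence_prob,
            self.background_presence_prob,
            self.plasmid_fraction,
            self.circular_fraction,
            self.dup_genome_prob,
            self.ortholog_rank_first_prob,
        ):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"probability {p} outside [0, 1]")


@dataclass
class FamilyTruth:
    family_id: str
    cls: str  # R | S | W
    category: str  # singleton | duplicate | fused | mixed | background
    recent_dup: bool
    in_block: bool
    block_id: Optional[str]
    p_op: float
    s_f: float
    protein_len: float
    presence_prob: float


@dataclass
class GroundTruth:
    families: dict[str, FamilyTruth]
    true_ortholog: dict[str, dict[str, str]]  # family -> genome -> gene_id
    divergence: dict[str, float]  # genome -> planted divergence from reference
    inversions: dict[str, int]  # genome -> planted inversion count
    blocks: dict[str, list[str]]  # block_id -> family ids in reference order

    def class_labels(self) -> dict[str, str]:
        return {f: t.cls for f, t in self.families.items()}

    def strength_labels(self) -> dict[str, str]:
        """Planted strong/weak label from the planted operon retention."""
        return {
            f: ("strong" if t.p_op >= 0.8 else "weak")
            for f, t in self.families.items()
            if t.category != "background"
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "families": {f: asdict(t) for f, t in sorted(self.families.items())},
                "true_ortholog": {
                    f: dict(sorted(m.items()))
                    for f, m in sorted(self.true_ortholog.items())
                },
                "divergence": dict(sorted(self.divergence.items())),
                "inversions": dict(sorted(self.inversions.items())),
                "blocks": {b: list(f) for b, f in sorted(self.blocks.items())},
            },
            indent=1,
        )


def emit_files(world: World, out_dir) -> dict:
    """Write the world in exactly the formats ``load_world`` reads back."""
    from .io import write_world

    return write_world(world, out_dir)


def _choose_classes(rng: np.random.Generator, spec: WorldSpec) -> list[str]:
    fr, fs, fw = spec.class_fractions
    n = spec.n_families
    n_r = int(round(fr * n))
    n_s = int(round(fs * n))
    classes = ["R"] * n_r + ["S"] * n_s + ["W"] * (n - n_r - n_s)
    rng.shuffle(classes)
    return classes


def _apply_inversions(
    units: list[int], k: int, rng: np.random.Generator
) -> list[int]:
    units = list(units)
    n = len(units)
    for _ in range(k):
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n))
        i, j = min(i, j), max(i, j)
        units[i : j + 1] = [-u for u in reversed(units[i : j + 1])]
    return units


def generate_world(spec: WorldSpec) -> tuple[World, GroundTruth]:
    """Build a complete, validated World plus its planted ground truth.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    world = World()

    # --- genomes -----------------------------------------------------------
    genome_ids = [f"G{i:03d}" for i in range(spec.n_genomes)]
    n_linear = spec.n_genomes - int(round(spec.circular_fraction * spec.n_genomes))
    linear_set = set(genome_ids[-n_linear:]) if n_linear > 0 else set()
    has_plasmid = {
        g: bool(rng.random() < spec.plasmid_fraction) for g in genome_ids
    }
    for g in genome_ids:
        world.genomes[g] = Genome(
            genome_id=g,
            size_bp=spec.genome_size_bp,
            topology=Topology.LINEAR if g in linear_set else Topology.CIRCULAR,
            phylum=f"phylum{int(rng.integers(0, 13)):02d}",
        )

    # --- families ----------------------------------------------------------
    family_ids = [f"FAM{i:04d}" for i in range(spec.n_families)]
    classes = _choose_classes(rng, spec)
    dup_rate = dict(zip("RSW", spec.duplicate_fraction_by_class))
    dup_flags = np.array(
        [rng.random() < dup_rate[c] for c in classes], dtype=bool
    )
    recent_flags = np.array(
        [bool(d) and rng.random() < spec.recent_dup_fraction for d in dup_flags],
        dtype=bool,
    )

    # fused / mixed planting on non-ribosomal families with enough neighbours
    non_r = [i for i, c in enumerate(classes) if c != "R"]
    special = rng.choice(
        non_r, size=min(len(non_r), spec.n_fused_families + spec.n_mixed_families),
        replace=False,
    )
    fusion_category = {}
    for rank, idx in enumerate(special):
        fusion_category[idx] = "fused" if rank < spec.n_fused_families else "mixed"

    # per-family parameters
    s_means = {"R": spec.s_by_class[0], "S": spec.s_by_class[1], "W": spec.s_by_class[2]}
    len_means = {
        "R": spec.len_by_class[0],
        "S": spec.len_by_class[1],
        "W": spec.len_by_class[2],
    }
    p_op_cls = {"R": spec.p_op_by_class[0], "S": spec.p_op_by_class[1],
                "W": spec.p_op_by_class[2]}

    families: dict[str, FamilyTruth] = {}
    for i, fam in enumerate(family_ids):
        cls = classes[i]
        s_f = float(np.clip(rng.normal(s_means[cls], spec.s_family_sd), 0.2, 1.6))
        plen = max(
            spec.min_protein_len,
            float(rng.normal(len_means[cls], spec.len_family_cv * len_means[cls])),
        )
        category = fusion_category.get(i)
        if category is None:
            category = "duplicate" if (dup_flags[i] and not recent_flags[i]) else "singleton"
        families[fam] = FamilyTruth(
            family_id=fam,
            cls=cls,
            category=category,
            recent_dup=bool(recent_flags[i]),
            in_block=False,  # filled below
            block_id=None,
            p_op=0.0,
            s_f=s_f,
            protein_len=plen,
            presence_prob=spec.presence_prob,
        )

    background_ids = [f"BG{i:04d}" for i in range(spec.n_background_families)]
    for fam in background_ids:
        families[fam] = FamilyTruth(
            family_id=fam,
            cls="W",
            category="background",
            recent_dup=False,
            in_block=False,
            block_id=None,
            p_op=0.0,
            s_f=float(np.clip(rng.normal(0.5, 0.1), 0.2, 1.5)),
            protein_len=max(spec.min_protein_len, float(rng.normal(300, 80))),
            presence_prob=spec.background_presence_prob,
        )

    # --- operon blocks ------------------------------------------------------
    # R and S families always belong to blocks; W families join with
    # weak_in_block_prob. Blocks are runs over a shuffled family list.
    blockable = [
        f
        for f in family_ids
        if families[f].cls in ("R", "S")
        or rng.random() < spec.weak_in_block_prob
    ]
    shuffled = list(blockable)
    rng.shuffle(shuffled)
    blocks: dict[str, list[str]] = {}
    pos = 0
    b = 0
    while pos < len(shuffled):
        size = int(rng.integers(spec.block_size_range[0], spec.block_size_range[1] + 1))
        chunk = shuffled[pos : pos + size]
        if len(chunk) < 2:
            break  # a 1-gene remainder stays solo
        block_id = f"BLK{b:03d}"
        blocks[block_id] = chunk
        for f in chunk:
            families[f].in_block = True
            families[f].block_id = block_id
        pos += size
        b += 1
    for fam, truth in families.items():
        if truth.category == "background":
            continue
        truth.p_op = p_op_cls[truth.cls] if truth.in_block else 0.0

    # --- reference unit order ----------------------------------------------
    # Units: operon blocks (atomic) and solo families, in a fixed shuffled
    # reference order. Paralog and plasmid placement happens separately.
    solo = [f for f in list(family_ids) + background_ids if not families[f].in_block]
    unit_families: list[list[str]] = [blocks[b] for b in sorted(blocks)] + [
        [f] for f in solo
    ]
    unit_order = list(range(len(unit_families)))
    rng.shuffle(unit_order)
    reference_units = [u + 1 for u in unit_order]  # signed, 1-based

    # --- per-genome layout --------------------------------------------------
    true_ortholog: dict[str, dict[str, str]] = {f: {} for f in families}
    paralogs: dict[str, dict[str, list[str]]] = {f: {} for f in families}
    divergence: dict[str, float] = {}
    inversions: dict[str, int] = {}
    cluster_members: dict[str, dict[str, list[str]]] = {f: {} for f in families}
    operon_calls: dict[str, OperonCall] = {}
    gene_records: dict[str, GeneRecord] = {}

    lo_d, hi_d = spec.divergence_range
    for gi, g in enumerate(genome_ids):
        genome = world.genomes[g]
        if gi == 0:
            d_g = lo_d  # reference-like genome
        else:
            d_g = float(rng.uniform(lo_d, hi_d))
        divergence[g] = d_g
        k_inv = int(rng.poisson(spec.inversions_per_divergence * d_g))
        inversions[g] = k_inv
        genome_units = _apply_inversions(reference_units, k_inv, rng)

        present: dict[str, bool] = {}
        for fam, truth in families.items():
            present[fam] = bool(rng.random() < truth.presence_prob)

        counter = 0
        plasmid_genes: list[tuple[str, str, int]] = []  # (fam, gene_id, plen)

        def new_gene_id() -> str:
            nonlocal counter
            counter += 1
            return f"{g}_{counter:05d}"

        # First pass: decide what goes where (presence, plasmid, paralogs,
        # protein lengths, intra-block gaps). Layout items are (gene plans,
        # strand); each plan is (fam, gene_id, plen, gap_after, is_paralog).
        layout: list[tuple[list[tuple[str, str, int, int, bool]], Strand]] = []
        occupied = 0
        for signed_unit in genome_units:
            unit = unit_families[abs(signed_unit) - 1]
            sign = 1 if signed_unit > 0 else -1
            members = list(unit) if sign > 0 else list(reversed(unit))
            strand = Strand.PLUS if sign > 0 else Strand.MINUS
            plans: list[tuple[str, str, int, int, bool]] = []
            for fam in members:
                if not present[fam]:
                    continue
                truth = families[fam]
                plen = max(
                    spec.min_protein_len,
                    int(round(rng.normal(truth.protein_len, spec.len_genome_sd))),
                )
                on_plasmid = (
                    has_plasmid[g]
                    and truth.category != "background"
                    and rng.random() < spec.plasmid_gene_prob
                )
                if on_plasmid:
                    plasmid_genes.append((fam, new_gene_id(), plen))
                    continue
                gap_after = int(
                    rng.integers(spec.intra_block_gap[0], spec.intra_block_gap[1] + 1)
                )
                plans.append((fam, new_gene_id(), plen, gap_after, False))
                occupied += plen * 3 + 3 + gap_after
            if plans:
                layout.append((plans, strand))
        placed_fams = {p[0] for plans, _ in layout for p in plans}
        for fam in family_ids:
            truth = families[fam]
            if not present[fam]:
                continue
            if not (truth.category == "duplicate" or truth.recent_dup):
                continue
            if fam not in placed_fams:
                continue  # ortholog went to the plasmid or is absent
            if rng.random() >= spec.dup_genome_prob:
                continue
            plen = max(
                spec.min_protein_len,
                int(round(rng.normal(truth.protein_len, spec.len_genome_sd))),
            )
            strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
            layout.append(([(fam, new_gene_id(), plen, 0, True)], strand))
            occupied += plen * 3 + 3

        # Second pass: spread the units over the whole replicon. Inter-unit
        # gaps are random weights normalised to consume exactly the free
        # space, so the layout always fits and spans the genome.
        n_units_placed = len(layout)
        free = genome.size_bp - occupied - 200
        mean_gap = free / max(1, n_units_placed)
        if mean_gap < 2 * spec.min_inter_unit_gap:
            raise ConfigurationError(
                f"genome {g}: layout needs more than genome_size_bp "
                f"({genome.size_bp}); enlarge the genome or reduce families"
            )
        weights = rng.uniform(0.5, 1.5, size=max(1, n_units_placed))
        gaps = np.floor(weights / weights.sum() * free).astype(int)
        pos = 100
        for (plans, strand), inter_gap in zip(layout, gaps):
            for fam, gene_id, plen, gap_after, is_paralog in plans:
                truth = families[fam]
                glen = plen * 3 + 3
                if pos + glen >= genome.size_bp:
                    raise ConfigurationError(
                        f"genome {g}: layout overflows genome_size_bp"
                    )
                gene_records[gene_id] = GeneRecord(
                    genome_id=g,
                    gene_id=gene_id,
                    replicon=Replicon.CHROMOSOME,
                    start_bp=pos,
                    end_bp=pos + glen - 1,
                    strand=strand,
                    protein_len_aa=plen,
                    cluster_id=fam,
                )
                cluster_members[fam].setdefault(g, []).append(gene_id)
                if is_paralog:
                    paralogs[fam].setdefault(g, []).append(gene_id)
                    in_operon = False
                else:
                    true_ortholog[fam][g] = gene_id
                    in_operon = truth.in_block and bool(rng.random() < truth.p_op)
                operon_calls[gene_id] = OperonCall(
                    genome_id=g,
                    gene_id=gene_id,
                    in_operon=in_operon,
                    operon_id=f"{g}:{truth.block_id}" if in_operon else None,
                )
                pos += glen + gap_after
            pos += max(spec.min_inter_unit_gap, int(inter_gap))

        # plasmid genes
        ppos = 100
        for fam, gene_id, plen in plasmid_genes:
            glen = plen * 3 + 3
            if ppos + glen > spec.plasmid_size_bp:
                raise ConfigurationError(f"plasmid of {g} overflows")
            gene_records[gene_id] = GeneRecord(
                genome_id=g,
                gene_id=gene_id,
                replicon=Replicon.PLASMID,
                start_bp=ppos,
                end_bp=ppos + glen - 1,
                strand=Strand.PLUS,
                protein_len_aa=plen,
                cluster_id=fam,
            )
            true_ortholog[fam][g] = gene_id
            cluster_members[fam].setdefault(g, []).append(gene_id)
            operon_calls[gene_id] = OperonCall(
                genome_id=g, gene_id=gene_id, in_operon=False, operon_id=None
            )
            ppos += glen + 500

    world.genes = gene_records
    world.operon_calls = operon_calls
    for fam in sorted(families):
        members = {g: list(m) for g, m in sorted(cluster_members[fam].items())}
        if members:
            world.clusters[fam] = OrthologCluster(cluster_id=fam, members=members)

    # --- hits ---------------------------------------------------------------
    hits: dict[str, list[HitRecord]] = {}

    def add_hit(rec: HitRecord) -> None:
        hits.setdefault(rec.query_gene_id, []).append(rec)

    # (a) rank-score lists for duplicated genomes. Bit scores are drawn from
    # the same planted similarity model as the ortholog-pair scores below
    # (paralogs score lower), so the hit files are internally consistent;
    # e-values implement the planted rank order.
    rank_pairs: set[tuple[str, str]] = set()
    for fam in family_ids:
        truth = families[fam]
        dup_genomes = sorted(g for g, p in paralogs[fam].items() if p)
        if not dup_genomes:
            continue
        single_genomes = sorted(
            g
            for g in cluster_members[fam]
            if len(cluster_members[fam][g]) == 1
        )
        for g in dup_genomes:
            ortho = true_ortholog[fam][g]
            copies = [ortho] + paralogs[fam][g]
            for h in single_genomes:
                query = cluster_members[fam][h][0]
                order = list(copies)
                if rng.random() >= spec.ortholog_rank_first_prob:
                    # paralog outranks the true ortholog in this list
                    order = order[1:] + order[:1]
                decay = math.exp(
                    -spec.s_divergence_decay * (divergence[h] + divergence[g])
                )
                for r, subject in enumerate(order):
                    is_ortho = subject == ortho
                    level = truth.s_f * decay * (1.0 if is_ortho else 0.75)
                    norm = float(
                        np.clip(
                            level + rng.normal(0.0, spec.s_pair_noise_sd),
                            0.05, 2.5,
                        )
                    )
                    aln = min(
                        gene_records[query].protein_len_aa,
                        gene_records[subject].protein_len_aa,
                    )
                    rank_pairs.add((query, subject))
                    add_hit(
                        HitRecord(
                            query_gene_id=query,
                            subject_gene_id=subject,
                            e_value=10.0 ** (-(50 - 8 * r)),
                            bit_score=norm * aln,
                            aln_len=aln,
                            pct_identity=float(np.clip(norm * 80.0, 10.0, 100.0)),
                            q_start=1,
                            q_end=aln,
                        )
                    )
            # within-genome copy pair: identity decides recent-vs-old
            lo, hi = (
                spec.recent_identity_range
                if truth.recent_dup
                else spec.old_identity_range
            )
            for para in paralogs[fam][g]:
                ident = float(rng.uniform(lo, hi))
                plen = gene_records[ortho].protein_len_aa
                add_hit(
                    HitRecord(
                        query_gene_id=ortho,
                        subject_gene_id=para,
                        e_value=1e-30,
                        bit_score=ident * plen / 50.0,
                        aln_len=plen,
                        pct_identity=ident,
                        q_start=1,
                        q_end=plen,
                    )
                )

    # (b) pairwise ortholog-vs-ortholog scores (the evolutionary-rate proxy)
    if spec.full_pairwise_hits:
        for fam in sorted(families):
            truth = families[fam]
            members = sorted(true_ortholog[fam].items())
            for ai in range(len(members)):
                for bi in range(ai + 1, len(members)):
                    ga, gene_a = members[ai]
                    gb, gene_b = members[bi]
                    if (gene_a, gene_b) in rank_pairs or (gene_b, gene_a) in rank_pairs:
                        continue  # already scored via a ranking list
                    decay = math.exp(
                        -spec.s_divergence_decay * (divergence[ga] + divergence[gb])
                    )
                    score = truth.s_f * decay + rng.normal(0.0, spec.s_pair_noise_sd)
                    score = float(np.clip(score, 0.05, 2.5))
                    aln = min(
                        gene_records[gene_a].protein_len_aa,
                        gene_records[gene_b].protein_len_aa,
                    )
                    add_hit(
                        HitRecord(
                            query_gene_id=gene_a,
                            subject_gene_id=gene_b,
                            e_value=1e-20,
                            bit_score=score * aln,
                            aln_len=aln,
                            pct_identity=float(np.clip(score * 80.0, 10.0, 100.0)),
                            q_start=1,
                            q_end=aln,
                        )
                    )

    # (c) fusion evidence: flagged proteins hit two other persistent families
    other_pool = [
        f for f in family_ids if families[f].category in ("singleton", "duplicate")
    ]
    for idx, cat in sorted(fusion_category.items()):
        fam = family_ids[idx]
        frac = (
            float(rng.uniform(0.55, 0.90))
            if cat == "fused"
            else float(rng.uniform(0.15, 0.45))
        )
        targets = rng.choice(len(other_pool), size=2, replace=False)
        fam_a, fam_b = other_pool[int(targets[0])], other_pool[int(targets[1])]
        member_genes = sorted(true_ortholog[fam].values())
        n_fused = int(round(frac * len(member_genes)))
        for gene_id in member_genes[:n_fused]:
            plen = gene_records[gene_id].protein_len_aa
            half = max(2, plen // 2)
            for target_fam, (qs, qe) in (
                (fam_a, (1, half - 1)),
                (fam_b, (half + 1, plen)),
            ):
                target_map = true_ortholog[target_fam]
                if not target_map:
                    continue
                target_gene = sorted(target_map.values())[0]
                add_hit(
                    HitRecord(
                        query_gene_id=gene_id,
                        subject_gene_id=target_gene,
                        e_value=1e-25,
                        bit_score=90.0,
                        aln_len=max(1, qe - qs + 1),
                        pct_identity=45.0,
                        q_start=qs,
                        q_end=qe,
                    )
                )
    world.hits = {q: hits[q] for q in sorted(hits)}

    # --- interactions -------------------------------------------------------
    persistent_fams = [
        f for f in family_ids if families[f].category != "background"
    ]
    by_class: dict[str, list[str]] = {"R": [], "S": [], "W": []}
    for f in persistent_fams:
        by_class[families[f].cls].append(f)
    edges: set[tuple[str, str]] = set()
    for (ca, cb), rate in sorted(spec.interaction_rates.items()):
        p_edge = min(1.0, rate * spec.interaction_density)
        members_a, members_b = by_class[ca], by_class[cb]
        for i, fa in enumerate(members_a):
            start = i + 1 if ca == cb else 0
            for fb in members_b[start:]:
                if fa == fb:
                    continue
                if rng.random() < p_edge:
                    edges.add(tuple(sorted((fa, fb))))
    self_rate = {"R": spec.self_interaction_rate[0], "S": spec.self_interaction_rate[1],
                 "W": spec.self_interaction_rate[2]}
    for f in persistent_fams:
        if rng.random() < self_rate[families[f].cls]:
            edges.add((f, f))
    world.interactions = [InteractionRecord(a, b) for a, b in sorted(edges)]

    # --- pathways -----------------------------------------------------------
    pathway_records: list[PathwayRecord] = []
    for f in sorted(by_class["R"]):
        pathway_records.append(PathwayRecord(f, "PWY_RIBO"))
    s_sorted = sorted(by_class["S"])
    n_s_groups = max(1, math.ceil(len(s_sorted) / spec.s_pathway_group_size))
    for i, f in enumerate(s_sorted):
        group = i // spec.s_pathway_group_size
        pathway_records.append(PathwayRecord(f, f"PWY_S{group:03d}"))
        for _ in range(int(rng.poisson(spec.s_extra_pathway_mean))):
            extra = int(rng.integers(0, n_s_groups))
            pathway_records.append(PathwayRecord(f, f"PWY_S{extra:03d}"))
    w_sorted = sorted(by_class["W"])
    n_w_pathways = max(2, int(spec.w_pathway_pool_factor * len(w_sorted)))
    for f in w_sorted:
        n_pwy = 1 + int(rng.poisson(spec.w_pathway_mean_extra))
        chosen = rng.choice(n_w_pathways, size=min(n_pwy, n_w_pathways), replace=False)
        for c in sorted(int(x) for x in chosen):
            pathway_records.append(PathwayRecord(f, f"PWY_W{c:03d}"))
    world.pathways = sorted(set(pathway_records), key=lambda r: (r.cluster_id, r.pathway_id))

    # --- COG map ------------------------------------------------------------
    weights = COG_WEIGHTS / COG_WEIGHTS.sum()
    for f in sorted(families):
        if families[f].cls == "R":
            world.cog_map[f] = "J"
        else:
            world.cog_map[f] = COG_CLASSES[int(rng.choice(len(COG_CLASSES), p=weights))]

    # --- optional sequences (ungapped alignments per family) ----------------
    if spec.emit_sequences:
        for fam in sorted(families):
            ancestor = rng.choice(AMINO_ACIDS, size=spec.seq_len)
            for g, gene_id in sorted(true_ortholog[fam].items()):
                p_sub = min(0.8, divergence[g])
                mask = rng.random(spec.seq_len) < p_sub
                seq = ancestor.copy()
                if mask.any():
                    seq[mask] = rng.choice(AMINO_ACIDS, size=int(mask.sum()))
                world.sequences[gene_id] = "".join(seq)

    world.validate()
    truth = GroundTruth(
        families=families,
        true_ortholog={f: dict(sorted(m.items())) for f, m in true_ortholog.items()},
        divergence=divergence,
        inversions=inversions,
        blocks=blocks,
    )
    return world, truth
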