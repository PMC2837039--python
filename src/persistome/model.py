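"""Domain types shared by every pipeline stage.

Coordinates are 1-based inclusive (GFF3 convention). A gene on a circular
replicon may wrap the origin, in which case ``end_bp < start_bp``; geometry
operations must handle that case explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Topology",
    "Replicon",
    "Strand",
    "Category",
    "Genome",
    "GeneRecord",
    "HitRecord",
    "OrthologCluster",
    "OperonCall",
    "InteractionRecord",
    "PathwayRecord",
    "DistanceMatrix",
    "World",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when input data violates a documented invariant."""


class Topology(str, Enum):
    CIRCULAR = "circular"
    LINEAR = "linear"


class Replicon(str, Enum):
    CHROMOSOME = "chromosome"
    PLASMID = "plasmid"


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"


class Category(str, Enum):
    """Copy-number / fusion category of an ortholog cluster."""

    SINGLETON = "singleton"
    DUPLICATE = "duplicate"
    FUSED = "fused"
    MIXED = "mixed"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class Genome:
    genome_id: str
    size_bp: int
    topology: Topology = Topology.CIRCULAR
    phylum: Optional[str] = None

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValidationError(f"genome {self.genome_id}: size_bp must be positive")


@dataclass(frozen=True)
class GeneRecord:
    genome_id: str
    gene_id: str
    replicon: Replicon
    start_bp: int
    end_bp: int
    strand: Strand
    protein_len_aa: int
    cluster_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start_bp < 1:
            raise ValidationError(f"gene {self.gene_id}: start_bp must be >= 1")
        if self.protein_len_aa <= 0:
            raise ValidationError(f"gene {self.gene_id}: protein_len_aa must be positive")

    @property
    def wraps_origin(self) -> bool:
        """True for a gene crossing the origin of a circular replicon."""
        return self.end_bp < self.start_bp


@dataclass(frozen=True)
class HitRecord:
    """One row of a tabular homology search (BLAST outfmt-6 style)."""

    query_gene_id: str
    subject_gene_id: str
    e_value: float
    bit_score: float
    aln_len: int
    pct_identity: float = 100.0
    q_start: int = 0
    q_end: int = 0

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError("e_value must be nonnegative")
        if self.aln_len < 1:
            raise ValidationError("aln_len must be >= 1")


def sort_hits(hits: list[HitRecord]) -> list[HitRecord]:
    """Canonical hit-list order: ascending e-value, ties by descending bit score."""
    return sorted(hits, key=lambda h: (h.e_value, -h.bit_score))


@dataclass
class OrthologCluster:
    cluster_id: str
    members: dict[str, list[str]]  # genome_id -> gene ids
    persistence_fraction: float = 0.0
    category: Optional[Category] = None
    resolved_ortholog: Optional[dict[str, str]] = None
    excluded_reason: Optional[str] = None

    def genomes_present(self) -> list[str]:
        return [g for g, members in self.members.items() if members]

    def n_members(self) -> int:
        return sum(len(m) for m in self.members.values())

    def all_gene_ids(self) -> list[str]:
        return [g for members in self.members.values() for g in members]

    def duplicated_genomes(self) -> list[str]:
        return [g for g, members in self.members.items() if len(members) >= 2]


@dataclass(frozen=True)
class OperonCall:
    genome_id: str
    gene_id: str
    in_operon: bool
    operon_id: Optional[str] = None


@dataclass(frozen=True)
class InteractionRecord:
    """Undirected protein-protein interaction; endpoints are canonically sorted."""

    protein_a: str
    protein_b: str

    @property
    def is_self(self) -> bool:
        return self.protein_a == self.protein_b

    @staticmethod
    def make(a: str, b: str) -> "InteractionRecord":
        return InteractionRecord(*sorted((a, b)))


@dataclass(frozen=True)
class PathwayRecord:
    cluster_id: str
    pathway_id: str


class DistanceMatrix:
    """Labelled symmetric nonnegative matrix with zero diagonal."""

    def __init__(self, labels: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise ValidationError(f"matrix shape {values.shape} does not match {n} labels")
        if len(set(labels)) != n:
            raise ValidationError("duplicate labels")
        finite = np.isfinite(values)
        if not np.allclose(values[finite], values.T[finite]):
            raise ValidationError("matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValidationError("diagonal is not zero")
        if np.any(values[finite] < -1e-12):
            raise ValidationError("negative distances")
        self.labels = list(labels)
        self.values = values
        self._index = {lab: i for i, lab in enumerate(labels)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return self.labels == other.labels and np.allclose(
            self.values, other.values, equal_nan=True
        )

    def upper_triangle(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        """Off-diagonal entries (i < j) with their label pairs."""
        iu = np.triu_indices(len(self.labels), k=1)
        pairs = [(self.labels[i], self.labels[j]) for i, j in zip(*iu)]
        return pairs, self.values[iu]


@dataclass
class World:
    """Everything one analysis run consumes, cross-referenced and validated."""

    genomes: dict[str, Genome] = field(default_factory=dict)
    genes: dict[str, GeneRecord] = field(default_factory=dict)  # gene_id -> record
    hits: dict[str, list[HitRecord]] = field(default_factory=dict)  # query -> rows
    clusters: dict[str, OrthologCluster] = field(default_factory=dict)
    operon_calls: dict[str, OperonCall] = field(default_factory=dict)  # gene_id -> call
    interactions: list[InteractionRecord] = field(default_factory=list)
    pathways: list[PathwayRecord] = field(default_factory=list)
    cog_map: dict[str, str] = field(default_factory=dict)  # cluster_id -> COG class
    sequences: dict[str, str] = field(default_factory=dict)  # gene_id -> aligned/plain seq

    def genes_of(self, genome_id: str) -> list[GeneRecord]:
        return [g for g in self.genes.values() if g.genome_id == genome_id]

    def validate(self) -> None:
        """Check every cross-reference; raise listing all offending ids."""
        problems: list[str] = []
        for gene in self.genes.values():
            if gene.genome_id not in self.genomes:
                problems.append(f"gene {gene.gene_id}: unknown genome {gene.genome_id}")
            else:
                genome = self.genomes[gene.genome_id]
                if gene.end_bp > genome.size_bp or gene.start_bp > genome.size_bp:
                    problems.append(
                        f"gene {gene.gene_id}: coordinates exceed genome size"
                    )
                if gene.wraps_origin and genome.topology is not Topology.CIRCULAR:
                    problems.append(
                        f"gene {gene.gene_id}: wraps origin of a linear genome"
                    )
        for cluster in self.clusters.values():
            for genome_id, members in cluster.members.items():
                if genome_id not in self.genomes:
                    problems.append(
                        f"cluster {cluster.cluster_id}: unknown genome {genome_id}"
                    )
                for gene_id in members:
                    if gene_id not in self.genes:
                        problems.append(
                            f"cluster {cluster.cluster_id}: unknown gene {gene_id}"
                        )
        for gene_id in self.operon_calls:
            if gene_id not in self.genes:
                problems.append(f"operon call references unknown gene {gene_id}")
        if problems:
            raise ValidationError(
                "world validation failed:\n" + "\n".join(problems[:50])
            )
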