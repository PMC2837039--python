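"""Readers and writers for every external format the pipeline touches.

Formats
-------
- Gene tables: TSV with header ``genome_id gene_id replicon start end strand
  protein_len cluster_id``.
- Genome table: TSV ``genome_id size_bp topology phylum``.
- Homology hits: 12-column BLAST tabular (outfmt 6).
- Ortholog groups: OrthoMCL group format ``GROUPID: taxon|gene taxon|gene``.
- Operon calls: TSV ``genome_id gene_id in_operon operon_id``.
- Interactions: MITAB 2.5 (columns 1-2 used; ``db:accession`` ids).
- Pathways / COG map: 2-column TSV.
- Sequences: FASTA (aligned rows of equal length per family).

``load_world(write_world(w)) == w`` holds for every record type: floats are
serialised with ``repr`` so they round-trip bit-exactly.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Optional

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

__all__ = ["load_world", "write_world", "write_report", "ParseError"]

GENE_COLUMNS = [
    "genome_id", "gene_id", "replicon", "start", "end", "strand",
    "protein_len", "cluster_id",
]


class ParseError(ValueError):
    """Malformed row; message carries file and line number."""


def _rows(path: Path, expect_header: Optional[list[str]] = None):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and expect_header is not None:
                if fields != expect_header:
                    raise ParseError(
                        f"{path}:1: expected header {expect_header}, got {fields}"
                    )
                continue
            yield lineno, fields


def read_genomes(path: Path) -> dict[str, Genome]:
    genomes: dict[str, Genome] = {}
    for lineno, f in _rows(path, ["genome_id", "size_bp", "topology", "phylum"]):
        try:
            genomes[f[0]] = Genome(
                genome_id=f[0],
                size_bp=int(f[1]),
                topology=Topology(f[2]),
                phylum=f[3] if f[3] != "-" else None,
            )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genomes


def read_gene_table(path: Path) -> dict[str, GeneRecord]:
    genes: dict[str, GeneRecord] = {}
    for lineno, f in _rows(path, GENE_COLUMNS):
        try:
            record = GeneRecord(
                genome_id=f[0],
                gene_id=f[1],
                replicon=Replicon(f[2]),
                start_bp=int(f[3]),
                end_bp=int(f[4]),
                strand=Strand(f[5]),
                protein_len_aa=int(f[6]),
                cluster_id=f[7] if f[7] != "-" else None,
            )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if record.gene_id in genes:
            raise ValidationError(f"{path}:{lineno}: duplicate gene id {record.gene_id}")
        genes[record.gene_id] = record
    return genes


def read_hits(path: Path) -> dict[str, list[HitRecord]]:
    """12-column BLAST tabular: qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore."""
    hits: dict[str, list[HitRecord]] = {}
    for lineno, f in _rows(path):
        if len(f) != 12:
            raise ParseError(f"{path}:{lineno}: expected 12 columns, got {len(f)}")
        try:
            rec = HitRecord(
                query_gene_id=f[0],
                subject_gene_id=f[1],
                pct_identity=float(f[2]),
                aln_len=int(f[3]),
                q_start=int(f[6]),
                q_end=int(f[7]),
                e_value=float(f[10]),
                bit_score=float(f[11]),
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        hits.setdefault(rec.query_gene_id, []).append(rec)
    return hits


def read_groups(path: Path) -> dict[str, OrthologCluster]:
    """OrthoMCL group format: ``GROUPID: taxon|gene taxon|gene ...``"""
    clusters: dict[str, OrthologCluster] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ParseError(f"{path}:{lineno}: missing ':' separator")
            cluster_id, rest = line.split(":", 1)
            cluster_id = cluster_id.strip()
            members: dict[str, list[str]] = {}
            for token in rest.split():
                if "|" not in token:
                    raise ParseError(
                        f"{path}:{lineno}: member {token!r} is not taxon|gene"
                    )
                taxon, gene = token.split("|", 1)
                members.setdefault(taxon, []).append(gene)
            clusters[cluster_id] = OrthologCluster(
                cluster_id=cluster_id,
                members={g: m for g, m in sorted(members.items())},
            )
    return clusters


def read_operons(path: Path) -> dict[str, OperonCall]:
    calls: dict[str, OperonCall] = {}
    for lineno, f in _rows(path, ["genome_id", "gene_id", "in_operon", "operon_id"]):
        try:
            calls[f[1]] = OperonCall(
                genome_id=f[0],
                gene_id=f[1],
                in_operon={"1": True, "0": False}[f[2]],
                operon_id=f[3] if f[3] != "-" else None,
            )
        except (KeyError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: bad operon row") from exc
    return calls


def _strip_db(token: str) -> str:
    return token.split(":", 1)[1] if ":" in token else token


def read_mitab(path: Path) -> list[InteractionRecord]:
    """MITAB 2.5; only interactor columns 1-2 are used. Undirected duplicates
    (A-B and B-A) collapse to a single record."""
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: MITAB rows need >= 2 columns")
            a = _strip_db(fields[0])
            b = _strip_db(fields[1])
            edges.add(tuple(sorted((a, b))))
    return [InteractionRecord(a, b) for a, b in sorted(edges)]


def read_pathways(path: Path) -> list[PathwayRecord]:
    seen: set[tuple[str, str]] = set()
    for lineno, f in _rows(path, ["cluster_id", "pathway_id"]):
        seen.add((f[0], f[1]))
    return [PathwayRecord(c, p) for c, p in sorted(seen)]


def read_cog_map(path: Path) -> dict[str, str]:
    return {f[0]: f[1] for _, f in _rows(path, ["cluster_id", "cog_class"])}


def read_fasta(path: Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


FILES = {
    "genomes": "genomes.tsv",
    "genes": "genes.tsv",
    "hits": "hits.tsv",
    "groups": "groups.txt",
    "operons": "operons.tsv",
    "interactions": "interactions.mitab",
    "pathways": "pathways.tsv",
    "cog": "cog.tsv",
    "sequences": "sequences.fasta",
}


def load_world(directory: str | os.PathLike) -> World:
    """Load a world bundle from a directory and validate cross-references.

    genomes.tsv and genes.tsv are required; every other file is optional.
    """
    directory = Path(directory)
    world = World()
    world.genomes = read_genomes(directory / FILES["genomes"])
    world.genes = read_gene_table(directory / FILES["genes"])
    if (directory / FILES["hits"]).exists():
        world.hits = read_hits(directory / FILES["hits"])
    if (directory / FILES["groups"]).exists():
        world.clusters = read_groups(directory / FILES["groups"])
    if (directory / FILES["operons"]).exists():
        world.operon_calls = read_operons(directory / FILES["operons"])
    if (directory / FILES["interactions"]).exists():
        world.interactions = read_mitab(directory / FILES["interactions"])
    if (directory / FILES["pathways"]).exists():
        world.pathways = read_pathways(directory / FILES["pathways"])
    if (directory / FILES["cog"]).exists():
        world.cog_map = read_cog_map(directory / FILES["cog"])
    if (directory / FILES["sequences"]).exists():
        world.sequences = read_fasta(directory / FILES["sequences"])
    world.validate()
    return world


def write_world(world: World, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Emit the world in exactly the formats ``load_world`` reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    path = out / FILES["genomes"]
    with open(path, "w") as fh:
        fh.write("genome_id\tsize_bp\ttopology\tphylum\n")
        for g in sorted(world.genomes.values(), key=lambda x: x.genome_id):
            fh.write(
                f"{g.genome_id}\t{g.size_bp}\t{g.topology.value}\t{g.phylum or '-'}\n"
            )
    paths["genomes"] = path

    path = out / FILES["genes"]
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in sorted(
            world.genes.values(), key=lambda x: (x.genome_id, x.start_bp, x.gene_id)
        ):
            fh.write(
                f"{g.genome_id}\t{g.gene_id}\t{g.replicon.value}\t{g.start_bp}\t"
                f"{g.end_bp}\t{g.strand.value}\t{g.protein_len_aa}\t"
                f"{g.cluster_id or '-'}\n"
            )
    paths["genes"] = path

    if world.hits:
        path = out / FILES["hits"]
        with open(path, "w") as fh:
            for query in sorted(world.hits):
                for h in world.hits[query]:
                    fh.write(
                        f"{h.query_gene_id}\t{h.subject_gene_id}\t"
                        f"{h.pct_identity!r}\t{h.aln_len}\t0\t0\t"
                        f"{h.q_start}\t{h.q_end}\t1\t{h.aln_len}\t"
                        f"{h.e_value!r}\t{h.bit_score!r}\n"
                    )
        paths["hits"] = path

    if world.clusters:
        path = out / FILES["groups"]
        with open(path, "w") as fh:
            for cid in sorted(world.clusters):
                cluster = world.clusters[cid]
                tokens = [
                    f"{g}|{gene}"
                    for g in sorted(cluster.members)
                    for gene in cluster.members[g]
                ]
                fh.write(f"{cid}: " + " ".join(tokens) + "\n")
        paths["groups"] = path

    path = out / FILES["operons"]
    with open(path, "w") as fh:
        fh.write("genome_id\tgene_id\tin_operon\toperon_id\n")
        for gene_id in sorted(world.operon_calls):
            c = world.operon_calls[gene_id]
            fh.write(
                f"{c.genome_id}\t{c.gene_id}\t{int(c.in_operon)}\t"
                f"{c.operon_id or '-'}\n"
            )
    paths["operons"] = path

    path = out / FILES["interactions"]
    with open(path, "w") as fh:
        fh.write(
            "#ID(s) interactor A\tID(s) interactor B\t" + "\t".join(["-"] * 13) + "\n"
        )
        for e in sorted(world.interactions, key=lambda x: (x.protein_a, x.protein_b)):
            fh.write(
                f"db:{e.protein_a}\tdb:{e.protein_b}\t" + "\t".join(["-"] * 13) + "\n"
            )
    paths["interactions"] = path

    if world.pathways:
        path = out / FILES["pathways"]
        with open(path, "w") as fh:
            fh.write("cluster_id\tpathway_id\n")
            for rec in sorted(world.pathways, key=lambda r: (r.cluster_id, r.pathway_id)):
                fh.write(f"{rec.cluster_id}\t{rec.pathway_id}\n")
        paths["pathways"] = path

    if world.cog_map:
        path = out / FILES["cog"]
        with open(path, "w") as fh:
            fh.write("cluster_id\tcog_class\n")
            for cid in sorted(world.cog_map):
                fh.write(f"{cid}\t{world.cog_map[cid]}\n")
        paths["cog"] = path

    if world.sequences:
        path = out / FILES["sequences"]
        with open(path, "w") as fh:
            for gene_id in sorted(world.sequences):
                fh.write(f">{gene_id}\n{world.sequences[gene_id]}\n")
        paths["sequences"] = path

    return paths


def _fmt(value) -> str:
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, float):
        return f"{value:.12g}"
    if value is None:
        return "-"
    return str(value)


def write_tsv(path: Path, columns: list[str], rows: Iterable[Iterable]) -> None:
    """Deterministic TSV: fixed column order, 12 significant digits for reals."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_report(results: dict, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write pipeline results: TSV tables, JSON summary, Newick trees.

    ``results`` maps names to payloads: a (columns, rows) tuple becomes a TSV,
    a string ending in ';' becomes a .nwk file, everything else is collected
    into summary.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    summary: dict = {}
    for name in sorted(results):
        payload = results[name]
        if isinstance(payload, tuple) and len(payload) == 2:
            path = out / f"{name}.tsv"
            write_tsv(path, payload[0], payload[1])
            paths[name] = path
        elif isinstance(payload, str) and payload.rstrip().endswith(";"):
            path = out / f"{name}.nwk"
            path.write_text(payload.rstrip() + "\n")
            paths[name] = path
        else:
            summary[name] = payload
    path = out / "summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    paths["summary"] = path
    return paths
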