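# persistome

Analysis pipeline for **persistent bacterial genes** — gene families found in
nearly all bacterial genomes — and the relationship between their **operon
preference** and functional properties: evolutionary rate, protein length,
protein–protein interactions and metabolic-pathway sharing.

The package is aimed at comparative genomicists who have already run the
standard homology machinery (an all-vs-all protein search plus OrthoMCL-style
clustering, external operon predictions, interaction and pathway databases)
and want the downstream multi-genome analysis: resolving true orthologs among
paralogs, classifying families, and relating operon organisation to
evolutionary and network properties. A first-class synthetic-world generator
produces complete input bundles with planted ground truth, so the whole
pipeline is testable without downloading a single genome.

## The methods at the core

**Persistence.** A family (ortholog cluster) is *persistent* when it occurs
in at least 90% of the *N* genomes, i.e. in ≥ ⌈0.9 *N*⌉ of them. Plasmid-borne
members are removed (plasmid genes have no well-defined chromosomal
position), and persistence is re-evaluated afterwards.

**Ortholog vs paralog by rank scoring.** When genome *g* carries *k* ≥ 2
copies of a family, each single-copy member of the family contributes its
homology hit list. Within a list the *k* copies are ranked by order of
appearance (1 = first; an absent copy gets rank *k* + 1), and ranks are summed
into a total score *S* per copy. The copy with minimal *S* is the putative
ortholog, accepted only if the margin to the runner-up satisfies

    S₂ − S₁ ≥ ⌈0.1 · S_min⌉,   S_min = number of contributing lists,

otherwise the genome — and by default the whole cluster — is ambiguous and
excluded.

**Classification.** Clusters are *singletons* or *duplicates* (a paralog
> 80% identical to the kept copy counts as a recent duplication and is
collapsed); clusters where > 50% (10–50%) of member proteins carry
non-overlapping high-scoring alignments to two distinct persistent families
are *fused* (*mixed*) and excluded from the statistical stages.

**Operon preference.** With external per-gene operon calls, a cluster whose
resolved orthologs sit in an operon in ≥ 80% of called genomes is a *strong*
operon gene, otherwise *weak*; ribosomal-protein clusters form a third class.

**Rates and lengths.** The evolutionary-rate proxy per ortholog pair is the
search bit score normalised by alignment length (bits/column); cluster means
are compared between groups by their medians with a two-sided Mann–Whitney
rank-sum test. Sequence distances use Scoredist: with BLOSUM62 score σ,
expected random score σ_r and mean self-score σ_UL,
d = −ln((σ − σ_r)/(σ_UL − σ_r)) · 100 · 1.337, capped when the normalised
score is ≤ 0.

**Gene order.** A conserved-proximity graph joins clusters whose orthologs
lie within 500 intergenic bp in ≥ 50% of co-containing genomes (connected
components ≈ operon-like blocks). Genome-scale order divergence is the signed
circular breakpoint distance, converted to an estimated number of inversions
by inverting a simulation-calibrated curve E[d | k inversions]; trees come
from neighbour joining.

**Networks.** Interactions and pathway co-memberships are counted per class
pair (R/S/W) and tested against a permutation null that shuffles class
labels over nodes (10,000 permutations), preserving topology and class sizes.

## Worked example

Simulate a 24-genome world and run every stage:

```sh
persistome simulate --seed 7 --out world
persistome all --world world --seed 7 --out report
```

`report/` then contains per-stage TSV tables, Newick trees and
`summary.json`. For seed 7 the run prints/records:

```
final clusters: 110
categories: {'duplicate': 29, 'fused': 2, 'mixed': 2, 'singleton': 77}
participation: 65.6%
medians: {'R': 0.85, 'S': 0.55, 'W': 0.69}
copy-number OR: 1.67  p 4.6e-08
lengths: {'S': 312.9, 'W': 502.8}  p 2.6e-10
partners: {'R': 11.4, 'S': 3.3, 'W': 5.6}
```

Reading: 110 of the 140 simulated families survive persistence filtering and
ortholog resolution. Ribosomal-like clusters (R) are the most conserved
(median 0.85 bits/column); weak-operon clusters (W, 0.69) evolve more slowly
than strong-operon clusters (S, 0.55) and their proteins are longer (503 vs
313 aa) with more interaction partners (5.6 vs 3.3) — the planted structure,
recovered end to end from the emitted flat files. The copy-number odds ratio
(1.67, Fisher p ≈ 5·10⁻⁸) says singleton occurrences favour operons over
duplicates.

The same stages are available individually (`persistome resolve|classify|
geometry|order|operon|rates|network`), and as library calls:

```python
from persistome import WorldSpec, generate_world, PipelineConfig, run_pipeline

world, truth = generate_world(WorldSpec(seed=7))
result = run_pipeline(world, PipelineConfig(seed=7), out_dir="report")
result.tables["group_median_bitscore"]   # {'R': 0.85, 'S': 0.55, 'W': 0.69}
```

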