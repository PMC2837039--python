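# Methods

This note documents the models and procedures implemented in `persistome`,
the choices made where the design was genuinely open, and what the synthetic
worlds do and do not establish about real data.

## Pipeline overview

Stages run in dependency order on a validated `World` (genomes, genes, hits,
clusters, operon calls, interactions, pathways):

1. **resolve** — rank-score ortholog resolution for duplicated genomes;
2. **classify** — persistence filtering, fusion detection, copy-number
   classification, plasmid pruning, final-set assembly;
3. **geometry** — persistent-gene genomic range, MED/MAD pair-spacing scan;
4. **order** — conserved-proximity graph, breakpoint/calibrated rearrangement
   distances, neighbour-joining trees, order-vs-sequence correlation;
5. **operon** — strong/weak profiles, copy-number × operon and
   identical-vs-mixed pair Fisher tests, per-COG summaries;
6. **rates** — normalised-bit-score cluster rates, protein lengths,
   rank-sum group comparisons;
7. **network** — class-pair interaction and pathway-sharing counts with
   permutation nulls.

`run_pipeline` works on a deep copy of the input cluster set, so a world can
be re-analysed under several configurations. One global seed fans out to
per-stage seeds by CRC32 of the stage name; disabling a stage never perturbs
another stage's randomness.

## Ortholog resolution

The rank of a copy within a contributing hit list is its first-appearance
position **among the k copies only** (not its absolute position in the full
list), after sorting by ascending e-value with ties broken by descending bit
score. This makes the smallest achievable total exactly the number of
contributing lists and renders the score insensitive to unrelated hits. Two
further choices the procedure itself leaves open:

- A copy absent from a list ranks *k* + 1 — one worse than the worst possible
  present rank — so absence is penalised but cannot dominate.
- A list containing *none* of the copies is skipped rather than charging
  every copy *k* + 1. Charging all copies equally would leave the score gap
  unchanged while inflating S_min (and with it the acceptance margin), making
  uninformative lists push clusters toward ambiguity for no reason.
- The acceptance margin uses `ceil(gap_fraction * S_min)` to keep the
  comparison in integers; `gap_fraction` defaults to 0.1.
- One ambiguous genome excludes the whole cluster (the conservative choice —
  a mis-assigned ortholog would contaminate every downstream distance);
  per-genome exclusion is available via `exclude_whole_cluster=False`.

## Classification

- Recent duplications are collapsed using the percent-identity column of the
  within-genome hit between the kept copy and the paralog (alignment-local
  identity, since that is what tabular search output provides). Threshold:
  strictly greater than 80%.
- The fusion detector is our concretisation: a protein is fused when it has
  hits at e ≤ 10⁻⁵ to members of ≥ 2 distinct persistent clusters whose query
  intervals overlap by < 20% of the shorter aligned region. Fused (> 50% of
  member proteins) and mixed (10–50%) clusters stay in the final set but are
  excluded from the statistical stages by default.
- Plasmid members are removed before the final persistence check, so a
  cluster at exactly the cutoff that loses a plasmid-borne member drops out.

## Geometry

Positions are 1-based inclusive; genes wrapping a circular origin carry
`end < start` and are handled natively. Minus-strand genes are mapped to
`size − start` (leading/lagging-strand correction) before range statistics.
The genomic range of a circular replicon is `L − (largest gap between
consecutive sorted starts)`, i.e. the shortest window containing every gene —
verified against exhaustive window search. Intergenic pair distance is the
number of bases strictly between gene boundaries, shorter arc on circles,
0 for overlapping or adjacent genes. Long-range spacing regularity uses
MED/MAD over genomes with a default threshold MAD ≤ 0.1·MED; the scan is
capped at `spacing_max_pairs` (default 2000) randomly chosen cluster pairs.

## Gene order

Breakpoint distance operates on signed circular adjacency sets with the
canonical form `min((a,b), (−b,−a))`, so a full reversal of a circular order
is distance 0. The rearrangement estimator is calibrated empirically: apply
*k* random inversions to the identity signed circular permutation of *n*
markers (grid of *k* up to 3 *n*), record the mean observed breakpoint
distance over `reps` replicates (default 200), force monotonicity by a
running maximum, and invert by linear interpolation. Observed distances at or
beyond the curve's plateau return the saturation value with a flag. The
original estimator of this family inverts a curve fitted over minimum
*inversion* distance; implementing an exact inversion-distance routine is out
of scope, so the curve is built over *breakpoint* distance instead — same
construction, different base measure — and `ede_calibrate` accepts a
user-supplied base-distance function for anyone wanting another measure.

Neighbour joining is delegated to scikit-bio with negative branch lengths
clamped to zero; on additive matrices the tree reproduces input distances to
1 × 10⁻⁹ (tested on 3-, 4- and 5-taxon cases).

The conserved-proximity graph joins clusters within `d_max = 500` intergenic
bp in at least `min_frac = 50%` of genomes; the denominator defaults to
genomes containing *both* clusters (an absent gene should not count as
evidence against proximity), with the all-genomes variant behind
`edge_denominator="all"`.

## Rates, lengths, distances

The rate proxy is bit score / alignment length per ortholog pair, averaged
per cluster; group summaries are medians of cluster means (lengths use
means). The unnamed two-group test is implemented as the two-sided
Mann–Whitney rank-sum test — appropriate for skewed cluster-level medians —
with a t-test behind a config switch. Scoredist uses BLOSUM62, the expected
random score computed from the two aligned sequences' residue compositions,
the mean of the two self-scores as upper limit, scale 100 × 1.337, and a cap
(default 1000) when the normalised score is non-positive. Gap columns are
ignored.

## Contingency and permutation statistics

- The copy-number × operon and identical-vs-mixed pair tests count gene
  *occurrences* (one resolved ortholog in one genome) and adjacent
  within-operon pairs respectively; both report the sample odds ratio ad/bc
  alongside the exact-test estimate, since a single published OR cannot
  disambiguate the estimator.
- The operon-fraction denominator is genomes where the gene is present *and*
  has a call; missing calls leave the denominator rather than counting as
  non-operon.
- Permutation nulls shuffle class labels over nodes/clusters, preserving
  graph topology and class sizes — the conservative choice given that the
  alternative (edge rewiring) changes degree structure. The pathway pair
  universe is restricted to clusters sharing ≥ 1 pathway with another
  cluster. p-values are one-sided (overrepresentation) raw fractions k/n, so
  0 and 1 are attainable; a (k+1)/(n+1)-corrected value is emitted alongside.
  Under-representation reads as p near 1.

## Synthetic worlds

The generator plants, per family: a class (R ribosomal-like / S strong
operon / W weak operon), presence dropout, paralogs (some recent at > 80%
identity), operon-block membership with class-wise retention p_op, a
similarity level s_f (mean normalised bit score), protein length, COG
category, and class-biased interactions and pathway memberships. Defaults
(24 genomes of 1.6 Mbp, 120 persistent-candidate + 20 background families)
mirror the structure of a many-genome bacterial study compressed to desk
scale:

| parameter | default | rationale |
|---|---|---|
| presence_prob | 0.96 | near-universal families with dropout |
| class fractions R/S/W | 0.21/0.34/0.45 | ribosomal/strong/weak split of a persistent gene set |
| duplicate fraction by class | 0.13/0.50/0.55 | ribosomal families are rarely duplicated; weak ones often |
| p_op by class | 0.95/0.95/0.50 | strong vs weak retention; weak families join blocks with prob 0.7 |
| s_f class means (bits/column) | 0.97/0.65/0.79 | ribosomal ≫ weak > strong conservation |
| protein length means (aa) | 130/335/497 | weak-operon proteins are longer |
| interaction rate matrix | R–W 6.8 … S–S 1.0 (× density 0.02) | per-pair edge densities of curated interaction data; weak proteins get more partners |
| self-interaction rate | 0.07/0.90/0.85 | frequent self-interactions outside the ribosome |
| pathway layout | S in groups of 8; W spread over a 3× pool, mean ≈ 2.5 memberships | strong families share tight pathways; weak ones appear in many |
| divergence → inversions | 30 × U(0.05, 0.5) | gene-order and sequence divergence grow together |

Layout: operon blocks are contiguous same-strand runs with 20–200 bp internal
gaps; blocks and solo genes are spread over the whole replicon by gaps
normalised to consume the free space (floor 600 bp, far above the 500 bp
clustering cutoff), so persistent genes span most of the genome as in real
chromosomes. Genome orders derive from a shared reference order by random
block-level inversions. Pairwise scores are generated directly
(s_f × e^(−0.25·(d_i+d_j)) + noise); ranking lists for duplicated genomes
draw from the same model (paralogs at 0.75×), so hit files are internally
consistent. An optional mode emits ungapped mutated protein sequences for the
Scoredist stages.

**What passing tests do not show:** the generator does not simulate sequence
evolution (no indels, no rate heterogeneity along sequences), horizontal
transfer, genome rearrangement below the block level, operon gain/loss
dynamics, database bias in interaction coverage, or non-orthologous gene
displacement. Recovery rates on these worlds certify the pipeline's logic,
not the biology of any particular genome collection.

## Problem sizes

The test suite and the acceptance script use: the 24-genome default world; a
100-genome/300-family world for resolution recovery; 500-family binomial
checks of presence sampling; 600 null graphs (120 nodes, 600 edges, 400
permutations each) for type-I calibration; 1000 rank-sum null simulations;
estimator calibration at n = 50 markers with 200 replicates and 40 trials per
planted k ∈ {1..10}. These sizes keep every stochastic check's standard error
well inside its asserted band while the whole suite runs in well under a
minute per file.

## Known limitations

- Rank scoring assumes hit lists are comparable across genomes; systematic
  database contamination would bias all lists alike and is not modelled.
- The breakpoint-based rearrangement curve saturates near the marker count;
  distances between highly shuffled genomes are reported as saturated rather
  than extrapolated.
- Scoredist requires equal-length (aligned) sequences; the pipeline does not
  run an aligner.
- Fisher tests on gene occurrences treat occurrences as independent, which
  overstates significance when cluster-level retention drives the counts —
  both tests should be read as descriptive, matching their customary use.
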