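# Methods

This note records the models, parameter choices, and numerical
decisions behind `microatlas`, and what the synthetic testbed does and
does not establish about real data.

## The data model

A run of droplet single-microbe shotgun sequencing yields paired-end
reads in which read 1 carries a cell barcode. After correction and
grouping, each *barcode group* is treated as a tiny metagenomic
sample: a bag of read pairs from one cell's genome plus a contamination
admixture (free DNA, multiplets, barcode collisions). Coverage per
cell is far below 1%, so two cells of the same species usually share no
sequence at all. Everything downstream is built around that fact: cells
are compared not by their reads but by the *taxonomic profile* of their
reads.

## Synthetic data generator

`simulate` emulates the assay's read structure, not its chemistry:

- **Genomes** are i.i.d. random nucleotide strings with a target GC
  fraction. Default community: one 50 kb genome per genus. Random
  sequence makes 21-mers effectively unique per genome, which is the
  regime the classifier needs; 50 kb keeps a ten-genus community and
  its k-mer index desk-sized.
- **Barcode groups**: the pair count is drawn uniformly from
  [1,000, 10,000]; each pair comes from an amplicon of uniform length
  in [400, 1000] bp placed uniformly on the (linear) genome; mate 1 is
  the amplicon's 5′ 150 bp, mate 2 the reverse complement of its 3′
  150 bp. The per-barcode contamination fraction is uniform on
  [0, 0.49] (a maximum-entropy reading of the stated range; a fixed
  per-tier fraction is also available via `fixed_contamination`), and
  contaminant pairs are drawn from uniformly chosen other community
  members. The contaminant pair count is round-half-to-even of
  n·fraction, for determinism.
- **Substitution errors** are optional (default 0) and i.i.d. per
  base; quality strings are constant (Q37, or the Phred equivalent of
  the configured error rate). No indels, chimeras, PCR duplicates, or
  insertion-bias model — positions are uniform, which real
  tagmentation is not.
- **Pseudo-contigs** are genome windows whose read group carries an
  *impurity* fraction of foreign reads, modelling chimeric or
  cross-mapped assembly contigs.
- **Strain panels** derive 2+ genomes from one ancestor by i.i.d.
  substitution at rate 0.01, giving pairwise identity near 98%
  (each strain diverges 1% independently) — the regime where single
  reads rarely discriminate strains.

All randomness flows through `numpy` Generators keyed on explicit
seeds; identical seeds give byte-identical FASTQ output.

What passing tests on this generator shows: the pipeline's logic —
grouping, classification, filtering, clustering, strain inference — is
correct under the stated read-structure model. What it does not show:
robustness to real-genome k-mer sharing between genera, uneven
coverage, sequencing error profiles, or database incompleteness. For
real data the classifier can be swapped for imported Kraken2/Bracken
reports at the same interface.

## Classifier

A canonical k-mer (min of forward and reverse-complement 2-bit codes,
k = 21 by default, odd so no k-mer is its own reverse complement)
indexes to the LCA of all genomes containing it. A read pair pools
both mates' k-mer hits; every candidate terminal taxon is scored by the
summed hit counts on its root-to-leaf path; the best-scoring terminal
wins, ties resolving to the LCA of the tied terminals; zero hits leave
the pair unclassified. k = 21 (rather than Kraken2's 35 with
minimizers) suits random 50 kb genomes, where 21-mers are already
effectively unique; there are no minimizers, spaced seeds, or
confidence thresholds because the surrounding pipeline only needs the
same input/output contract as the external tools.

Counts are then moved to a working rank (genus by default): counts at
or below the rank lift to their rank ancestor; counts above the rank
are split among the node's rank-level descendants *proportionally to
the lifted counts* (uniformly if all are zero) — the proportionality
that dominates Bracken's re-estimation; counts on paths with no node
at the rank drop out. Conservation (lifted + redistributed + dropped =
classified) is property-tested on random trees.

## Taxonomic discovery (TDA)

Each unit (cell barcode group or contig read group) becomes a vector
of relative abundances over the taxa seen at the working rank,
normalized over *classified* reads. Purity is the maximum entry;
classified fraction (classified/total) is kept separate so partial
classification and mixed content are distinguishable failure modes.
Filters are inclusive at their boundaries (a unit exactly at a
threshold is retained, matching the "remove less-than" phrasing of the
cutoffs): read count ≥ 1000, classified fraction ≥ 0.5, purity ≥ 0.8
for cells and ≥ 0.9 for contigs.

Clustering runs on the shared-nearest-neighbour graph of the vectors
(cosine kNN, Jaccard-weighted shared-neighbour edges) with Leiden
(RB-configuration modularity, resolution 1.0, fixed seed, 2
iterations). The 2-D UMAP embedding (cosine metric, fixed seed) is for
display only; labels never depend on it. Defaults: `n_neighbors = 30`.
With the expected tens of members per population, 15-neighbour graphs
proved under-connected — nearest-neighbour tie-breaking among
near-identical vectors can fragment a population into sub-communities
— while 30 neighbours makes recovery robust across partition types and
seeds. Row vectors are L1-normalized (relative abundances) rather than
raw counts: cosine similarity on compositions is scale-free, so read
depth does not masquerade as biology. Fewer than 6 units falls back to
SVD coordinates; an all-identical matrix short-circuits to a single
cluster.

Annotation: each unit gets its dominant taxon (ties break
lexicographically and are flagged); each cluster gets the modal unit
annotation. Contig vectors pass the stricter 0.9 purity gate and are
then simply concatenated with the cell vectors for joint clustering —
no batch correction, by design; the benchmark checks that contigs
co-locate with same-organism cells.

## Strain resolution

Each read pair is aligned to every panel strain by exact 21-mer
seeding (stride 25, both orientations) and ungapped extension with at
most 5 mismatches; the per-strain log-likelihood at the best placement
is m·log(ε/3) + (L−m)·log(1−ε) with ε = 0.01. Mates contribute the sum
of their per-strain log-likelihoods; once any strain explains both
mates, single-mate placements on other strains count as
non-alignments, so likelihoods stay comparable across strains. Pairs
aligning nowhere are dropped.

Abundance is inferred by mean-field VB on the mixture
P(read|θ) = Σ_s θ_s·L_is with a Dirichlet(α = 0.1) prior: iterate
r_is ∝ L_is·exp(ψ(a_s) − ψ(Σa)) and a_s = α + Σ_i r_is until the
posterior-mean θ moves < 1e-8; the ELBO trace is monotone and checked.
α = 0.1 is a sparse prior appropriate for cells that contain one (or
two) strains; with ≥1000 reads the posterior is likelihood-dominated
and VB agrees with a long-run EM oracle to ~1e-4 per component on
alignment-style likelihood matrices. Assignment: the top strain if its
abundance is ≥ 0.15 (the boundary is assigned, matching "smaller than
15% → mixed"), else "mixed"; exact ties are "mixed". Read positions
are modelled uniform; fragment-bias and sequence-bias corrections of
full transcript-quantification machinery are out of scope. SAM input
(all-matches alignments with NM tags) can replace the internal
aligner.

## Analytics

Coverage uses half-open 0-based intervals; rarefaction subsamples
placements without replacement (default cap 10,000 reads) and
evaluates cumulative coverage at evenly spaced depths, so the final
point equals full-sample coverage by construction. The cluster error
rate is the fraction of pooled reads not attributable to the cluster's
organism. Gene presence/absence filtering drops genes in < 10 cells,
then cells with < 10 genes, in one pass in that order (no fixed-point
iteration — documented rather than iterated). Gene-based subclustering
runs Leiden on a Jaccard-similarity kNN graph of the binary matrix.
Feature counting keeps records with MAPQ ≥ 42, deduplicates identical
(feature, position) records, and reports hits × 10⁶ / total reads.
Droplet occupancy is Binomial(n = gels per droplet, p = load rate),
with a Poisson(np) alternative; at the defaults (n = 5, p = 0.02)
P(≥1 cell) = 1 − 0.98⁵ ≈ 9.6%.

## Problem sizes used in tests and the acceptance script

Chosen once as desk-scale mirrors of the study conditions: the
simulator contract runs 10 species × 20 barcodes at the full
1,000–10,000 pair width; the ten-population recovery runs 10 genera ×
50 barcodes with contamination uniform on [0, 0.2] and 1,000–2,000
pairs per barcode (the filters' read-count gate sits at the low edge,
so it stays active, while the narrower width keeps the fixture small);
classifier-oracle checks use a 3-species community with a shared
4 kb genome block (≥5,000 reads); strain recovery uses 4 strains ×
20 kb at 1% divergence, 200 single-strain barcodes of 1,000 pairs and
40 50/50 doublets.

## Known limitations

- Random genomes have no shared gene content between genera; real
  communities produce denser LCA entries and lower purity.
- The classifier has no confidence threshold and no minimizer
  compression; indexes of real genome collections would be large.
- Strain alignment is ungapped and mismatch-capped; indels break
  placements.
- Contig integration does no batch correction between cell and contig
  vectors.
- The demultiplexer models the barcode as one contiguous block and
  trims adapters only as exact prefix/suffix matches with one allowed
  mismatch.
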