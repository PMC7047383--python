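# Methods

This document describes the models, algorithms, default parameters and
numerical choices used by `panhgt`, together with the scope of the bundled
simulator and the known limitations of each stage.

## Overview

`panhgt` analyses a collection of annotated bacterial genomes (FASTA +
GFF3) with the workflow used in comparative studies of rhizobial symbiosis
gene evolution:

1. pan-genome construction (protein clustering with Markov clustering),
2. whole-genome ANI and 95% single-linkage species delineation,
3. core-gene species tree and a likelihood-based vertical-descent screen,
4. detection of recent horizontal gene transfer (HGT) between species from
   the high-identity tail of shared-gene similarity distributions,
5. plasmid relatedness networks from shared protein families,
6. symbiosis-gene (nod/nif/fix) phylogenies and host-concordance summaries.

A simulator (`panhgt.synthetic_data`) plants a fully known ground truth —
species membership, gene families, transferred genes, plasmid clusters —
so that every stage can be validated by exact recovery rather than by
comparison to stored outputs.

## Sequence alignment primitives (`panhgt.align`)

All pairwise alignment is affine-gap dynamic programming implemented with
numba; a gap of length L costs `open + ext * L`.

- **Global DNA (EMBOSS-needle defaults):** match +5, mismatch −4, gap open
  10, gap extension 0.5. Used for per-gene similarity in the HGT detector.
  Reported similarity is `identities / alignment_length * 100`, matching
  the "needle similarity" convention.
- **Global/local protein:** BLOSUM62; local (Smith–Waterman) scoring uses
  gap open 11 / extension 1 (BLAST-like), used for pan-genome graph
  weights; the plasmid-network protein clustering uses global alignments
  with gap open 10 / extension 0.5.
- **Banded local DNA for ANI:** match +1, mismatch −1, gap open 5,
  extension 2, band half-width 8 around a seeded diagonal (below).

Scores are exact dynamic-programming optima within their stated search
space; the banded ANI aligner is exact only inside its band (a deliberate
speed/accuracy trade-off — see limitations).

## Pan-genome (`panhgt.pangenome`)

Proteins are compared all-vs-all with Smith–Waterman (BLOSUM62, 11/1)
after a 5-mer prefilter (pairs sharing fewer than two 5-mers are skipped).
Edges are weighted by the bit-score-like ratio `score(a,b) /
min(score(a,a), score(b,b))` and kept when the ratio is at least 0.4.
Markov clustering (MCL) with inflation 2.0 on the sparse similarity graph
yields gene families. Families are partitioned into **core** (present in
all genomes), **dispensable** (2..n−1 genomes) and **unique** (one
genome); the three counts always sum to the total number of families.
Presence/absence profiles are clustered with average-linkage on Jaccard
distances for the pan-genome dendrogram.

## ANI and species delineation (`panhgt.ani_species`)

ANI follows the fragment-mapping approach: the query genome is cut into
1020-bp fragments; each fragment is located on the subject via a 15-mer
index (step 8) with diagonal voting, strand chosen by vote, and aligned
with the banded Smith–Waterman above. Fragments are retained when identity
exceeds 30% over at least 70% fragment coverage; ANI is the mean identity
of retained fragments, symmetrised by averaging the two directions.
Species are single-linkage clusters of genomes at ANI ≥ 95%.

## Phylogenetics (`panhgt.phylo`)

- **Family alignment:** progressive profile alignment (BLOSUM62, affine
  gaps) over a 3-mer-distance NJ guide tree, then codon back-translation
  for nucleotide-level analyses.
- **Distances/NJ:** Jukes–Cantor distances (proportions ≥ 0.749 are capped
  at distance 5.0 to avoid the logarithm singularity); neighbour joining
  with deterministic tie-breaking. NJ is exact on additive matrices.
- **Likelihood:** HKY + discrete-gamma (4 categories) via Felsenstein
  pruning, vectorised over site patterns and rate categories. Branch
  lengths are optimised per edge with Brent's method on an above/below
  factorisation of the tree likelihood, so each trial length costs
  O(16 × patterns) instead of a full pruning pass.
- **Vertical screen:** per single-copy-core family, an NJ gene tree is
  compared to the species tree with the Shimodaira–Hasegawa (SH) test
  using RELL bootstrap (1000 replicates by default). If the gene-tree
  topology equals the species tree (RF = 0) the family is consistent by
  construction and the test is skipped. Families with SH p < α (default
  0.05) are flagged as inconsistent with vertical descent.
- **Species tree:** NJ on JC distances from the concatenated single-copy
  core alignment.

## Recent HGT detection (`panhgt.hgt`)

For each pair of species (representative = longest genome per ANI
cluster; pairs at ANI ≥ 95 are skipped), the best-matching member pair of
every shared gene family is globally aligned and its percent similarity
recorded. The similarity distribution is modelled as a two-component
Gaussian mixture truncated to (0, 100]: a *vertical* component around the
genome-wide divergence and a *transferred* component near 100%. The EM
algorithm uses a numerically optimised M-step (L-BFGS-B on the truncated
log-likelihood) with the transferred component initialised at 98.5%. A
gene is called transferred when its posterior responsibility for the
transferred component exceeds 0.5 **and** its similarity is at least the
threshold (98.5% by default). With fewer than 20 shared genes the mixture
is unreliable and a pure threshold rule is used instead (recorded in the
output as `method = "threshold"`). A species pair is *significant* when
its transferred-gene count exceeds `min_genes` (50 by default, following
the empirical "large recent transfer" criterion). Transferred genes are
localised to replicons via a reference genome, and the correlation between
transfer counts and pairwise ANI is summarised with an exact/permutation
Spearman test when at least five pairs are available.

## Plasmid network (`panhgt.plasmid_network`)

Plasmid proteomes are clustered greedily into protein families (global
identity > 40% over ≥ 80% of the shorter protein, processed in
length-descending order for order invariance). A bipartite
plasmid–family graph links plasmids to the families they carry. Plasmid
relatedness is the Jaccard distance between family repertoires; average
linkage with a dendrogram cut at 0.15 defines plasmid clusters. COG-style
category enrichment uses one-sided Fisher's exact tests and reports raw
(uncorrected) p-values, stated explicitly in the output column name.

## Symbiosis genes (`panhgt.symbiosis`)

nodABC, nifHDKENB and fixABC are extracted by annotation name (duplicates
resolved to the longer CDS; genomes missing any gene are flagged
incomplete). Per-gene NJ trees with codon-resampling bootstrap (1000
replicates) are labelled with percent support. Host concordance reports
per-host monophyly and the within/between-host patristic distance ratio.

## Statistics (`panhgt.stats`)

- **Wilcoxon rank-sum:** exact double-tail enumeration of all group
  assignments when n₁+n₂ ≤ 12 (midranks for ties), normal approximation
  with tie correction otherwise.
- **Spearman:** midrank correlation; the p-value is an exact full
  permutation enumeration for n ≤ 8, Monte-Carlo permutation for
  8 < n ≤ 20 and a t-approximation above. Exact enumeration beyond n = 8
  is computationally infeasible (n! permutations).
- **Fisher's exact test** (via scipy) backs the enrichment analyses.

## Simulator (`panhgt.synthetic_data`)

Genomes evolve by HKY (κ = 2, equal base frequencies) along a pure-birth
species tree scaled so any two species differ by at least the configured
between-species divergence (default 8%); genomes within a species differ
by the within-species divergence (default 1%). Each genome carries a
chromosome and two plasmids (one symbiosis plasmid, pSym, carrying the 12
symbiosis genes contiguously). Defaults: 6 species × 2 genomes, 80 core +
60 accessory families, mean gene length 150 codons, and a neutral
intergenic backbone of 600 bp per gene slot so planted transfers remain a
small fraction of the genome (~106 kb per genome). Plasmid contents come
from per-group family templates; species in the same group share
templates, which plants the true plasmid clusters. An HGT plan replaces
recipient gene copies with near-identical donor copies (configurable
residual divergence); all genomes of the donor species are harmonised at
the transferred loci so the planted signal does not depend on which
genome represents the donor cluster. Truth tables record species
membership, family membership, transferred CDS ids and plasmid cluster
labels.

**Scope:** the simulator is designed for validating the inference stages,
not for realism. It omits indels in coding sequences, rearrangements,
gene gain/loss dynamics, codon/GC bias, recombination within genes and
annotation noise.

## Numerical choices

- All randomness flows through `numpy.random.Generator` objects spawned
  from a single seed; reruns are byte-identical.
- Likelihood computations are performed in log space with per-node scaling
  implicit in the pattern-batched pruning; JC distances are capped before
  the logarithm singularity.
- EM asserts a monotone non-decreasing log-likelihood and reports
  convergence status rather than failing silently.

## Limitations

- The banded ANI aligner can underestimate identity when true alignments
  drift outside the ±8 band; at the divergences relevant to the 95%
  species threshold this effect is negligible, but ANI values below ~80%
  are indicative only.
- The SH screen tests a single alternative topology (the NJ gene tree);
  weak single-gene signal (short internal branches) reduces its power to
  flag genuinely discordant histories.
- The mixture-based HGT detector assumes one dominant recent-transfer
  mode; continuous gene flow or multiple transfer ages would violate the
  two-component model.
- Protein families from greedy clustering are not guaranteed optimal;
  MCL granularity depends on the inflation parameter (2.0 by default).
- Raw p-values are reported throughout descriptive tables; apply
  multiple-testing control when using them inferentially.
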