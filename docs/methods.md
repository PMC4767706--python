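# Methods

## Scope and model

genotax treats prokaryotic taxonomy as a thresholding problem on
pairwise whole-genome relatedness. Three indices feed the same
clustering machinery: fragment-based average nucleotide identity (ANIb),
tetranucleotide z-score correlation (TETRA), and digital DDH (dDDH)
values ingested from files. Species, subspecies and higher "group"
ranks are delimited by F-linkage clustering of the distance matrix at
rank-specific thresholds, and the quality of any such delimitation is
interrogated with chance-corrected partition agreement (MRI),
pair/triplet consistency, neighbor-joining trees, and collector's
curves.

## ANIb

The query genome is fragmented into consecutive, non-overlapping
1,020-nt windows per contig; the terminal remainder and windows that are
more than half ambiguous (N) are discarded. Each fragment is aligned
against the subject with exact local Smith–Waterman (Biopython's
`PairwiseAligner`) under +2/−3 match/mismatch and −5/−2 affine gap
scores, on both strands. For speed the subject search space is
restricted to windows around diagonals supported by shared 15-mers; a
fragment with no shared 15-mer reports no hit. A hit contributes its
percent identity (identical columns over alignment columns) when it has
≥ 30% identity and its aligned fragment positions cover ≥ 70% of the
fragment; ANIb one-way is the mean over contributing fragments, and the
matrix stores both directions (reciprocal values) with NaN for pairs
with no accepted hit. These fragment-length and filter constants are the
standard ANIb convention; all are keyword-overridable.

The identity filter interacts with the seeding: truly unrelated
sequences rarely share a 15-mer, and the decoy behaviour is covered by a
test that checks a no-seed pair returns no hit.

## TETRA

Tetranucleotide counts are pooled over all contigs and their reverse
complements (so the profile is strand-invariant by construction). The
null expectation is the maximal-order Markov model
`E(abcd) = N(abc) * N(bcd) / N(bc)` with variance
`E * (N(bc) - N(abc)) * (N(bc) - N(bcd)) / N(bc)^2`; components with an
undefined expectation or non-positive variance get z = 0. Genome pairs
are compared by the Pearson correlation of their 256-component z-score
vectors (lexicographic AAAA..TTTT). A zero-variance profile (possible
only for degenerate sequences) is an error rather than a silent NaN.

## dDDH and scale handling

dDDH matrices are read from delimited text on the percentage scale and
clustered directly with thresholds stated as percentages (species 70,
subspecies 79, group 31.8), after conversion *d* = 100 − value. This is
justified by a property the clustering provably has and the tests
assert: F-linkage output depends only on the relation *d* ≤ *T*, so any
strictly increasing rescaling of distances together with the threshold
leaves the partition unchanged. Clustering percentages at 70% dDDH is
therefore identical to clustering the native genome-to-genome distances
at the equivalent threshold. The subspecies threshold (79%) comes from
the established subspecies-delineation convention for dDDH.

## F-linkage clustering

Starting from singletons, the pair of clusters with the highest
inter-cluster link fraction (share of pairs with *d* ≤ *T*) merges while
that fraction is at least *F* and strictly positive; the strictness
clause makes *F* = 0 behave as single linkage (connected components of
the link graph, asserted against an independent graph-traversal oracle)
instead of merging everything. Ties are broken deterministically:
highest link fraction, then lowest mean inter-cluster distance, then the
lexicographically smallest pair of smallest member identifiers. The
implementation maintains link counts and distance sums incrementally, so
a 93-genome clustering takes milliseconds and full rarefaction sweeps
stay cheap.

MRI is implemented as the adjusted (chance-corrected) Rand index by pair
counting on the label contingency table, and is cross-checked in the
tests against scikit-learn's implementation. The parameter sweep scores
a full (F, T) grid; the default T grid uses midpoints between
consecutive observed distances, which exhausts every distinct link
relation the matrix can produce.

## Consistency diagnostics

Given a partition and threshold, a pair is inconsistent iff (same
cluster ∧ *d* > *T*) ∨ (different clusters ∧ *d* ≤ *T*). Each cluster's
consistency is the consistent fraction among pairs touching the cluster;
the headline number is the unweighted mean across clusters (the exact
per-cluster normalization is a genuine design choice; the global
pairwise fraction is always reported alongside so no information is
lost). Triplet consistency counts transitive link relations among all
C(n,3) triplets in closed form from the link graph (open two-link paths
= Σ C(deg,2) − 3·triangles), verified against brute-force enumeration.

## Neighbor joining

Canonical Saitou–Nei agglomeration with lexicographic tie-breaks in the
Q-matrix. Negative branch-length estimates — routine for non-additive
ANI-derived distances — are clamped to zero with the deficit transferred
to the sibling branch, preserving tip-to-tip path lengths; the original
estimate is retained on the node. Outgroup rooting bisects the
outgroup's terminal branch. On additive matrices the tree reproduces
input distances exactly (tested), and topology agrees with scikit-bio's
NJ as an independent oracle.

## Pan-genome fractions

Ortho-groups are a deliberate, testable surrogate for Markov-clustering
pipelines: all-vs-all local protein alignment (BLOSUM62, −11/−1 gaps,
4-mer prefilter), hits filtered by ≥ 50% coverage on *both* sequences
and a score floor calibrated on shuffled-sequence decoys at a fixed seed
(playing the role an e-value cutoff plays in BLAST-based pipelines,
without depending on any engine's statistics); then bidirectional best
hits between genomes plus within-genome edges scoring at least the
weaker gene's best inter-genome hit (in-paralogs); groups are connected
components. Externally produced hit tables (12-column tabular) and
groupings can be passed through instead.

Fractions follow the set definitions exactly: core = groups in every
genome; group core per label; group-specific = one label's core minus
every other label's core; strain-specific = CDSs in groups confined to
one genome (CDS counting by default, family counting by option); pan =
all groups. Percentages are relative to the arithmetic mean per-genome
CDS count. Trait prevalence reports, per group label, the percentage of
members carrying a complete marker set or at least its functional core
subset.

One property worth stating because it surprises: the *count* of
recovered ortho-groups is not monotone in the genome set — a newly added
genome's genes can bridge two components that lacked a direct BBH edge.
The set-level invariant (no family disappears when a genome is added)
holds and is what the tests assert.

## Collector's curves

Each replicate draws one random permutation of the genomes and evaluates
the statistic on every prefix (nested/accumulation sampling, matching
"sequentially added strains"); independent per-size subsampling is
available by flag. Defaults: 200 replicates, empirical quartiles with
numpy's default (type-7) interpolation. Within a replicate, core sizes
are non-increasing and pan sizes non-decreasing in the sample size;
across replicates the mean at size *n* converges to the exact average
over all C(N,n) subsets, which the tests verify by full enumeration on a
six-genome pangenome. Note the mean can fall outside [Q1, Q3] for
skewed discrete statistics; Q1 ≤ median ≤ Q3 is the invariant that
actually holds.

## Synthetic data: what it emulates and what it does not

The generators plant a groups → species (→ subspecies) → strains
hierarchy three ways:

* **Sequences** — one root genome; group, species and strain sequences
  derived by i.i.d. per-site substitution at per-level rates
  (transition:transversion = 2, no indels, no recombination or gene
  flux). This gives controlled ANI/TETRA structure: a pair whose lineage
  accumulated rates r₁ and r₂ shows ANI ≈ 100·(1−r₁)(1−r₂).
* **Proteomes** — random-sequence gene families (80–400 aa, members
  mutated at 15% per residue, so ≥ ~70% within-family identity against
  ~5% between families), with a shared core, group-exclusive families,
  Poisson strain-exclusive genes and within-genome paralogs.
* **Matrix shortcut** — reciprocal similarity values drawn uniformly
  around per-level means, for dataset-scale tests without alignment.

The flagship study, `fluorescens_complex_design()`, emulates a 93-strain
species complex: 8 groups of 21/17/14/12/10/8/6/5 strains containing 69
species and 75 subspecies, with dDDH-scale level means 91 / 75 / 45 /
20% (± 1.5 uniform noise) chosen on the published landmarks of the
dDDH scale — conspecific strains around 90%, the species boundary at
70%, the group level at 31.8%. The ANI-scale variant (98.2 / 96.8 / 87 /
78% ± 0.5) additionally pins one conspecific pair at 94.5% ANI to
emulate the documented fragility of pairwise ANI thresholds, which
average-linkage clustering (F = 0.5) absorbs.

Passing tests on these data show the machinery is correct, not that real
genomes are this clean: real matrices have heavier asymmetries, level
overlap (hence consistency < 1), missing cells, and orthology ambiguity
from domain shuffling — none of which the generators model. Exact-scale
published fraction sizes (core ≈ 1.3k, pan ≈ 31k CDSs for a real
93-proteome complex) depend on the original search engine and
Markov-clustering granularity and are validated here only qualitatively
(group cores exceed the complex core, pan ≫ core, open-pan behaviour)
plus by exact planted-truth recovery.

## Numerical choices and problem sizes

Floating-point tie tolerance in merges and Q-matrix minima is 1e-12;
matrix validation enforces scale ranges ([0,100] similarity, [−1,1]
TETRA) and symmetric input for clustering/trees, with `mean`/`min`/`max`
symmetrization of reciprocal values (mean by default). Missing cells may
be kept, dropped greedily by most-missing genome, or rejected. Test and
acceptance runs use matrix-mode studies at the full 93-genome scale and
sequence-mode studies on 4–8 kb genomes and ~200-CDS proteomes — sizes
chosen so every oracle (quadratic Smith–Waterman, exhaustive subset
enumeration, brute-force triplets) stays exact while the whole suite
runs in minutes.

## Known limitations

dDDH and GBDP distances are never computed (ingested only). The
orthology surrogate has no inflation parameter and will lump families a
Markov clustering would split at high inflation. NJ is plain (no
BIONJ/FastME refinements, no bootstrap). The simulator's uniform noise
cannot produce the long-tailed asymmetries of real reciprocal ANI
calculations.
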