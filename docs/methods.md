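# Methods

## The analysis in one paragraph

`famdomevo` reconstructs the evolutionary dynamics of protein families
and protein domains over a fixed, rooted, branch-length-annotated
species tree (nine metazoans plus yeast and choanoflagellate
outgroups).  Families are clusters of homologous proteins (Markov
clustering of an all-against-all similarity graph; multi-member
clusters only); domains are profile hits grouped by accession.  Two
complementary event layers are inferred.  *Birth/death* events treat
each family or domain as a binary presence/absence character and place
a single gain plus a minimal set of losses on the tree by Dollo
parsimony.  *Duplication/deletion* events operate within a family:
a neighbor-joining gene tree is rooted by minimum duplication+loss cost
and reconciled against the species tree by LCA mapping.  Counts are
normalized by branch length (substitutions/site) into rates, condensed
into four per-lineage indices, and compared across event types with
Pearson correlations (Student-t significance, n−2 df).  Family sets of
interest (e.g. families born at a clade's last common ancestor) are
tested for term enrichment with the exact hypergeometric test, an
elim-style refinement, and a permutation false-discovery rate.

## Models and conventions

### Species tree and branch naming

Every event is reported against a branch, identified by the canonical
name of its head node (sorted leaf names joined by commas).  Births of
characters present in all taxa sit on the virtual branch `@root`, which
has no length and is excluded from every rate.  The packaged fixture
carries the published branch lengths for the 17 metazoan lineages;
the two outgroup pendant branches and the stem into the metazoan crown
carry placeholder length 1.0 and are excluded from rate and index
computations (printed lengths exist only for the metazoan lineages).
The rooting places the choanoflagellate as sister to Metazoa with
yeast outside, the accepted phylogeny.

### Family construction

The similarity graph weights edges `min(−log10 E, 200)` averaged over
both search directions (E = 0 maps to the cap).  MCL follows the
classic formulation: self-loops equal to each node's maximum incident
weight (1 for isolated nodes), column normalization, then repeated
expansion (matrix squaring) and inflation (entrywise power 2.0,
renormalize) with pruning of entries below 1e−5, to a stationary
matrix (tolerance 1e−8, at most 200 iterations).  Clusters are read
from the attractor structure; a node pulled by several attractor
systems goes with its largest converged weight, ties to the
lexicographically smallest cluster.  Inflation 2.0 is the default
granularity; it is a configuration knob, not re-calibrated here.
Clusters with a single member are not families.

### Dollo reconstruction

For a character present in taxa S, the gain is the branch above
lca(S); losses are the branches into the maximal subtrees of the gain
clade containing no member of S.  This loss set is minimal among all
single-gain scenarios (verified exhaustively in the tests for all
trees with ≤ 6 leaves).  Dollo overestimates content at ancient nodes
when characters are lost convergently; no correction is applied — the
bias is a property of the method being studied, and the simulator's
constrained regime (below) shows exactly when the reconstruction is
error-free.

### Gene trees and reconciliation

Distances: p-distance or Kimura-corrected protein distance
d = −ln(1 − p − p²/5) with pairwise gap deletion; saturated pairs
(p ≥ 0.85) receive a finite ceiling (default 10.0) so NJ stays
defined.  Likelihood distances are deliberately out of scope: the
downstream reconciliation uses topology only, and precomputed PHYLIP
square matrices are accepted wherever alignments would be.

NJ is the Saitou–Nei Q-criterion agglomeration with a deterministic
tie-break (lexicographically smallest pair of subtree labels) and
negative branch-length estimates clamped to zero with the deficit
moved to the sibling.  On additive matrices the generating topology
and all path lengths are recovered exactly (regression-tested on 200
random matrices, n ≤ 12).

Reconciliation maps every gene-tree node to the species-tree LCA of
its descendants' species.  A node whose image equals a child's image
is a duplication, charged to the branch above the image; every species
node skipped on the way from a node's image to a child's image charges
one loss to the branch it skips (the sibling branch).  Duplication and
loss have equal unit cost.  Unrooted gene trees are rooted by
evaluating every edge and keeping the cheapest rooting (ties: fewer
duplications, then smallest canonical edge label).  Gene trees with
more than 1000 leaves are excluded from aggregation and reported, the
same size guard used when the published counts were produced.

### Rates, indices, correlations

Rates divide each count by the lineage's branch length.  The four
indices are, per lineage:

* family change = log2(B_fam / D_fam)
* domain change = log2(B_dom / D_dom)
* domain shuffling = log2(B_fam / B_dom) — branch-length normalization
  cancels in the ratio and is omitted
* adaptation AI = log2(B_fam/l) + log2(D_fam/l)

All logs are base 2: that base uniquely reproduces the published
shuffling indices for the human (2.18), mouse (1.97) and chicken
(1.32) terminal lineages; e and 10 do not.  A zero count leaves an
index undefined (reported `NA`) unless a pseudocount is configured
(default off; missing values are dropped pairwise in correlations).
Correlations are computed on rates, not raw counts — on raw counts
family birth and death correlate *positively*; only rates reproduce
the published negative coefficient — with two-sided significance from
t = r√(n−2)/√(1−r²).

A reproduction note: the packaged fixture stores branch lengths to the
2 decimals at which they were printed, so recomputed coefficients can
differ from the published ones in the second decimal (e.g. family
birth vs death gives −0.589 against a printed −0.58).  The regression
tests therefore require agreement within one unit in the second
decimal place for the anchored coefficients.

### Enrichment

Annotations are lifted from proteins to families with set semantics (a
term found in several members counts once) and closed over is_a /
part_of ancestors.  Enrichment of a target family set against a
background (default: all families with at least one annotation) is the
exact hypergeometric upper tail; depletion is the lower tail.
Refinement is an elim-style pass from the DAG leaves upward: when a
term is significant at the threshold (default 0.001), the target
families it annotates are eliminated from all its ancestors before
those are re-tested; terms significant only through their descendants
are flagged `refined_out`.  The FDR is the min-p permutation estimate:
random same-size targets are drawn from the background (default 1000
replicates, seeded), and a term's FDR is the fraction of replicates
whose best p-value beats it.  The conventional selection keeps terms
with refined p < 0.001 and FDR < 0.1 jointly.  The exact internals of
the original refinement/FDR tooling are not published; these are
documented, seeded approximations of the same ideas.

## The synthetic benchmark

The simulator walks the species tree from the root with a genome of
families.  Per branch of length l, event counts are Poisson with
exposure rate·l·(count at branch start): family birth (0.15 per family
per unit length), family death (0.05), member duplication (0.15 per
member), member deletion (0.10), standalone domain gain (0.02).  The
root genome holds 150 families (members geometric with mean 2, minimum
2; architectures of 1–3 fresh domains).  A new family is founded by
one new domain (probability 0.3) or by shuffling one domain from each
of two distinct existing families, and starts as two copies (a
founding duplication), so every family is observable as a multi-member
cluster from birth.  Member deletion never empties a lineage (and
never breaks the founding pair on the birth branch), so presence per
species coincides with family survival.  Domain presence is the union
of the local architectures of surviving families; domain birth/death
counts are read off per-node genome differences, so a domain "dies"
when its last local carrier family does.

Sequences are never simulated.  Pairwise distances are true gene-tree
path lengths plus optional Gaussian noise (σ = 0.02 by default),
which makes the dataset exactly invertible at zero noise because only
topology is used downstream.  Similarity edges connect all intra-family
pairs at weight 100, each dropped with probability 0.01; spurious
cross-family edges at weight 10 are added at 0.005 expected per
protein.  These moderate-noise values are the documented default
conditions; `zero_noise()` and `duplication_only()` derive the exact
regimes.

Two structural constraints (both on by default) make histories
Dollo-consistent and exactly recoverable: families never re-emerge
after death (single origin), and deaths avoid (a) the sister branch of
a branch that already lost the family and (b) the child branches of
the family's birth node.  Under (a)+(b) the carrier set's LCA is the
true birth node and every maximal empty subtree is exactly one death
branch, so Dollo recovery is exact — this is the end-to-end acceptance
surface, verified over 5 seeds.  Duplication localization by LCA
mapping is exact on duplication-only histories (no deletions, no
family deaths); with deaths present a duplication whose descendants
were lost on one side genuinely cannot be placed on the correct branch
by parsimony, so the exact duplication check runs on the
duplication-only regime.  Domain characters are *not* loss-constrained
(their carriers are families, which die on their own schedule), so
per-branch domain birth recovery is not guaranteed exact; totals
always match the observed repertoire.  An explicit violating mode
(`allow_rebirth`) re-activates dead families to demonstrate Dollo
undercounting.

What the generator does not emulate: sequence-level evolution and
alignment error, annotation bias between well- and poorly-annotated
proteomes, clade-correlated rate variation, and the sheer scale of
real proteomes (hundreds of families versus tens of thousands).
Passing the recovery tests therefore shows the inference machinery is
correct and calibrated, not that real data meet its assumptions.

## Numerical choices and edge cases

* MCL: convergence 1e−8 on the max entry change; prune 1e−5; warning
  plus current clustering on non-convergence.
* NJ requires ≥ 3 taxa; 2-leaf families are reconciled directly from
  the trivially rooted cherry; 1-member clusters contribute nothing.
* Reconciliation requires binary gene trees; the NJ trifurcation is
  handled by rooting on an edge, never by resolving a polytomy.
* Zero-variance vectors make Pearson r undefined (error, not NaN);
  |r| = 1 returns p = 0.
* Domain-hit overlaps above 50% of the shorter envelope are resolved
  by bit score, then E-value, then accession — a deterministic rule
  chosen because the source tooling's behaviour is unspecified.
* Problem sizes in the test suite (150-family genomes, 5 + 5 + 20
  simulation seeds, exhaustive oracles to 6 leaves for Dollo and to 4
  gene-tree leaves for reconciliation with seeded 5–6-leaf sampling)
  are the package's chosen desk-scale regression surface; the full
  enumeration of 6-leaf gene trees over all 4-taxon species trees is
  combinatorially out of reach of an exhaustive oracle and is covered
  by sampling instead.

## Known limitations

* Equal duplication/loss costs only; no transfer events, no NNI-aware
  reconciliation, no bootstrap support.
* The E-value→weight transform and the MCL inflation are conventions;
  the published clustering cannot be reproduced bit-for-bit without
  the original search results.
* Dollo's ancient-node bias is uncorrected by design.
* The enrichment refinement and FDR approximate unpublished tooling;
  absolute p-values from the original study's annotation snapshot are
  not reproducible and are not attempted.
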