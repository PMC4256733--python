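# Methods

This note documents the models, algorithms and numerical choices behind
`mitoevo`, in the spirit of a statistical-software methods appendix: it
states what each component assumes, which knobs matter, and what the
synthetic-data tests do and do not demonstrate about real data.

## Orthology clustering

**Similarity search.** Sequence-vs-sequence scoring uses Smith–Waterman
local alignment (Biopython's `PairwiseAligner`) with BLOSUM62 and
affine gap penalties (open 11, extend 1).  Like any database search
tool, the all-vs-all stage reports only significant hits: a null
distribution is built from residue-shuffled cross-genome pairs (500 by
default), a Gumbel is fitted by the method of moments, and a hit's
e-value is `N · P(S ≥ s)` with `N` the database size.  Hits with
e > 0.01 are omitted.  The 0.01 reporting level is the same
significance level used by every other similarity decision in the
procedure (profile recruitment and cluster merging); at desk scale it
plays the role that the default reporting threshold of a large-database
BLASTP search plays at genome-database scale, where a chance hit of
raw score ~40–60 has an e-value in the hundreds and is never reported.
This matters: unconstrained maximal local paths between *unrelated*
sequences pass a 50 % coverage requirement roughly 1 % of the time at
any sequence length (they are chains of small positive cores, not
bridges over deep dips, so an X-drop criterion would not remove them
either), and in a genome that happens to lack a family such a chance
hit would otherwise become that family's reciprocal "best hit by
default" and occasionally fuse two families at the triangle stage.

**Reciprocal best hits and triangles.** After a bidirectional coverage
filter (≥50 % of query *and* subject; boundary inclusive), each
sequence retains its single best-scoring subject per foreign genome
(score ties break to the lexicographically smaller id).  Mutual choices
form undirected edges; 3-cliques spanning three distinct genomes are
enumerated and merged transitively on shared edges.  Because one
protein can sit in triangles with two disjoint genome pairs, components
sharing only a vertex are merged as well — the result must be a
partition.  All stages are deterministic for a fixed input.

**Profiles.** Cluster alignments come from a center-star construction
(star = member with maximal summed pairwise score; members aligned
globally to the star; gaps propagated), or from a supplied external
alignment that is validated against the membership.  Columns with gap
fraction > 0.5 are discarded (this replaces a separate
alignment-trimming step).  Per column, the log-odds score of residue
`c` is

    score(c) = log2( ((n_c + β·b_c) / (N + β)) / b_c )

with counts `n_c`, non-gap total `N`, Robinson–Robinson background
`b_c`, and pseudocount weight β = 5.  With β = 0, absent residues are
floored at −30 instead of −∞.  Profile-vs-sequence alignment is an
affine-gap local DP (numba-compiled; unknown residues score 0);
e-values are again empirical-Gumbel, pooling ≥30 residue shuffles of
every database sequence.

**Expansion, merging, orphans.** Unassigned sequences join the cluster
giving their best hit at e ≤ 0.01 (lowest e-value, then highest score,
then smallest cluster id); assigned sequences never move.  Merging is
iterative: per round each cluster's profile is searched against all
clustered sequences, self-cluster hits are discarded, mean scores per
hit cluster are compared, and reciprocal best-mean nominations merge
pairwise (smallest-id pair first when chains occur) until a fixpoint.
Finally every remaining sequence becomes a singleton orphan cluster or
joins a curated cluster from a membership table, so the cluster set
partitions the input.

## Ancestral gene content

**Model.** Binary family profiles evolve by pure loss on a rooted
(possibly multifurcating) species tree: a family present at the parent
is absent at child `c` with probability `q_c`, and absence is
absorbing.  The root family count is Poisson(λ).  Branch loss is
parameterised directly as a probability per branch rather than
rate × length, because the species trees this is used with are
cladograms; when branch lengths exist they only seed the initialisation
(`q = 1 − e^−ℓ`).

**Likelihood and posteriors.** The pruning pass computes
`D_v(1) = Π_c [q_c D_c(0) + (1−q_c) D_c(1)]` and `D_v(0) = Π_c D_c(0)`
(a node in state 0 forces its whole subtree to 0).  The outside pass
uses prefix/suffix sibling products — never division, since zero
partials are routine under pure loss.  Posteriors condition on the
family being present at the root *and* observed; families with
all-zero profiles are rejected as input errors.  A node with at least
one present descendant leaf is forced present analytically, and its
posterior is set to exactly 1 rather than 1 − ε, so the expected root
count equals the observed family count exactly — this is the model's
signature analytic property, not a numerical coincidence.

**EM.** The conditional likelihood `Σ_f log[L_f / (1 − E0)]`, with
`E0 = P(all leaves absent | present at root)`, is maximised by EM.  The
E-step computes expected per-branch loss events
`P(parent 1, child 0 | profile)` for every observed family plus
`F·E0/(1−E0)` phantom all-zero families (the standard truncated-data
augmentation; the Poisson root makes it exact); the M-step sets
`q_b = E[losses on b] / E[present at parent of b]`.  The conditional
log-likelihood is non-decreasing across iterations (asserted in tests);
convergence is `|Δℓ| < 1e-8` with a 500-iteration cap, non-convergence
flagged rather than raised.  `λ̂ = F / (1 − E0)`.

**Loss propensity.** The number of lineages that lost a family is
reported in two modes: `expected` (default) sums the per-branch joint
posteriors; `thresholded` counts branches whose loss posterior exceeds
0.5.  Group (complex) propensity is the arithmetic mean over member
families.

**Dollo parsimony.** Each character is gained exactly once, at the last
common ancestor of its present leaves; an internal node is in state 1
iff it is inside the gain clade and has a present descendant; losses
are 1→0 branches.  This placement is optimal among single-gain
scenarios (verified against exhaustive enumeration on all test trees
with ≤6 leaves).  All-absent characters are valid and flagged (no
gain, no losses).

## Phyletic patterns

Presence is "any member in the species"; the compartment matrix marks a
(family, species) cell `dual` when both a mitochondrial and a nuclear
member exist — the signature of a recent, still-redundant transfer.  A
cell whose only members come from neither compartment (bacterial
outgroups) is marked `other` so presence remains equivalent to
"not absent".  Coverage reports give the fraction of each genome's
mitochondrial proteins assigned to non-orphan clusters, summarised as
min/median/max per taxon group (second lineage level by default).

**Fisher test.** Dual-encoding enrichment contrasts dual gene instances
with species counts (a deliberately unit-mixed 2×2, kept because it is
the construction used in the motivating analyses).  Two two-sided
conventions are implemented: `minlike` (sum of all tables with point
probability ≤ observed; the default) and `doubled` (twice the smaller
tail, capped at 1).  On the reference table {12, 2; 6, 40} they give
9.4 × 10⁻⁷ and 1.9 × 10⁻⁶ respectively; the minimum-likelihood value
matches the published figure for that comparison, which is why it is
the default.

**Ortholog vetting.** A nuclear candidate in a gene tree is accepted
iff the smallest clade containing it and at least one
mitochondrion-encoded sequence contains only mitochondrial,
alpha-proteobacterial and candidate leaves.  This replaces manual tree
inspection with a single reproducible rule; no bootstrap filtering is
applied.

## Intron architecture

Intron positions are 0-based offsets into the spliced coding sequence,
so phase is `offset mod 3` and untranslated regions are irrelevant;
GFF3 (1-based, genomic) is converted exactly once, at input, with
minus-strand segments taken in transcription order.  Density is pooled
(1000 × introns / coding nucleotides), never averaged over genes.
Internal exons are classified by flanking phases into the nine classes
0–0 … 2–2; terminal exons are counted separately.  Back-translation
expands each protein alignment column to three nucleotide columns
(`cds_length` must equal 3 × residues; stop codons are excluded before
the check), and two introns are shared iff they occupy exactly the same
alignment nucleotide column — equal phase is implied and asserted.  The
density comparison against a genome-scale reference (supplied as two
integers: intron and coding-position counts, as such references come
from published genome statistics) is a 2×2 chi-squared without
continuity correction, df = 1, with a warning flag when an expected
cell is below 1.

## Synthetic data

The generators encode the study conditions the analyses assume.
Defaults: 43 species, 71 families (all observed), per-branch gene-loss
probability 0.15, protein families of 90–150 residues diverging by
uniform random substitution at 0.05 per site per branch (no indels —
clustering tests need controllable identity, not realism), intron
density target 4 per kb with phase bias (0.5, 0.3, 0.2), intron loss
probability 0.1 per branch below the gain, and a focal clade (~¼ of
species) whose intron presences are thinned with retention probability
1/1.5 to emulate a land-plant-like density deficit.

Design points worth knowing:

- **Fragments and decoys live in their source member's genome.**
  Fragments (60 % prefix truncations) are recruitment targets; decoys
  (residue-shuffled members) are negative controls for the profile
  stage.  Placing a decoy in a genome that lacks its source family
  would instead probe a different pathology — "best hit by default" at
  the RBH stage — because composition alone beats unrelated proteins.
  Keeping the real member alongside its shuffle pins each control to
  the stage it is meant to test.
- **Intron orthologs are equal-length (identity alignment)** so that
  projection correctness is decoupled from aligner quality; the
  character count is calibrated analytically from the tree's expected
  clade sizes so the realized density approaches the target.
- **The focal deficit is a thinning, and exactly that.**  The retention
  frequency of focal-species intron presences equals the deficit factor
  (tested); the realized focal/background density *ratio* additionally
  absorbs tree-geometry differences in expected presence per species,
  so tests assert the construction property and a significantly lower
  focal density rather than an exact ratio.
- All generators are bit-reproducible from `(seed, config)`; truth
  objects (planted families, loss events, gain branches, thinning
  events) are first-class outputs and the tests compare pipeline output
  to them, never to hard-coded numbers.

What passing tests show — and what they do not.  Exact family recovery
(ARI 1.0) on synthetic data demonstrates the machinery is correct under
substitution-only divergence with wide true/chance score separation; it
does not promise exact recovery on real proteomes, where domain
shuffling, composition bias and genuinely ambiguous paralogy blur the
separation the synthetic world keeps clean.  Likewise the EM recovery
experiment uses a *balanced* 8-leaf tree: parameter-recovery studies
need comparable information per branch, and with 500 families a
balanced tree gives every branch ≥ ~360 informative lineages (MLE
standard error ≈ 0.02), whereas the deep branches of a random
caterpillar tree are reached by too few families for a ±0.05 check to
be meaningful.

## Problem sizes and numerics

The default validation sizes — 10 genomes × 30 families for clustering,
500 families for EM recovery, ≥1000 random instances for the
likelihood and Dollo oracles, 1000 null replicates for chi-squared
calibration — were chosen so each check is statistically meaningful
while the whole suite runs in a few minutes on one CPU.  Numerical
guards: Gumbel scale floored at 1e-9; profile scores floored at −30;
posterior and loss probabilities clipped to [0, 1]; EM divisions guard
zero denominators by keeping the previous estimate; forced-presence
posteriors set to exactly 1.  Tie-breaks are lexicographic everywhere
(best hits, star selection, cluster nominations, merge order), which
makes every pipeline stage deterministic for fixed inputs and seeds.

## Known limitations

- The center-star alignment is a fallback, not a substitute for a
  profile aligner; supply external alignments for production use.
- Empirical Gumbel e-values are calibrated per search (pooled shuffled
  nulls), ignore sequence-length dependence within a database, and are
  not comparable across databases of very different composition.
- The pure-loss model has no gains, duplications or rate variation
  across families; characters violating single-origin (e.g. parallel
  intron insertion) will be misattributed by Dollo.
- HSP semantics: coverage comes from the single maximal-scoring local
  alignment; no HSP tiling is attempted.
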