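# Methods

`coevokit` asks whether two gene families that are genomic neighbours in
several mammals — one family single-copy in most placental mammals but
duplicated in murid rodents and cattle, the other showing the same
pattern — share an evolutionary history, and provides the statistical
machinery to answer that question on any pair of families. Three lines
of evidence are computed, plus the expression layer and a simulator that
makes every statistic testable without any external data.

## 1. Copy-number concordance

The species panel is a table of per-species copy numbers for the two
families. `contingency_from_profiles` cross-tabulates species by
(family-B copies, family-A copies), using the observed distinct copy
values as levels (not a fixed 0/1/2 grid), so the table has no all-zero
rows or columns by construction. `pearson_chi2_test` computes

    X² = Σ (O − E)² / E,   E_ij = (row_i total)(col_j total)/n,
    df = (r − 1)(c − 1),

with the p-value from the upper tail of the χ² distribution via the
regularized upper incomplete gamma function, and no continuity
correction. On the packaged 8-species panel this gives X² = 8.0, df = 2,
p = 0.018.

The asymptotic reference is shaky at this size (four of six expected
counts are below 5), so a permutation companion shuffles the family-B
column against family A and uses the add-one estimator
p = (1 + #{X²_perm ≥ X²_obs}) / (1 + n_perm). When the number of
distinguishable orderings of the family-B multiset is small (56 for the
packaged panel), `exact_permutation_independence_test` enumerates them
all instead. On the packaged panel all three routes agree that the two
families' copy numbers are dependent (asymptotic 0.018, exact 0.018,
Monte-Carlo within binomial error of exact).

**Caveat — species are not exchangeable.** The permutation null treats
species as interchangeable. Real species (and simulated ones) are not:
sister taxa share most of their duplication history, so both families'
copy-number vectors are autocorrelated on the same species tree. Even
when the two families evolve *independently* (coupling κ = 0 in the
simulator), the species-label permutation test over-rejects — we measure
a 17.6 % type-I rate at a nominal 5 % on 30-species panels, while the
identical machinery is exactly calibrated (4.4–4.6 %) once
exchangeability is restored by shuffling one family's species
assignment. This is the classical phylogenetic pseudoreplication
problem, and it applies equally to the asymptotic test. Concordance
p-values on species panels should therefore be read as evidence against
the *exchangeable* null, not as tree-aware inference; a tree-aware null
(permuting per-branch events rather than species labels) is the natural
extension and is deliberately out of scope here.

## 2. Identity-vector correlation

Within each family's alignment, `identity_vector` computes the percent
identity of every species' protein to a chosen reference species
(typically human). Identity between two aligned rows is computed column
by column without realignment: columns where both rows are gaps are
excluded; columns where exactly one row is a gap count as mismatches;
the denominator is the number of retained columns. Species with several
paralogs collapse to the **maximum** identity (the paralog closest to
the reference represents the species); the rule is logged.
`vector_correlation` then takes the Pearson correlation of the two
families' vectors over the species present in both (at least 3
required). A high correlation means species diverge from the reference
in step in both families.

## 3. Mirror-tree correlation

`msa_distance_matrix` converts a family alignment to a per-species
distance matrix with distance = 100 − identity%, collapsing
multi-paralog species by the **mean** over paralog pairs (logged;
maximum-vs-mean asymmetry with the identity vector is intentional — a
distance summarises the family, an identity vector picks a best
representative). `mirror_correlation` restricts both matrices to their
common species, sorted, and reports the Pearson correlation over
upper-triangle entries (k(k−1)/2 pairs for k species). The statistic is
invariant to label order and to affine rescaling of either matrix.

The permutation p-value shuffles the species-label assignment of the
second matrix before restriction — preserving both distance
distributions while breaking any shared structure — with the add-one
estimator, two-sided by default (`alternative="greater"` for the
one-sided version). All k! relabellings are enumerated exactly when k is
small. Note the null here is "no shared structure beyond the marginal
distance distributions", which is the right baseline: even two families
with independent rate variation correlate strongly if they share the
species-tree topology and branch lengths (the simulator measures a mean
r ≈ 0.81 at κ = 0), so the raw r must never be compared to 0.

## 4. Paralog-aware expression quantification

Reads (or ESTs) are scored against candidate transcripts. The package
consumes a generic (read, transcript, score) TSV so any aligner can sit
upstream; a bundled scorer computes the optimal **ungapped** placement
score of each read on each transcript (match +1, mismatch −2) by an
exhaustive vectorised scan — sufficient for the simulator's indel-free
reads, and exact where a seed-and-extend heuristic could miss.
`assign_best_score` keeps a read only when its best score both clears
`min_score` (a required, explicit parameter — no universal default is
defensible across scorers) and is *strictly* unique after rounding to 6
decimals; tied-best reads are discarded ex-aequo, which sacrifices depth
for specificity exactly where paralogs are least distinguishable.
Counts normalise to RPKM = count·10⁹/(length_nt·total_mapped), with
total_mapped defaulting to reads assigned to any transcript of the
sample's index (configurable to library size — the choice matters for
cross-sample comparability and is echoed in reports). Cross-sample
expression correlation is plain Pearson; constant vectors raise rather
than returning a silent 0.

## 5. The simulator and what a green test establishes

`synthdata` generates a stated world: a Yule-topology species tree with
Exponential(0.1) branch lengths; two families starting as single-copy at
the root; on each branch family A duplicates one copy with probability
`p_dup` while family B reuses A's indicator with probability `kappa`
(else draws its own), and each copy is lost independently with `p_loss`;
lognormal(0, `rate_sigma`) branch-rate multipliers likewise shared with
probability `kappa`; residue substitution as per-site Poisson events
with uniform replacement over the other 19 amino acids, giving the
closed-form expected identity 1/20 + (19/20)·exp(−(20/19)d) used as an
analytic oracle; and uniform short reads with uniform base errors.
Defaults (8 species, p_dup 0.15, p_loss 0.05, κ 1, 300 residues, 1,000
reads of 75 nt at 1 % error) mirror the motivating biological setting: an 8-species
panel with roughly two duplications across its ~14 branches and at
most one loss. Every generator is
bit-reproducible under its mandatory seed.

The simulator omits, on purpose: indels (rows stay pre-aligned, so the
statistics are tested in isolation from alignment quality), empirical
substitution matrices (uniform replacement buys the closed form; a
pluggable model hook exists), rate variation across sites, coupled
*loss* events (κ couples duplications and rates only), and any realism
in genome structure. Consequences measured and accepted rather than
hidden: at κ = 1 with losses enabled, independent losses decouple the
two families' leaf copy numbers often enough that the asymptotic test's
power on 8-species two-level panels is ≈ 0.5 (it is exactly 1 with
losses disabled, where the table is forced diagonal); and the κ = 0
type-I inflation described in §1. A green test on this world
establishes the statistics and their estimators, not the realism of any
biological conclusion.

## Numerical and design choices

* **Alignment.** Needleman–Wunsch and Smith–Waterman with affine gaps
  via Biopython's `PairwiseAligner`; defaults BLOSUM62, gap open 10,
  gap extend 0.5 (a gap of length L costs open + (L−1)·extend). Global
  mode leaves terminal gaps free — the convention of the classical
  global-alignment tools, and the only configuration that makes sense
  when orthologs differ greatly in length (e.g. a premature stop codon
  truncating one lineage's protein). Identity% and similarity% use the
  full alignment length (including gap columns) as denominator;
  similarity counts identities plus substitutions with strictly
  positive matrix score. Optimal alignments can be tied; arguments are
  aligned in canonical (lexicographic) order and swapped back, making
  identity/similarity symmetric in argument order. Local alignments
  with no positive-scoring segment return an empty alignment with
  score 0. `X` scores through the matrix's X row when present, else 0.
* **Offsets.** 1-based everywhere a biologist reads a position: motif
  matches, masking intervals (1-based *inclusive* TSV — documented
  against BED's 0-based half-open convention), conservation columns.
* **Motifs.** Ordered residue-set patterns (`CF[AT]C[FY]`, `CXXC`);
  the wildcard X matches any residue including X itself; scanning is on
  ungapped sequences, so matches never span alignment gaps; overlapping
  matches are all reported.
* **Permutation p-values** always use the add-one estimator (never
  exactly zero), require an explicit seed, enforce n_perm ≥ 99, and
  compare with a 1e−12 tolerance so ties in a discrete statistic count
  as hits.
* **Ties in read scores** are declared on values rounded to 6 decimals.
* **Degenerate inputs** fail loudly: single-level contingency tables
  direct the user to the permutation test; sub-minimum panels, constant
  expression vectors, missing references and out-of-bounds masks raise
  with the offending values listed.

## Known limitations

Beyond the simulator's omissions above: no tree inference (distance
matrices come from alignments, trees, or the simulator — inferring them
is upstream scope); the mirror statistic here is a plain Pearson over
distances, not any published server's internal variant, so its values
are comparable within this package only; the copy-number tests inherit
the exchangeability caveat of §1; and the bundled read scorer is
ungapped, so indel-bearing reads need an external aligner upstream.
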