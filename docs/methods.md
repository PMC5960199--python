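# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `phylodiag`, in the order the pipeline runs them.

## Substitution models and likelihoods

All likelihood machinery assumes a reversible continuous-time Markov chain
over k = 4 (nucleotide) or k = 20 (amino acid) states. The rate matrix is
built as `q_ij = s_ij π_j` from a symmetric exchangeability matrix S and
stationary frequencies π, rescaled so one unit of branch length is one
expected substitution per site (−Σ π_i q_ii = 1). Because Q is reversible,
`D^{1/2} Q D^{−1/2}` (D = diag π) is symmetric; transition matrices
`P(t) = exp(Qt)` come from its eigensystem, with entries clipped at zero
and rows renormalized to absorb roundoff (≤1e−15). The test suite
cross-checks this route against `scipy.linalg.expm` and asserts detailed
balance and Chapman–Kolmogorov identities.

Models provided: GTR (six free exchangeabilities, any frequency vector),
LG (fixed published exchangeabilities and frequencies, "+F" empirical
option), and JC for tests. Rate heterogeneity is the usual discrete-gamma
layer: K equal-probability categories of a Gamma(α, mean 1) distribution,
category rates equal to the conditional bin means (computed from the
regularized incomplete gamma with shifted shape; rates average exactly 1).
Default K = 4. `n_categories = 1` reduces exactly to the homogeneous
model.

Note on P(0): the eigendecomposition reproduces the identity only to
~1e−16 per entry, so an "impossible" column at all-zero branch lengths
yields a finite but astronomically negative log-likelihood rather than
−∞; site likelihoods are additionally floored at 1e−300 before the log.
Four-leaf site likelihoods cannot underflow double precision above that
floor, so no per-node scaling vectors are needed at this tree size.

## Quartet engine

A quartet has five branches. For topology (i,j | k,l) the site likelihood
is `Σ_x π_x L_i(x) L_j(x) Σ_y P_int(x,y) L_k(y) L_l(y)`, averaged over
gamma categories with equal weights — evaluated by pruning on unique site
patterns with multiplicities (patterns cap at 256 for nucleotides, which
is what makes 5,000-site quartets cheap). Columns in which any of the
four taxa is missing are excluded per partition; a quartet with zero
usable sites is "undetermined" and bookkept separately.

Branch lengths are optimized coordinate-wise (bounded Brent per branch,
bounds [1e−8, 10], round-robin over the five branches) until the
log-likelihood improves by <1e−6 or 100 rounds elapse. A caching
evaluator recomputes only the component affected by the branch being
moved (one tip partial or the internal transition matrix), which is the
difference between minutes and hours at acceptance scale. The coordinate
search on this 5-parameter concave-ish surface converges in a handful of
rounds; convergence failure is flagged, never raised.

Branch lengths are shared across partitions; each partition contributes
its own model (frequencies, exchangeabilities, gamma shape) additively to
the log-likelihood. Per-partition branch scalers are deliberately not
implemented: quartet data per partition are often a few dozen columns and
free scalers overfit them.

Per-partition model parameters are estimated once on the full supermatrix
and held fixed across quartets: frequencies are empirical per partition
(pseudocount 1; LG frequencies optional for amino acids), and GTR
exchangeabilities plus the gamma shape are refined by coordinate ascent
of the quartet likelihood of the four taxa with the most observed cells
(deterministic choice), two rounds of bounded scalar searches with branch
lengths re-optimized between rounds. Per-quartet re-estimation would be
unstable on sparse quartets and is avoided by design.

Topology weights are `p_i = exp(lnL_i − logsumexp(lnL))`. They are
invariant to adding a constant to all lnL and permute consistently under
leaf relabeling (both property-tested).

## Bowker symmetry screening

For each taxon pair, joint state counts are taken over columns where both
taxa are observed ('-', '?', and the fully ambiguous code of each alphabet
never count). Bowker's statistic sums `(n_ij − n_ji)²/(n_ij + n_ji)` over
unordered pairs with a nonzero denominator; df is the number of such
pairs; the p-value is the χ² upper tail with no continuity correction.
df = 0 (no off-diagonal disagreement) is defined as p = 1 — no evidence
against symmetry, keeping the heat map total. The heat-map classification
is `pass` iff p > α (strictly), matching the white-cell convention; pairs
with no jointly observed column are flagged `no_overlap` rather than given
a p-value. Rows/columns follow input taxon order.

Calibration is verified by simulation: under stationary homogeneous
two-taxon evolution at 10,000 sites the rejection rate at α = 0.05 sits
inside [0.03, 0.07] (2,000 replicates in the acceptance script); with the
default heterogeneous override (one lineage's A frequency raised from
0.30 to 0.55) power is essentially 1.

## Four-cluster likelihood mapping

Quartets are the full Cartesian product over the four hypothesis groups
(order fixes corner identity), or a seeded uniform subsample without
replacement. The weight simplex embeds in the triangle with vertices
(0,0), (1,0), (0.5, √3/2). Seven regions: corner C_i when p_i > 2/3,
else an edge between the two largest weights when min p < 1/6, else the
center. These boundary constants approximate the canonical
likelihood-mapping partition and are configurable arguments, since no
authoritative definition of the region geometry is assumed; all shipped
checks are robust to their exact values. Ties break toward the lower
region index (deterministically).

Region proportions are computed over determined quartets only. The
permutation-corrected support is the region-wise floored difference
`max(0, original − permuted)`, reported next to the raw values together
with the winning corner before and after correction.

## Permutation schemes

Scheme I permutes observed cells within each partition across taxa and
sites — cell-wise, not column-wise, because destroying phylogenetic
signal while keeping composition and mask requires cross-taxon mixing.
Scheme II draws every observed cell i.i.d. from a frequency vector: LG
frequencies (amino acid matrices only), empirical per-partition (default
for nucleotides), or uniform. Scheme III applies scheme II and then
permutes the observed/missing indicator within each partition, cell-wise
by default (column-wise available); cells that land on previously missing
positions receive fresh draws, and all missing cells are written as '-'.
Conservation contracts (residue multisets, masks, missing-cell counts)
are asserted exactly in tests. All schemes are deterministic given a
seed.

## Supermatrix assembly

Masked amino acid columns are removed gene-wise (with their codons on the
nucleotide track). Surviving columns inside a domain annotation pool into
one block per domain id across genes; leftover columns form one residual
block per gene. Pooling keys on the domain id only (no clan-level
pooling), and residual regions stay per-gene. Blocks concatenate in
lexicographic name order; absent taxa are filled with '-'.

"No phylogenetic information content" is proxied by two testable
conditions — fewer than four taxa with data, or no parsimony-informative
column (≥2 states each in ≥2 taxa) — and recorded as such in the block
report; this proxy is not an information-theoretic matrix-reduction
score. The required-groups filter keeps a block only if every configured
group has at least one member with at least one observed character in the
block (taxon presence with a fully gapped row does not count). The two
filters commute (property-tested).

Codon-aware schemes: NT123 emits three partitions per block (positions
1, 2, 3 by frame offset); NT12 emits two and removes third positions from
the scheme's column universe entirely, so its total length is exactly 2/3
of NT123's on in-frame blocks.

`mcmc_sample_budget` implements retained-sample bookkeeping for
multi-run MCMC designs (samples per run = generations / interval,
generation 0 excluded; floor(burnin × samples) discarded per run). The
reference design of three 3,000,000-generation runs sampled every 500
with 25% burn-in retains 13,500 trees.

## Synthetic data

The generator emulates the geometry of a domain-partitioned
target-enrichment study: a four-cluster tree (monophyletic groups g1..g4,
caterpillar structure within groups, configurable central internal
branch), per-gene amino acid (LG+Γ4, shape 0.8) and nucleotide (GTR+Γ4,
shape 0.8, exchangeabilities 1.2/3.0/0.8/0.9/3.2/1.0, frequencies
0.30/0.20/0.20/0.30 — unequal, transition-rich values typical of insect
nuclear data) tracks simulated independently on the same tree, whole-gene
taxon dropout at occupancy 0.8, 10% alignment masking, and domain
annotations drawn from a small shared pool so domains recur across genes.
Lineage-heterogeneous composition is induced by rebuilding the model with
override frequencies on all edges below a clade's MRCA — a genuinely
non-stationary process, which is what the symmetry screen is meant to
catch.

What it does *not* emulate: indels and alignment error (masks are random,
not error-driven), codon-level linkage between the tracks (the 3:1
correspondence is bookkeeping only; no codon model), site-specific
profiles/heterotachy, and biased gene occupancy (dropout is independent
across taxa and genes). Passing tests therefore demonstrate correctness
and calibration of the diagnostics under their own model assumptions, not
robustness to every real-data pathology.

Fixture shapes: `tiny` (8 taxa / 3 genes, seconds, drives the CLI smoke
tests), `small` (24 taxa / 20 genes), `paper_shaped` (183 taxa / 195
genes with hypothesis-style group sizes 2 / 5 / 42 / 134 at reduced gene
lengths).

## Problem sizes and determinism

Shipped checks use deliberately scaled problem sizes chosen to give
tight statistical bounds at desk scale: likelihood-mapping recovery on
200 quartets × 5,000 nucleotide sites (≥95% correct-corner at internal
branch 0.3; modal center at branch 0); symmetry calibration on 2,000
pairs × 10,000 sites; permutation contrasts on the 16-quartet
(2,2,2,2) hypothesis at 5,000 sites; supermatrix algebra on 100
randomized gene sets; branch recovery (±20%) on 50 replicates of 10,000
sites. Every stochastic component takes an explicit seed, and all
pipeline randomness flows from one top-level seed through named
substreams; fixed seed plus fixed inputs gives byte-identical reports.

## Known limitations

- No NEXUS I/O; partition files use the RAxML-style dialect only.
- The quartet engine handles exactly four taxa; it is not a tree builder.
- No invariant-sites category, codon models, or mixture models.
- Coordinate-wise branch optimization can in principle stall on ridges;
  with five parameters and the convergence cap this has not been observed
  outside degenerate all-identical inputs, which are handled explicitly.
- Real-data region proportions from published studies are not reproduced
  here: that requires the deposited supermatrices and cluster-scale
  inference; the package validates the method on data with known truth
  instead.
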