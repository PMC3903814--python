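# Methods

## Model

`mutorder` treats the sampled tumor cells as the leaves of an unobserved
genealogy and mutation events as points on its branches. For a site pair
(x, y), the mutations are *ancestrally related* (x→y or x←y) when one
lies on the root-to-leaf lineage through the other, and *independent*
(x⇎y) when they lie on lineages with disjoint descendant sets. The
observed data enter through a per-cell likelihood that mixes the
relation-conditional distribution of the *true* binary genotype pair
(i′, j′) ∈ {0,1}² through a sequencing-error channel into the *observed*
pair (i, j) ∈ {0,1,2}²; Bayes' theorem then scores the three relations
per pair. Only pairwise relations are modeled — the joint ordering of
all sites is combinatorially infeasible — and the tree is assembled from
the pairwise calls afterwards.

Assumptions: one mutation per site (infinite-sites), neutral
Wright–Fisher genealogy with constant population size, globally constant
error rates, and missingness that is ignorable (cells missing at either
site of a pair are simply excluded from that pair's likelihood —
"pairwise complete").

## Coalescent prior

A genealogy of n cells is simulated as a Kingman tree: starting from n
lineages, a uniformly chosen pair merges until one remains, with interval
durations T_k ~ Exponential(rate k(k−1)/2) (time in coalescent units of
2N generations) for k = 2..n. The stem interval T_1 — the lone lineage
from the tumor's earliest mutation down to the sample's MRCA — is set
deterministically from the stem-time fraction α via
T_1 = α/(1−α) · Σ_{k≥2} T_k, so T_1/ΣT_k = α exactly in every draw.

Mutations are placed with probability proportional to branch length: a
specific lineage during interval k is hit with probability
T_k / Σᵢ i·Tᵢ, and the position within the interval is uniform. (A
time-uniform-then-random-extant-branch scheme would instead weight a
lineage by T_k/(k·ΣTᵢ); we use the branch-length-proportional form, the
standard infinite-sites mutation model, which is also what the placement
probability above states.)

Per mutation pair, the relation is read off the laminar structure of
descendant leaf sets: nested ⇒ ancestral (equal sets mean the same
lineage chain, ordered by time), disjoint ⇒ independent. Tallies over
`b_tree` genealogies × `b_mut` pairs give

* the order prior: ancestral draws are pooled and split evenly between
  the two directions, so Pr(x→y) = Pr(x←y) holds exactly rather than up
  to Monte-Carlo noise, and Pr(x⇎y) = 1 − 2·Pr(x→y);
* the conditional true-genotype tables Pr((i′,j′)|x∼y), tallied **per
  leaf**: each simulated pair contributes one observation per cell,
  which is the unit the per-cell likelihood consumes. The backward table
  is the exact transpose of the forward one, and independent-pair
  single-carrier mass is symmetrized across (1,0)/(0,1). Three entries
  are structural zeros by construction: a descendant cannot be carried
  without its ancestor (forward (0,1), backward (1,0)) and independent
  mutations are never co-carried ((1,1)).

Defaults `b_tree = 1000`, `b_mut = 10000` follow the original analysis.
Tables are cached on (n, α, b_tree, b_mut, seed): leave-one-out reuses
one table for all replicates (the prior depends only on the cell count),
and grid tuning reuses tables across fits.

## Error model

FD = Pr(observe 1 | true 0) = 6.04×10⁻⁵ and
AD = Pr(observe 0 or 2 | true 1) = 0.4309 are the published
MDA single-cell exome rates of the packaged dataset; dropout splits
evenly between the two homozygous calls. A residual rate
c = Pr(observe 2 | true 0) is exposed as a parameter but defaults to 0
(it is not determined by FD/AD and is assumed negligible). True
genotypes are binary: a genuine homozygous mutation at a base pair is
considered too unlikely to model, so observed 2s arise only through
dropout (or c).

## Likelihood, posterior, numerics

All likelihood arithmetic is in log space with explicit −∞ for
structurally impossible observations; posteriors are normalized by
log-sum-exp. Degenerate cases are flagged rather than guessed: a pair
with no jointly observed cells, or whose data are impossible under all
three relations, is marked unclassifiable and contributes no edge to the
order graph. Exact posterior ties are broken by preferring independent,
then forward — refusing to invent a direction without evidence — and the
tie is recorded.

## Stem-fraction tuning

α is fitted on a grid (default 0.01..0.99, step 0.01) by minimizing
Σ_{i,j∈{0,1,2}} (p_ij − f_ij)², where f_ij pools observed genotype pairs
over all ordered site pairs and jointly observed cells, and p_ij is the
model marginal at that α. One prior seed is shared across grid points
(common random numbers), which keeps the objective curve smooth in α so
the argmin is not dominated by Monte-Carlo jitter. The fit is intended
for the *full* site panel of an assay (the larger the panel, the less
pair-sampling noise in f); the tree can then be built for a curated
subset at the fitted α.

A documented statistical limitation: all sites of one tumor share one
genealogy, so f_ij converges (as sites grow) to the *conditional*
pair-genotype distribution of that genealogy, not to the model marginal.
The estimator is consistent in the ensemble sense — averaging f over
independent genealogies recovers α exactly on the grid — but a single
dataset carries irreducible genealogy noise. Because f responds steeply
to α only when the stem dominates total branch length, single-dataset
recovery is precise for large α (the regime of the packaged dataset,
α̂ ≈ 0.9) and widens substantially below α ≈ 0.5; the recovery test in
the suite measures exactly this.

## Mutation tree

Each pair whose maximum-posterior relation is directed contributes one
edge with weight −log posterior ≥ 0; independent pairs contribute none.
The tree is the minimum-weight spanning arborescence over all candidate
roots (computed with networkx's Chu–Liu/Edmonds implementation;
minimizing total weight is equivalent to trying every root and keeping
the cheapest rooted tree, and to maximizing the posterior product). If
no site reaches all others the arborescence is built over the largest
root-reachable set and the remaining sites are flagged as excluded
rather than failing. Cycles in the raw order graph — which arise from
errors and missingness and are why transitive reduction alone cannot
build the tree — are reported as a diagnostic only.

Under exactly zero error rates, every strictly nested carrier pair has
posterior 1 for its direction, so all ancestor→descendant edges carry
weight 0 and the minimum arborescence is tie-degenerate among valid
ancestors: the inferred branch set is then one spanning choice from the
planted partial order (every branch correctly directed), not necessarily
its transitive reduction. With nonzero error rates the weights are
generically distinct and ties do not arise; residual ties would be
resolved by the deterministic ordering of the edge list.

## Synthetic data

`simulate_dataset` runs the generative model forward: one genealogy
(topology + intervals at a chosen α), one branch-length-uniform mutation
per site, leaf genotypes by subtree membership, FD/AD corruption per
call, then independent uniform masking. Defaults mirror the packaged
study: 58 cells, 18 sites, α = 0.92, published FD/AD, 45% missingness
(the 712-site preset uses 58%, the full assay's missing rate). It
emulates the statistical structure the inference assumes — and only
that: no doublets, no copy-number events, no site- or cell-specific
error rates, and missingness independent of genotype, whereas real
dropout and coverage failures are correlated within cells and regions.
Passing recovery tests on this generator therefore validates the
inference machinery under its own assumptions, not robustness to
assay-specific artifacts.

## Problem sizes in the test suite

Unit tests run the Monte-Carlo machinery at reduced sizes (tens of
genealogies × hundreds of pairs), which leaves posterior classification
qualitatively stable; the end-to-end checks of the packaged dataset (the
full tree and the 58 leave-one-out replicates) run at the published
sizes, b_tree = 1000 × b_mut = 10000. The α-recovery check uses
b_tree = 400 × b_mut = 1000 with one shared prior grid, sized so that
prior Monte-Carlo error is small against the genealogy noise it
measures.

## Data fidelity note

The packaged 18 × 58 table is transcribed from the published article.
Its per-site tallies at the two extremes (DLEC1 18/21 = 0.857 observed
mutated fraction, PABPC1 4/40 = 0.100) differ slightly from the rates
printed in the original figure (0.864, 0.122) — consistent with one
extra non-missing mutated call per row in the journal original. The
ranking of sites and every downstream result reported by the acceptance
script are unaffected.
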