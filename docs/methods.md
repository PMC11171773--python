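# Methods

This note records the statistical model implemented by `tcsignal`, the
numerical choices behind it, what the synthetic-data generator does and
does not emulate, and the limitations a user should know before
applying the pipeline to real data.

## Prior knowledge network

The PKN is a directed multigraph of genes, proteins, complexes and
metabolites.  Edges carry a sign (activation / repression / unknown), a
mechanism (`transcriptional_regulation`, `ppi`, `metabolic`,
`correlation`, `virtual`) and an influence-factor (IF) reliability
score.  Edges with IF < 0.86 are **flagged** low-confidence rather than
deleted — path search skips them by default but every statistic that
does not traverse paths still sees them, and a single switch
(`include_low_confidence`) restores them.  Complexes are decomposed by
virtual member→complex activation edges, so a signal can flow from a
subunit into the assembled regulator; the direction is a convention
(nothing in the data dictates it) and is isolated in `expand_virtual`.
Parallel edges from different sources are kept as a multiset; path
search collapses each pair to its max-IF representative.

Two views drive the analyses: the dysregulation stage uses the
correlation plus transcriptional layers (duplicate pairs collapsed to
one unordered pair), while path search uses the directed causal layers
(transcriptional, metabolic, virtual forward; PPI both directions;
correlation never — co-expression is evidence of dysregulation, not a
causal conduit).

## Edge dysregulation and driver calling

**Sample augmentation.**  Dense time courses have few replicates, so
each timepoint group is augmented with a pseudo-sample equal to the
per-gene group mean; unreplicated data additionally receive the
midpoint of the two timepoints, guaranteeing three points per side.
The augmentation is a smoothing device, not extra evidence: it enters
both the observed edges and the permutation null identically.

**Density estimate.**  For an edge (gᵢ, gⱼ) each group's points
(xᵢ, xⱼ) become a mixture of axis-aligned Gaussian kernels with
per-axis Silverman bandwidths, h = 0.9·min(sd, IQR/1.349)·M^(−1/5),
computed on the *pooled* M points of both groups so that both densities
share one scale (a `bandwidth_scale` multiplier is exposed).  Both
densities are evaluated on a common grid — by default the M×M Cartesian
product of the observed coordinate values, which makes the discrete
double sum of the divergence well defined; a regular padded grid is
available in the configuration and is what the numerical-oracle tests
use.  Densities are floored at 10⁻¹² and renormalized before the
symmetrized KLD is taken, so log(0) and division by zero cannot occur.

**Degenerate clouds.**  When the pooled 2×2 covariance is rank
deficient or its condition number exceeds 10⁸ (collinear or constant
expression), the points are rotated to principal axes and the
degenerate axis receives seeded Gaussian jitter of 10⁻³·σ_max; all
identical points jitter on both axes.  This keeps the kernel estimate
full-rank without visibly moving well-behaved data.

**Permutation null and empirical p.**  The null scores uniformly random
unordered expressed gene pairs that share no edge in the selected view
(10,000 draws by default; sampling is with replacement, with a warning
when fewer admissible pairs exist).  The empirical p-value is add-one
smoothed, p = (1 + #{null ≥ obs}) / (1 + N), strictly positive so the
downstream logarithm is defined.

**Gene-level aggregation.**  A gene's edge p-values combine via
Fisher's χ² = Σ −2 ln p with Brown's moment correction for dependence.
The covariance of −2 ln pᵢ and −2 ln pⱼ is approximated by the
Kost–McDermott polynomial 3.263ρ + 0.710ρ² + 0.027ρ³, where ρ is the
Pearson correlation of the two partner genes' expression profiles.  ρ
is estimated **across the full series**, not the six-or-so samples of
one segment: with so few samples the correlation estimate has sd ≈
0.45, and because the polynomial is convex this noise systematically
inflates the variance estimate and halves a high-degree gene's
effective df even when its partners are independent.  With one edge, or
all ρ = 0, the statistic reduces exactly to Fisher with df = 2k.

**Properties.**  The KLD is non-negative, zero iff the two normalized
densities coincide on the grid, and bit-exactly symmetric under group
swap (the two directed divergences are averaged; the grid is built from
sorted pooled values so it is order-invariant).  Under a global null
the empirical edge p-values are marginally uniform.  Two dependence
effects matter when *checking* that uniformity with a pooled KS test:
all edges share one estimated null (its ECDF error, ~N^(−1/2), shifts
every p coherently), and edges sharing a gene share that gene's
replicate noise.  Neither is a miscalibration — the type-I error rate
at α = 0.05 stays within Monte-Carlo error of 0.05 — but both inflate
the KS statistic, which is why calibration experiments here use
degree-homogeneous networks and, in the acceptance script, pool edges
from independent replicate simulations.

**A scale note.**  Because the bandwidth comes from the pooled spread,
the statistic measures separation *relative to* that spread; a step
change much larger than the replicate noise saturates around two
pooled-sd of separation.  Detection of a driver therefore leans on the
breadth of its edge signature (every incident edge shifts) rather than
on the raw magnitude of any single edge's divergence.

## Upstream-regulator enrichment

Every node with outgoing transcriptional edges is evaluated twice, once
per pseudo activation state.  Edge sign × state gives the predicted DEG
direction (unknown signs match either direction).  Over the node
universe of the regulatory view after virtual expansion (size n):

* a — targets of r that are DEGs matching their own edge's prediction;
* b — other PKN DEGs matching any direction r's edge signs predict;
* c — remaining targets of r;  d = n − a − b − c.

Splitting the "pattern-matching DEG" pool into the per-edge-matched
targets and the any-direction-matched non-targets keeps every cell
non-negative even for regulators with mixed-sign regulons.  The
one-sided Fisher exact p is the hypergeometric upper tail
P(X ≥ a), X ~ Hypergeom(n, a+b, a+c), computed by summing the point
probabilities of the tables (a+k, b−k, c−k, d+k) for k = 0 … min(b, c)
in log-factorial space (`scipy.special.gammaln` + `logsumexp`); the
bound min(b, c) is exactly the set of tables with non-negative cells,
which makes the sum identical to the hypergeometric survival function —
the property the test suite verifies exhaustively for n ≤ 40.
Benjamini–Hochberg FDR runs over the doubled regulator × state family;
raw p-values are reported alongside.

DEG calling itself is a per-gene Welch t-test with BH correction
(FDR ≤ 0.1, |fold change| ≥ 1.5, comparisons inclusive at the
boundary), replaced by fold-change-only calls when a side has a single
replicate.  With triplicates the Welch degrees of freedom are the
binding constraint: even an 8σ step yields p ≈ 10⁻³–10⁻², so small
regulons sit near the BH threshold when few genes are truly changed —
a power limitation of small-n designs, not of the implementation.

## Path collection and temporal statistics

Shortest paths are found by an in-package breadth-first search that
keeps **all** predecessors at minimum distance and backtracks every
minimum-length path (lexicographic order; an optional per-pair cap
guards pathological graphs).  A driver that is itself a significant TF
contributes a length-0 path.  Unreachable pairs are recorded with a
reason code.  networkx serves as the independent oracle in tests, never
as the implementation.

Node frequency in a segment counts path *memberships* (a node on three
paths counts three), preserving hub weighting.  Mean and population sd
are taken across all segments, absent segments counting zero.  The
per-segment Z-test uses the one-sided upper-tail normal survival
(computed via erfc; sd = 0 degenerates to z = 0, p = 1).  Callback
regulators are nodes that terminate a path in segment e and originate
one in segment r with 0 < r − e ≤ 5 (segment units, strictly forward;
length-0 paths count as both terminus and source, but the same-segment
case is excluded by r > e).  Pruning keeps the top 10% of nodes by
total frequency (ceiling count, boundary ties kept) plus callback
regulators significant (p < 0.05) in their reuse segment; kept edges
are path-view edges lying on at least one collected path with both
endpoints kept.  The top-decile cut is global across segments; a
per-segment variant would require only changing the totals it ranks.

## Hypernodes and GO flow

The pruned network, direction dropped and one unit of weight per kept
edge, is clustered by Louvain modularity optimization
(`networkx.community.louvain_communities`, seeded, resolution 1.0 by
default).  Edges whose endpoints share a regulon or complex have their
weight multiplied by a boost (default 2.0, applied once even when both
memberships are shared), encouraging functionally coherent hypernodes.
Hyperedges aggregate the kept edges between two communities with a
unanimous / mixed sign summary and edge-count weight; the boost and
resolution are configuration values because no principled default
exists — the tests document the boost's effect by constructing a
marginal case that flips at boost 4.

The GO view propagates annotations up the parent DAG (cycle detection
included), restricts candidate terms to those covering at most half of
a segment's DEGs (over-general terms are uninformative), and greedily
picks the term adding the most uncovered DEGs until the best candidate
adds fewer than 3 genes or more than half of its DEGs are already
covered; ties break by smaller term size, then lexicographically.
Selected terms become per-segment nodes; adjacent-segment nodes link
with weight equal to their shared covered genes.  All thresholds are
configuration values surfaced on the CLI.

## Synthetic data

The generator produces what the analyses assume: a preferential-
attachment signed regulatory core (activation 0.7 / repression 0.3, IF
~ Uniform(0.5, 1)), a correlation layer restricted to co-regulated
sibling pairs, regulons (out-neighborhoods of the largest regulators),
small complexes with intra-complex PPI cliques, and log2 expression
with per-gene baselines Normal(10, 1), i.i.d. replicate noise and
step-type planted signals.  A `topology="uniform"` variant places the
same number of edges between uniformly random pairs; calibration
experiments use it because hub genes couple many edge statistics and
distort pooled uniformity tests.

The planted signal is deliberately sparse: each planted driver's own
expression steps by +δ at the onset segment, and one cascade
(driver → intermediate → TF, chosen as a genuine shortest path through
modest-degree nodes) carries the step, sign-aware, into the terminal
TF's small regulon.  By default the whole cascade fires within the
onset segment — signaling is fast relative to the sampling interval —
while a `lag` parameter spreads it one edge per `lag` segments for
studying delayed propagation.  Callback events are planted by
re-perturbing the first cascade's terminal TF (and, inverted, its
regulon) a configurable number of segments later, so the TF is a path
terminus at onset and a path source at reuse.  Sparsity is not
cosmetic: every shifted gene contaminates a fraction of the permutation
null's random pairs, and a generator that shifted whole regulons of hub
drivers would erase the very contrast the driver statistic relies on.

What the generator does **not** emulate: array-level artifacts (dye or
probe effects), heteroskedastic or intensity-dependent noise,
autocorrelated temporal drift, feedback dynamics, or partial/graded
regulation — steps are clean and persistent.  Passing tests therefore
demonstrate correctness of the machinery and recoverability of clean
planted signal at realistic sizes, not performance on real microarray
noise.

## Problem sizes and defaults

Defaults follow the published protocol wherever one exists: IF
threshold 0.86, DEG FDR 0.1 and fold change 1.5, 10,000 null draws,
driver and TF α = 0.05, callback window 5, top-decile fraction 0.10,
Z-test α = 0.05.  The bundled experiments run at 200 genes / 600
regulatory edges / 8 timepoints; driver-recovery experiments use 3
replicates and a 1,000-draw null, calibration experiments pool ~2,000
edges, and end-to-end fixtures use 4 replicates so that small planted
regulons survive the BH threshold (see the DEG power note above).  All
randomness flows from one root seed through recorded per-stage derived
seeds, and a rerun from the same manifest is byte-identical.

## Known limitations

* Sign consistency along a signaling path is not enforced — an
  activating path and a repressing path are collected alike.
* The driver statistic is relative to the permutation null from the
  same data; if a large fraction of the transcriptome changes between
  two timepoints, the null absorbs the signal and sensitivity drops.
* The FET universe n counts the regulatory view's nodes; other
  universes (expressed genes only, array content) are defensible and
  would shift absolute p-values.
* Louvain is a heuristic optimizer; determinism is guaranteed under a
  fixed seed, optimality is not.
* With unreplicated timepoints DEG calling degrades to fold-change
  thresholds and the t-based FDR control is unavailable.
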