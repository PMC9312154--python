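# Methods

## The model

`rwdir` ranks the unlabeled vertices of a three-class RNA interaction
network (mRNA, miRNA, lncRNA) by their probability of being related to a
disease of interest, given a partial labeling of the vertices as
*related*, *irrelevant* (associated with other diseases only) or
*unlabeled*.

### Heterogeneous adjacency and transfer parameters

The network is undirected, unweighted and simple.  Vertices are held in a
canonical order (mRNAs, then miRNAs, then lncRNAs, lexicographic within
class), so the adjacency H is a symmetric 0/1 matrix with a 3×3 block
layout.  Three transfer parameters apportion a walker's transition mass
across classes from ratios of block edge counts:

    λ = |mRNA–miRNA|   / (|mRNA–mRNA|   + |miRNA–miRNA|)
    δ = |mRNA–lncRNA|  / (|mRNA–mRNA|   + |lncRNA–lncRNA|)
    θ = |miRNA–lncRNA| / (|miRNA–miRNA| + |lncRNA–lncRNA|)

On the real colon-cancer network's published counts (7408, 389, 604, 569,
94, 587) these are λ ≈ 0.0730, δ ≈ 0.0117, θ ≈ 0.5911: lncRNA–miRNA
coupling is strong, mRNA–lncRNA coupling weak.

The block transition matrix row-normalizes each adjacency block
separately and scales it by λ/δ/θ for cross blocks and by the remainder
(1 minus the class's two cross parameters) for the diagonal block.
Each parameter must lie in [0, 1] and each class's two cross parameters
must sum to at most 1; otherwise the diagonal weight would be negative
and the constructor raises rather than clamping.  Two degenerate cases
are resolved explicitly:

* **Dangling blocks.** A vertex with no edge into a positively weighted
  block would emit a sub-stochastic row; its row is renormalized, which
  redistributes the missing mass proportionally over its non-empty
  blocks.
* **Zero rows.** Zero-degree vertices keep an all-zero row.  The same
  can happen to a positive-degree vertex exactly at a parameter boundary
  (e.g. θ = 1 for a lncRNA vertex with only lncRNA neighbors: all of its
  class budget points at a block it has no edges into, and every block
  it does reach has weight 0).  The row stays zero; the restart term of
  the walk re-injects the leaked mass, and such vertices rank last.

### The incentive walk

The walk iterates Pt+1 = α·WᵀPt + (1−α)·P0 with W row-stochastic (rows
are sources, so the transpose action moves mass source → destination).
α defaults to 0.85, the conventional restart-walk retention; it is
exposed because results depend on it.  P0 starts as the indicator of the
maximum-degree related vertex (ties to the lowest canonical index).
Each iteration:

1. vertices whose Pt entry changed by more than `visit_eps` (default
   1e−12, a float-noise guard only) are marked visited;
2. each newly visited related vertex is added to P0 with weight 0.1 and
   P0 is renormalized — idempotent per vertex, so the seed is never
   down-weighted;
3. every visited irrelevant vertex has its Pt entry divided by its
   degree (zero-degree vertices skipped with a warning), and Pt is
   renormalized after the sweep.

Renormalizing P0 and Pt keeps the update a convex combination; without
it the incentive would silently inflate total restart mass above 1.

### Entropy-guided belief propagation

Once the walk has covered the graph — every vertex reachable from the
seed visited, or no new visit for 5 consecutive iterations (which
handles components the seed cannot reach) — each vertex receives a
two-label belief (m1, m2), m1 + m2 = 1.  Labeled vertices are clamped:
related = (1, 0), irrelevant = (0, 1).  Unlabeled vertices are
initialized from the visit ranking, m1 = (h − rank)/h with rank 1 the
largest Pt entry, so vertices the walk frequents start with high m1.
(The opposite rank orientation would give the most-visited vertex m1 ≈ 0,
inverting the algorithm's purpose.)

Every subsequent iteration:

* the binary entropy E(v) = −m1·log2 m1 − m2·log2 m2 is computed;
* the transition matrix is rebuilt so that row v distributes its mass
  over the closed neighborhood N+(v) (neighbors plus v itself)
  proportionally to the *destination's* entropy — the walker seeks
  uncertain vertices.  If the whole closed neighborhood has zero
  entropy the row falls back to uniform over N+(v).  This rebuilt W
  drives both the Pt update and the message passing;
* beliefs propagate: vertex i aggregates m_k(j)·W(j, i) over its
  in-neighbors, normalizes over the two labels, and labeled vertices are
  re-clamped.  A vertex receiving no mass keeps its beliefs; in
  particular an unlabeled vertex whose belief reaches an exact extreme
  has zero entropy, attracts no messages, and stays frozen (it ranks at
  the corresponding end).

Because the destination entropy appears in every incoming message, it
cancels in the two-label normalization: the update is a weighted average
of in-neighborhood beliefs with weight 1/Σ_{k∈N+(j)} E(k) per source j —
confidently surrounded sources weigh more.

The run stops when the L1 change of Pt drops below `tol` (default 1e−6,
`max_iter` 1000) and, for the full algorithm, beliefs exist.  Unlabeled
vertices are ranked by final m1, ties broken by final Pt then canonical
index.  When the network has no unlabeled vertex the belief machinery is
vacuous and skipped entirely, so the Pt trajectory coincides with the
no-entropy variant.

**Known limitation — sustained oscillation.** The per-iteration penalty
(divide, then renormalize) makes the Pt map nonlinear, and on some small
networks the late-stage dynamics settle into an exact period-2 cycle
instead of a fixed point.  The run is then flagged `converged=False` and
the last iterate is used; rankings are still deterministic.

### Baselines

* **TRWR** — traditional restart walk: plain degree-normalized W, restart
  vector with weight 0.1 on every related vertex (normalized, i.e.
  uniform over the related set), no label updates; unlabeled vertices are
  ranked by stationary Pt.  The iterative solution matches the closed
  form (1−α)(I−αWᵀ)⁻¹P0.
* **No-entropy ablation** — incentives and penalties only; no belief
  state is ever allocated; ranking by final Pt.

## Evaluation

Leave-one-out over the related vertices: fold r relabels the held-out
related vertex *and* the whole sampled negative set (drawn uniformly
without replacement from the irrelevant pool, one negative per positive)
as unlabeled, runs the algorithm, and records the held-out score (m1 for
the full algorithm, Pt for the baselines).  Relabeling the negatives is
necessary: an irrelevant-labeled vertex has m1 clamped to 0 and would
make the comparison trivial.  Each negative's score is its mean over all
folds, so no single fold's seed choice dominates it.  The ROC curve is a
threshold sweep over every distinct score with integer tp/fp counts, and
the AUC is the integer trapezoid numerator divided by 2·n_pos·n_neg —
exactly the Mann-Whitney statistic with half-credit ties, with no
floating-point discrepancy between the two formulations.

## Synthetic data

The generator plants a planted-partition structure: a "related
community" (the related vertices plus a configurable number of unlabeled
members) whose internal edge probabilities — within and across classes
alike — are multiplied by a homophily factor ≥ 1 (clamped at 1), while
irrelevant vertices sit outside the community at background density.
This is the minimal structure the incentive walk exploits: disease RNAs
sharing neighborhoods across all six edge classes.

`table4_like_spec` scales the real network down to h = 150 (110 mRNA,
20 miRNA, 20 lncRNA) with block densities chosen so the *expected* block
edge counts are one tenth of the real network's six counts; the expected
λ, δ, θ therefore sit in the real regime (θ ≫ λ > δ), which the test
suite verifies by Monte-Carlo at neutral homophily.  Its planted module
has 24 members, 16 related — known disease RNAs dominate their module,
and the module's dense blocks saturate at the default homophily of 8, so
members' neighborhoods are mostly related vertices, mirroring the
observation on the real network that the top candidates' neighbors were
essentially all related.  45 irrelevant vertices model the large share
of RNAs annotated to other diseases.  Replicate counts in the test suite
and the acceptance script (20 replicates) keep full three-method LOO
comparisons to a few seconds at this scale.

### What the fixtures do and do not show

The generator reproduces the class structure, the block edge-count
ratios and label homophily, but *not* two features of real disease
networks: hub-dominated degree distributions, and — importantly —
negatives that are interleaved with the disease module (other-cancer
RNAs share pathways and neighbors with the disease RNAs).  On the
planted fixtures the negatives are structurally remote from the module,
so plain walk proximity is a near-perfect classifier and the Pt-ranked
variants (TRWR and especially the no-entropy ablation) saturate near
AUC 1.  The belief-propagation score, whose fixed point depends only on
local label composition and forgets the walk's proximity signal, is
noisier in this regime: all three methods beat chance by a wide margin,
but the planted fixtures do not reproduce the real-network result that
the full algorithm outranks both baselines, and the corresponding
ordering test is expected to fail on them.  Passing tests on these
fixtures therefore demonstrate correctness and calibration of each
component, not end-to-end superiority of the full method on real data.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| alpha | 0.85 | probability of following W rather than restarting |
| tol | 1e−6 | L1 convergence threshold on Pt |
| max_iter | 1000 | iteration cap; non-convergence is flagged |
| visit_eps | 1e−12 | minimum Pt change that counts as a visit |
| stagnation_window | 5 | iterations without new visits before coverage is declared |
| incentive weight | 0.1 | P0 weight granted to a newly reached related vertex |
| TRWR restart weight | 0.1 | per-related-vertex P0 weight in the baseline |
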