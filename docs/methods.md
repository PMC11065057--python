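# Methods

## Model

The package treats the brain as a transport system: regions are cities,
structural connections (SC) are roads whose quality is the connection
strength, and functional connections (FC) are traffic demand between city
pairs.  Route choice follows an economy assumption — travelers prefer short,
well-paved roads — so the cost of one step between adjacent regions is the
Euclidean distance between their centroids divided by the SC strength of
that edge.  The most efficient pathway (EP) for a region pair is the simple
path of at most `max_steps` edges (default 4) minimizing the summed step
costs.  An absent structural edge (SC = 0) has infinite cost: tractography
absence means no road, and no smoothing is applied.

The USFC value of a structural edge is the sum of the FC values of all
routed pairs whose EP traverses it.  Default accumulation sums |FC|
("absolute" mode): traffic is a magnitude, and signed summation would let
opposite-sign flows cancel, contradicting the load interpretation.  A
"signed" mode is kept as an option; which convention underlies any given
published map is generally not determinable from the map alone, so both are
exposed and the choice is recorded in the run report.

Which pairs are routed is a policy: `all_nonzero` routes every pair with
FC ≠ 0; `masked` routes only pairs flagged in a per-subject significance
mask (a helper builds such masks from Pearson r values via the t-transform
with per-subject BH-FDR at 0.05, given the time-series length).  The `auto`
default uses masks when all subjects have one.  Pairs with no admissible
route within the hop limit are recorded as unroutable and logged, never
silently dropped.

## Routing algorithm

Optimal substructure holds only per hop count, so the search keeps the best
state per (node, number of edges): a hop-layered relaxation over the cost
adjacency, O(max_steps · E) per source, exact, no heuristic.  Stored states
carry their full node sequence; extensions that revisit a node are skipped
(with strictly positive costs a revisit can never be optimal, but the
sequence is needed for tie-breaking).  Ties are broken deterministically:
smaller cost, then fewer steps, then lexicographically smallest node-index
sequence.  `brute_force_pathway` — exhaustive enumeration of all simple
paths up to the hop limit with the same tie-break — serves as an independent
oracle; the suite checks exact agreement (cost to 1e-9 and the tie-broken
sequence) on hundreds of random graphs.

## Group statistics

Edge-wise group inference uses one-sample t-tests against zero across
subjects, with Benjamini–Hochberg FDR at alpha = 0.05.  Only edges observed
nonzero in at least one subject enter the FDR family: untested structural
non-edges would otherwise dilute the correction.  An edge with zero variance
and nonzero mean has an undefined t statistic; it is declared significant
with p := 0, since a constant nonzero load is maximal evidence against the
zero null.

Regional load is the sum of a region's incident edge values, computed on the
significance-masked group mean (group maps are reported after FDR
correction).  Outlier regions exceed the upper IQR fence q3 + 1.5·IQR, with
quartiles by linear interpolation between order statistics — the most common
convention, stated here so numbers are reproducible.  Only the upper side is
flagged: the question is which regions carry disproportionately heavy load,
and a symmetric fence on a right-skewed load distribution would mark
unremarkable low-load regions.

Network-level values are per-subject means of regional load over each
network's regions, compared pairwise with paired t-tests across subjects
(BH-corrected).  Whether such comparisons should run across subjects or
across regions is genuinely open; across-subjects is the default and an
across-regions variant sits behind a flag.

## SC–FC coupling along routes

Routes are reduced to those consistent across the cohort: per pair, the
modal exact node sequence, kept only when its frequency strictly exceeds the
threshold (default 0.5 — "more than half").  Exact-sequence identity is the
default because it is strict and unambiguous; a step-count-only identity is
available behind a flag.  Modal ties drop the pair with a warning.  For each
consistent route the structural value is the arithmetic mean SC over its
consecutive edges averaged across subjects, and the functional value is the
group-mean FC of the pair.  Routes are classified by the sign of group-mean
FC (exact zeros excluded, logged) — classification after group averaging,
not per subject — and grouped by step count; Spearman's rho is computed per
group with at least 3 routes.  P-values use the t approximation for n ≥ 10
and an exact permutation enumeration (all n! pairings of the rank vectors)
below that: 3- and 4-step groups are routinely small and the approximation
is poor there.  Four-step groups are computed like any other; they are
simply expected to be small or empty because hop-limited routing rarely
produces a modal 4-step consensus.

## Graph metrics

Connectivity weights measure strength, so shortest-path metrics use edge
length = 1/weight (standard for connectivity matrices; zero weight = no
edge).  FC enters as |FC| — negative correlations carry no meaningful path
length; an option to zero out negatives instead exists.  Global and nodal
efficiency are means of inverse weighted shortest-path lengths (0 for
unreachable pairs); local efficiency of a node is the global efficiency of
its neighbor-induced subgraph.  Betweenness is weighted shortest-path
betweenness, normalized by (N−1)(N−2)/2, with shortest-path multiplicity
shared fractionally.  Community detection is deterministic greedy
agglomerative modularity maximization (reproducibility outweighs the
marginal Q gains of stochastic multi-restart methods); Q is computed from
the strength-preserving null model, and each node's modularity contribution
is Σ_{j in C(i)} (w_ij − s_i s_j / 2W) / 2W, a decomposition that sums
exactly to Q — this is what "nodal modularity" means here, since no standard
nodal formula exists.  Cross-type comparisons (SC vs |FC| vs USFC) normalize
each matrix per subject (default: divide by its maximum) because the three
types live on very different scales and raw comparisons would reflect scale,
not topology; `none` reproduces the naive comparison.  Comparisons are
paired two-sided t-tests globally and per node with BH correction across
nodes.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the biophysics.  Defaults are the study conditions used throughout the test
suite: 90 regions, 8 networks, 20 subjects, SC density 0.15, subject noise
SD 0.05, backbone strength 0.9.

* **Geometry.** Centroids are uniform in a brain-sized ellipsoid
  (140 × 180 × 120 mm).  Network `N1` is a midline corridor — the ~12
  regions nearest the anterior–posterior axis within the central band —
  and the remaining regions form spatially contiguous clusters
  (farthest-point seeding, nearest-seed assignment).
* **SC.** Connection probability decays with distance (scale 120 mm),
  boosted ×4 within networks and rescaled to the configured density.
  Ordinary weights rise with proximity inside (0.05, 0.45).  The backbone
  chain — corridor regions ordered anterior to posterior — gets weight 0.9.
  Backbone regions are relay hubs: every region has a direct spoke to each
  of them at weight ≈ 0.45, mirroring the widespread connectivity of
  thalamus-like relay structures.  The ordinary-weight ceiling equals the
  spoke weight so no emergent relay can out-compete the corridor on-ramps.
* **FC.** Cheapest routes on the group-mean SC define FC: positive pairs get
  FC growing with route cheapness and route-mean SC; pairs between
  designated network blocks (default: two spatially separated non-corridor
  pairs) get negative FC whose magnitude increases linearly with the mean SC
  of their cheapest route.  A random tenth of the negative-block pairs also
  receive a strong, variable direct SC edge (weights 0.35–0.70), planting
  single-step routes under negative FC whose strength varies — the
  "stronger SC under stronger negative FC" relation at every step count.
* **Subjects.** Each subject is the group mean plus symmetric Gaussian noise
  (SD 0.05), clipped to the valid range.  SC noise applies only on the
  group-mean support: additive noise on true zeros would densify the graph
  with near-zero edges and change per-subject topology, breaking the
  configured density.  Clipping after noise (rather than
  truncation-resampling) is used for simplicity; boundary mass is negligible
  at the default noise level.
* **Determinism.** Two rng streams derived from the seed (atlas; cohort)
  with a fixed draw order give bitwise-identical cohorts per (config, seed).

What the generator does **not** emulate: BOLD time series (FC matrices are
drawn directly), tractography biases (distance-dependent false negatives,
gyral bias), heavy-tailed SC weight distributions, subject-specific
topology, or any behavioral covariate.  Passing recovery tests therefore
shows that the pipeline detects the planted structure under idealized noise
— it does not validate the model on real imaging data, where SC/FC
relationships are weaker and noise is structured.

## Problem sizes and numerical choices

Recovery checks run at the default conditions (90 regions, 20 subjects,
seeds 1–5).  The routing oracle comparison uses 200 random graphs with
5–12 nodes and density 0.2–0.5 at every hop limit 1–4; mass conservation is
checked to 1e-9 over 50 small random cohorts; determinism is verified by
running the full pipeline twice at 30 regions / 5 subjects and comparing
artifacts byte for byte.  Symmetry tolerance for all matrix validation is
1e-9 absolute, and asymmetric inputs are rejected rather than symmetrized.
Coincident centroids are an error (a zero distance would zero out a step
cost).  Matrix files are written with 17 significant digits and parsed in
round-trip float mode, so disk round-trips are exact.

## Known limitations

Routing is static: the cost of a step ignores current traffic, so the model
has no congestion feedback.  One-step connections inherit whatever the SC
matrix calls a direct connection; if an SC edge actually bundles several
white-matter pathways the step-count stratification inherits that ambiguity.
The hop limit of 4 is a modeling choice, not an estimate.  Efficiency
comparisons across connectivity types depend on the normalization
convention; the default (max) is scale-free but still a convention, and the
relative ordering of USFC vs SC efficiencies on synthetic cohorts should not
be read as a substantive claim about real connectomes.
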