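# Methods

## Hierarchical complexity

For a simple undirected graph, nodes are grouped into degree classes
`K_p` (all nodes of degree `p`).  Each node's neighbourhood degree
sequence is stored ascending; any fixed consistent order gives identical
positional variances, and ascending is used throughout.  For a class with
`|K_p| ≥ 2`, the positional sample variance (denominator `|K_p|−1`) is
computed at each of the `p` sequence positions and averaged, giving the
class's mean positional variance `W_p`.  `R` averages class terms over
the `D` distinct degrees of the network; classes with a single member
contribute nothing but still count towards `D` (they are hierarchy levels
with trivially homogeneous patterns).

Two class-term conventions are implemented:

* **slot-normalised** (`scaled=True`, the default): `W_p / (p·|K_p|)`.
  Dividing by the number of neighbour slots of the class (degree × class
  size) puts classes of very different degree and size on a common
  per-slot scale, preventing large, populous classes from dominating.
  Ensemble magnitudes under this convention match the values reported for
  matched null models in the structural-connectome literature (ER ≈ 0.01,
  RGG ≈ 0.08 at n = 85, ~36% density), which is why it is the default.
* **raw** (`scaled=False`): `W_p` itself, the plain mean-positional-
  variance reading.  On this convention the small worked example used in
  the tests (graph G5, edges a−b, a−c, b−c, c−d, d−e) has `R = 1/18`.

Both conventions are zero exactly when every degree class has internally
identical sequences — all regular graphs, paths, stars, and every
vertex-transitive graph — and both are invariant under node relabelling.
The implementation is validated against an independent brute-force
enumeration (explicit loops over classes, positions and nodes) to 1e-12
on random graphs.

Degree-restricted complexity averages the class terms over a chosen set
of degree values and is NaN (not 0) when no class in the range has two
members: an absent quantity, not an observed zero.

## Comparison indices

* Degree variance `V`: sample variance (denominator n−1) of the degree
  sequence.  The same convention is used for neighbourhood degree
  variances `V_i`.
* Assortativity `r`: Pearson correlation of degrees over edge endpoints,
  each edge contributing both orientations; NaN for regular graphs
  (zero endpoint variance).  Cross-checked against networkx's
  degree-assortativity in the tests.
* Clustering `C`: transitivity, `3·triangles / Σ k(k−1)/2`; density
  `P = 2m/(n(n−1))`; `γ = C/P`.
* Characteristic path length `L`: mean shortest-path length over
  unordered pairs; disconnected graphs are restricted to the largest
  component with a warning (connectomes at ~36% density are connected;
  sparse nulls occasionally are not).
* Mean rich-club: `φ(k) = 2E_{>k}/(N_{>k}(N_{>k}−1))` averaged over
  `k = 1..k_max−1` where at least two nodes have degree > k.  The
  coefficient is **unnormalised** (no randomised-graph baseline); this is
  recorded in the run manifest.

## Null models

All three nulls match the reference network's node and edge counts.

* **Erdős–Rényi**: a uniform sample of m unordered pairs without
  replacement (equivalent to keeping the m largest of i.i.d. uniform pair
  weights).
* **3D RGG**: n points uniform in the unit cube; edges are the m closest
  pairs.  Only the distance ordering matters, so the domain scale is
  irrelevant.  Exact ties (measure-zero for random points, systematic for
  mirrored atlas coordinates) are broken by a stable sort over an
  RNG-shuffled pair order.
* **Configuration rewiring**: degree-preserving double-edge-swap MCMC.
  Swaps proposing self-loops or parallel edges are rejected, so the graph
  stays simple and the degree sequence — hence `V` — is conserved
  exactly.  The number of *attempted* swaps is `swaps_per_edge × m`
  (default 10 per edge); at the default the output shares no systematic
  structure with the input beyond degrees, and doubling the count does
  not change ensemble statistics beyond sampling noise.

Every generator takes an explicit integer seed; cohort-level runs derive
per-replicate seeds as seed + replicate index.

## Cohort construction

Weighted cohorts are binarised with a group-consistency threshold: an
edge survives in a subject iff the subject has positive weight there and
the edge has positive weight in at least a fraction (default 2/3,
inclusive comparison) of all subjects.  Diagonals are removed.  Degree
tiers are computed per subject — degree magnitudes differ across
subjects, so a shared split would misclassify hubs — and mapped back to
named ROIs through a consistency table: an ROI is assigned to a tier only
if it occupies that tier in strictly more than the threshold fraction of
subjects (2 of 3 subjects is *not* enough at threshold 2/3), otherwise it
is reported unclassified.

Two tier definitions are implemented because "top 25% of degrees" admits
both readings; the mode is recorded in every output:

* `mode="degree"` (default): the distinct degree values, sorted
  descending, are split into T contiguous blocks of `round(D/T)` values
  (conventional half-up rounding; the final block absorbs the
  remainder).  When D is divisible by 2T, 2T-tier blocks nest pairwise in
  the T-tier blocks.  With fewer distinct degrees than tiers the split
  degenerates to fewer blocks with a warning.
* `mode="node"`: nodes sorted by degree descending are split into T
  blocks of `round(n/T)` nodes, ties broken by stable rank order.

Tier connectivity profiles compare the observed tier mix of a node's
neighbourhood, `n_ik/Σ_k n_ik`, with the whole-network mix `N_k/Σ_k N_k`;
both sum to one, and isolated nodes give NaN observed fractions.

## Cohort statistics

Group comparisons use the pooled-variance Student t-test (two-sided),
consistent with Cohen's d whose denominator is the pooled SD; a Welch
variant is available behind a flag.  p-values are reported raw — the
analysis makes a handful of planned comparisons, and readers can apply
any correction downstream.  Index correlation structure is the Pearson
matrix over {R, V, r, C, γ, L, rich-club mean} across the cohort, with
constant indices marked NaN.

## Synthetic cohort generator

The generator replaces the MRI data everywhere and encodes the study
conditions the analysis assumes: 79 subjects, 85 ROIs (34 cortical + 8
subcortical per hemisphere + brain stem, Desikan–Killiany names),
per-subject edge counts `m ~ round(Normal(1281.5, 136.72))` (~36% raw
density), FA-like Beta(8,12) edge weights in (0,1), and bilateral
mirrored 3D atlas geometry (left-hemisphere nodes uniform in half the
unit cube, reflected through the midplane, plus one midline node).

Each subject keeps the m highest-scoring node pairs under

    score(i,j) = g·z(−dist) + (1−g)·[ fitness term + dv·orientation term ] + ε

with three cohort-shared node fields:

* **fitness** `f_i > 0`: hub propensity.  Values are the exact
  lognormal(0, σ_f) quantiles — the fitness distribution is identical in
  every cohort — arranged over the atlas by the rank of a smooth Gaussian
  random field (squared-exponential kernel, length scale 0.25), so hub
  regions cluster spatially as they do anatomically.  The pairwise term
  `f_i + f_j` is centred and divided by its dispersion at the default
  σ_f = 0.7 rather than its own, so degree variance is monotone in σ_f
  instead of being normalised away.
* **orientation** `o_i`: a per-region role, drawn independently of
  fitness, that biases the region's connections towards hubs (`o_i > 0`)
  or the periphery (`o_i < 0`) through the symmetrised cross term
  `o_i·u_j + o_j·u_i` with `u = z(log f)`.  Orientations are damped by
  hubness rank — the strongest hubs connect broadly regardless of role.
  This term is what gives equal-degree regions systematically different
  neighbourhood degree profiles; it is precisely the structure that
  degree-preserving rewiring destroys, and without it a geometry+fitness
  model is barely more hierarchically complex than its own rewiring.
* per-subject score jitter ε ~ Normal(0, 0.06) and the per-subject edge
  count draw; subjects are otherwise identical.

Defaults (g = 0.5, σ_f = 0.7, dv = 1.0, noise 0.06) were calibrated once
so that the thresholded binary cohorts land where adult structural
connectome cohorts are reported to land: degree variance ≈ 195 (the
generator yields ~155–255 across cohort seeds, ~196 at seed 0), binary
edge counts within 2 SD of the 1281.5 target, and cohort complexity
exceeding configuration rewirings with Cohen's d > 0.8 by a wide margin.
With g = 1 and zero noise the model reduces exactly to an RGG on the
atlas coordinates.

What the generator does *not* emulate: true tractography biases
(distance-dependent false negatives, gyral bias), anatomically realistic
coordinates or region volumes, real inter-subject anatomical variability
(subjects share one atlas and one field realisation), streamline-count
weights, or the study cohort's specific regional tier assignments.
Passing tests therefore show that the *pipeline* behaves correctly on
cohorts with the assumed statistical structure, not that real brains have
that structure.  One systematic deviation is documented: 2/3-consistency
thresholding of subjects whose raw edge counts vary with SD 137 removes
~9–12% of edges, so binary densities sit near 0.32 rather than the raw
0.36.

## Problem sizes and runtime

The analysis drivers and acceptance script use the full study geometry
(79 replicates/subjects, n = 85); these complete in well under a minute.
Unit and property tests use small graphs (n ≤ 45) and short cohorts,
chosen so the whole suite runs in a few seconds while still exercising
every code path at the full cohort scale in the end-to-end tests.

## Known limitations

* The slot-normalised default for `R` is a package convention chosen to
  match reported ensemble magnitudes; analyses comparing against other
  implementations should state which convention they use (both are
  exposed).
* The tier "degree mode"/"node mode" ambiguity is inherited from the
  field's informal definitions; results in skewed degree distributions
  differ between modes.
* Rich-club values are unnormalised; comparisons with normalised
  rich-club curves elsewhere are not direct.
* The generator's effect sizes for cohort-vs-rewiring comparisons are
  larger than those reported for real cohorts (real anatomy is noisier
  than the stylised model); ordering-level conclusions are the intended
  use.
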