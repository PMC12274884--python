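# Methods

This note documents the models implemented in `microcortex`, the parameter
choices that matter, the numerical details, and what the synthetic-data
pipeline does and does not demonstrate.

## Topological morphology descriptor

A neurite is a rooted tree; a filtration function `f` assigns each node its
radial (Euclidean) or path distance from the root. Each terminal branch
contributes one bar `(b, t)`: `b = f` at the bifurcation where the branch's
component merges into an older one, `t = f` at the leaf that originated the
component. Merging follows the elder rule — of the components meeting at a
bifurcation, the one whose originating leaf has the largest `f` survives;
ties are broken toward the lower node id so extraction is deterministic.
The surviving component yields the essential bar `(f(root), f(leaf))`.
Consequently the number of bars equals the number of leaves; the number of
*branch sections* (maximal paths between consecutive
bifurcations/terminations) is leaves + bifurcations, and the two quantities
agree only for unbranched neurites.

Per-neuron barcodes pool all dendritic trees; radial distances are then
measured from the soma center, path distances from each tree root (which
sits on the soma surface after curation).

**Entropy.** `E(PB) = -Σ (l_i/L)·ln(l_i/L)` with `l_i = |t_i - b_i|`,
`L = Σ l_i`, natural log (the invariance properties are base-independent).
`E` is exactly invariant under uniform scaling, since the normalized lengths
are; this is what makes it a pure shape statistic.

**Persistence images.** Sum of isotropic Gaussians centered on diagram
points, sampled on a regular grid. Defaults: 100×100 grid, σ = 1/20 of the
larger axis range, bounds = the data range padded 5%. The kernel is
separable, so a population image is one rank-`n_bars` outer-product
accumulation — cheap enough to sit inside an optimization loop.

**Scaling optimization.** The distance between two populations is the L1
difference of their population images on a common grid; the common grid
covers the target population and the source population scaled by the
largest admissible factor (default 4), so no bars are clipped during
optimization. Population images are divided by population size inside the
fit so differently sized populations compare on equal footing. The
optimizer is a deterministic coarse scan (21 log-spaced factors per
parameter) followed by gradient descent with a central-difference gradient
and backtracking line search, stopping when the relative improvement falls
below 1e-6 or after 500 iterations. Plain fixed-step gradient descent is
sensitive to the arbitrary scale of the objective; the scan-plus-line-search
variant recovers planted uniform factors to well under 1% and non-uniform
pairs to under 1% on synthetic populations, which is the property the
module is accountable for.

**Diagram mixtures.** Maximum-likelihood Gaussian mixtures (full
covariances, 5 seeded restarts) over pooled diagram points, defaulting to
three centers. Degenerate clusters are handled by covariance regularization
(1e-6 of the pooled variance), flagged on the result.

**Complexity profile.** Per distance bin, two curves: the mean over neurons
of the number of bars whose span intersects the bin ("bars alive"), and the
entropy of bar-overlap lengths pooled across the population within the bin.
The bars-alive curve is the per-neuron average; the binned entropy is a
population-level curve. Both constructions are provided because the exact
curve definition is a free choice; neither is asserted to be canonical.

## Synthetic morphologies

The generator inverts the topological description: a species preset gives,
per cell class and neurite type, a Gaussian mixture over diagram points, a
truncated-normal bar-count distribution, and tree counts. A sampled barcode
forces one essential bar with birth 0 and death 5% beyond the largest
sampled death, and rejects mixture draws violating `t > b ≥ 0`.

Realization sorts bars by decreasing death and attaches each bar at path
distance `b` on a uniformly chosen previously placed bar whose span strictly
contains it; since every attached bar dies strictly before its parent, the
elder rule returns exactly the input bars, and the path-distance round trip
is exact to float precision (tested at 1e-6 μm). Unrealizable barcodes (a
bar whose birth lies outside every longer-lived bar's span) raise an error
rather than being silently repaired, preserving the round-trip guarantee.
Branch geometry is a direction-persistent random walk with 10 μm steps;
apical trees grow toward +Y (the pia-ward axis), axons downward, basal
trees in distributed directions. Diameters taper linearly from 1.0 μm at
the soma to a 0.2 μm floor.

Preset parameters encode the published species statistics: apical/basal
branch (bar) counts 54±21 / 61±34 (human) vs 36±11 / 46±19 (mouse), total
dendritic lengths ≈11,600 vs ≈5,500 μm, radial extents ≈690 vs ≈350 μm, and
the signature human feature — a dedicated mixture center near (300, 470) μm
that concentrates branch mass in the 200–500 μm perisomatic band. The mouse
preset is proximally compact, so that uniformly scaling mouse barcodes up
to human size does *not* reproduce the human perisomatic shell — mirroring
the finding that simple scaling cannot map one species' topology onto the
other's. Bar-count distributions are truncated normals because no
parametric form is published. Axons are generated long and sparse (≈28-30
bars, several mm of cable) so apposition detection is exercised
non-trivially; axonal statistics are deliberately loose, since axonal
reconstructions are the least reliable part of the source data.

## Anatomy

Closed-form mean nearest-neighbor distance for a uniform point process,
`⟨R_v⟩ = 0.554·N_v^(-1/3)`; the simulation places `round(density·V)` points
uniformly in the layer box (1 mm × 1 mm × layer thickness), averages each
point's distance to its nearest neighbor, and means over 100 seeded
instances. No edge correction is applied — this matches the stated
simulation protocol — so the simulated mean sits slightly above the
unbounded closed form (≈1-3% in these geometries).

The species registry (JSON, one provenance string per field) holds the
printed layer-2/3 values: densities 25,700 vs 137,600 /mm³; excitatory
fractions 0.70 (human) and 0.85 (mouse, Methods value); synapse volume
densities 11.8e8 vs 26.56e8 /mm³; synapse linear densities 0.88 vs 2.15
/μm; synapses per neuron 15,000 vs 12,000; synapses per connection 4 vs
3.2. The mouse interneuron fraction is stored separately as the printed 12%
even though it is inconsistent with the 85% excitatory figure; class
densities therefore use 0.85 for pyramidal cells and 0.12 for interneurons,
which is how the published per-class distances were evidently computed.
Bouton density carries no species value (the underlying measurements are
inconclusive); the axon-density formula is provided without asserting a
result.

## Circuits and appositions

Circuits are hexagonal prisms (side α, height H along +Y) tiled as a
central column plus six edge-sharing neighbors; all analysis restricts to
central-column cells to avoid boundary effects. Somata are uniform in each
prism with fixed per-class counts (human: 10,500 PC + 4,500 IN; mouse:
15,200 PC + 2,700 IN at full scale); no layer 2 vs 3 distinction and no
density gradients. The desk-scale spec divides counts by a configurable
factor (default analyses use 1/20 → ≈750 cells/column) and shrinks the
hexagon side by the square root of that factor, preserving densities while
keeping the layer thickness.

Cloning translates a donor to the soma position, rotates it about +Y by a
seeded uniform angle, and adds zero-mean Gaussian coordinate noise
(default sd 1 μm — "minimal noise"; the magnitude is unspecified in the
source protocol). Rotation is on by default to avoid artifactual alignment
of identical clones; `rotate=False` reproduces the stricter
noise-only reading. Note that independent per-node jitter inflates each
segment's expected length by ≈3σ²/(2ℓ); at the default 10 μm segments this
is ≈3%, which bounds how exactly clone morphometrics can match donors.

An apposition assigns a directed edge i→j when any axonal segment of i
passes within 2 μm of a dendritic segment of j; the per-edge count is the
number of such axonal segments, and edge existence is count ≥ 1.
Segment-to-segment distances use the exact closed form for 3D segments.
The production path prunes candidate pairs with a KD-tree on segment
midpoints at radius `threshold + (max axon segment + max dendrite
segment)/2` — a provably conservative bound — so it returns exactly the
brute-force result (asserted in tests on ≤50-cell circuits).

The hybrid circuit isolates dendritic shape from size and density: a
human-dimensioned column whose cells carry mouse dendrites scaled (per cell
class) so total dendritic length equals the human pool mean, with human
axons grafted at the soma.

## Networks

Network density follows the printed convention — edges divided by the
*squared* node count — which is unconventional (no self-edges exist) but
kept for consistency; the complete digraph on 10 nodes has density 0.90.
Pruning keeps a uniformly random `floor(density·n²)`-edge subset of the
apposition graph, emulating the selection of actual synapses from potential
ones; the ≈4% target derives from per-neuron synapse statistics
(15,000/4 = 12,000/3.2 = 3,750 expected in-degree; ≈3.75% at 100K neurons).

Directed simplex counts enumerate ordered tuples `(v0,…,vk)` with an edge
`vi→vj` for every i<j, by recursive out-neighborhood intersection; this is
exact and counts each clique once per linear extension consistent with its
edges (reciprocal pairs yield several orderings; nothing is collapsed).
Null models: directed Erdős–Rényi (each ordered pair an edge with the given
probability) and a directed Watts–Strogatz variant — a ring lattice in
which every node sends edges to its k nearest neighbors (k/2 per side, so
out-degree is exactly k at p=0) with each edge's target rewired with
probability p avoiding self-loops and duplicates. No undirected-then-orient
construction is used, because it cannot satisfy the out-degree-k contract.

## Memory capacity and statistics

Capacities are computed with exact integer binomials before the logarithm
(beyond ~1e308 the log is taken via bit-length shifting), so arbitrarily
large arguments neither overflow nor lose the 1e-9 relative accuracy the
tests assert. At m=1 the non-linear model reduces exactly to the linear
one; less obviously, at m=s (one synapse per subunit) it *also* collapses
to the linear value, so capacity as a function of subunit count at fixed
s=m·k rises to an interior maximum rather than increasing over the whole
divisor range. The "capacity grows with branches" statement holds in the
regime where each subunit keeps at least d synapses, and that is what the
tests assert.

For real or synthetic neurons the subunit count m is mapped to the number
of dendritic terminal branches (the source model counts computational
subunits, not physical branches, but publishes no mapping; this choice is
configurable), and k = round(total dendritic length · synapse linear
density / m), floored at 1. The capacity–complexity association uses
Spearman rank correlation (both quantities are monotone transforms of
branch statistics; no coefficient is prescribed). The number of input lines
d defaults to 10.

KS comparisons use the two-sample asymptotic test; underflowing p-values
are floored at the smallest positive normal double so a p-value of exactly
zero is never reported. Group variability compares mean pairwise L1
distances between per-cell persistence images within vs between groups
(singleton groups excluded, with a warning), reporting the within/between
ratio.

## Problem sizes and seeds

Default analysis sizes were chosen so the full pipeline runs comfortably on
a single core: 100 point-process instances (~3,900–32,000 points each) for
distance statistics; 1/20-scale columns (≈750 cells, ~20 donor morphologies
cloned) for circuit comparisons; exhaustive simplex enumeration on the
resulting ~500-760-node, 4%-density subnetworks. All randomness flows from
explicit integer seeds through `numpy.random.Generator`; identical seeds
reproduce circuits, populations and SWC files bit-for-bit.

## Known limitations

- The generator reproduces barcode statistics, not full 3D anatomy: real
  dendrites fill space with correlated, tortuous branches, and real axon
  collaterals have laminar targeting none of which a direction-persistent
  random walk captures. Passing pipeline tests therefore demonstrate
  correctness of the *machinery* on populations with the published summary
  statistics, not fidelity to any individual reconstruction.
- At desk scale the directed-simplex comparison has limited resolution: the
  structured circuits show a severalfold excess of high-dimensional
  simplices over matched random controls, but the integer maximal-dimension
  statistic saturates (both reach dimension 4 at ~500 nodes and ~4.5%
  density), and the hybrid circuit's simplex profile tracks the human-like
  circuit rather than the mouse-like one — with matched cable lengths,
  shared axons and identical column geometry, barcode-shape differences
  move apposition statistics only at second order. Distinguishing those
  regimes appears to require full-scale (10-17K cell) circuits built from
  real reconstructions.
- Tissue-shrinkage unraveling, cut-branch repair, spines, synapse
  physiology and EM-derived connectivity preferences are out of scope;
  curation is limited to root reconnection, zero-diameter repair and apical
  alignment.
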