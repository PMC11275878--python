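# Methods

## The question and the model

A compact island of mistargeted retinal boutons in the dLGN, separated from
the surrounding retinal input by a bouton-free exclusion zone, suggests a
synaptically segregated subcircuit: thalamocortical cells (TCs) near the
zone should be innervated exclusively by one bouton field. The analysis
formalizes "no segregation" as the **independent-dendrite null**: each
primary dendrite of a TC (a soma-adjacent subtree that carries at least one
retinal input) independently connects to the island or the non-island field
with probability ½. A TC with k such dendrites is then *captured* — all its
retinal input from one field — with probability 2^(1−k), and the number of
captured TCs across cells with dendrite counts k₁…kₙ is Poisson-binomial
with pᵢ = 2^(1−kᵢ).

Two routes compute this null. `exact_capture_distribution` convolves the n
Bernoulli factors sequentially (O(n²); n is at most tens, so clarity beats
FFT). `monte_carlo_null` simulates dendrite assignments directly (default
100,000 trials, one seeded NumPy generator per run, seed recorded in the
output). Quantiles follow the "m or fewer" convention: the reported
threshold is the smallest m whose (empirical or exact) CDF reaches the
level. For the reference dendrite counts (2,2,3,4,4,4,5,5,7) the exact CDF
is 0.9429 at 3 and 0.9916 at 4, so the 0.99 threshold is 4 of 9 (44%); the
exact mean is Σ 2^(1−kᵢ) = 1.765625, and full capture of all nine cells has
probability 2^(9−Σkᵢ) = 2^(−27). The comparison of an observed capture
count with this null is reported as tail probabilities and threshold
positions only; the package deliberately attaches no significance wording.

`classify_tc` maps a count triple (island, non-island, ambiguous) to a
capture class: `no_rgc` (no inputs), `ambiguous_zone` (ambiguous fraction
above a cutoff, default 0.5 — a configuration knob, since mid-zone cells
are a qualitative category), `pure_island` / `pure_nonisland`, else
`mixed`. The classification is exhaustive and symmetric under swapping the
two fields. Cohort capture fraction is captured / eligible, where eligible
excludes `no_rgc` cells (a cell without retinal input cannot be captured).

## Bouton-field classification

The island is defined optically in tissue; computationally we use a density
surrogate. Bouton positions are histogrammed on a regular grid, smoothed
with an isotropic Gaussian kernel (bandwidth default: 2× the mean
nearest-neighbor spacing of the cloud; grid spacing: half a bandwidth,
coarsened if the grid would exceed ~2 M voxels), and corrected for the
finite support of the cloud by dividing by the smoothed indicator of the
cloud's convex hull — without this, field density halves at the volume
boundary and edge boutons are spuriously orphaned. The density is
thresholded at `level_fraction` (default 0.1) of its peak; 26-connected
components above threshold are candidate fields; the component with the
smallest voxel-volume-to-bouton-count ratio (the most compact) is the
island, all other components are non-island. A bouton below threshold
adopts the nearest component's field if that component lies within half a
bandwidth, and is otherwise **ambiguous**. The fallback is a deliberate
choice: Poisson dips inside a uniform field would otherwise orphan interior
boutons, while genuinely mid-gap boutons (several bandwidths from either
component) remain ambiguous. If only one populated component exists the
labeling carries a `no_split` flag instead of raising — the caller decides.

All gridding, the separation-axis search, and ray casting run in a
canonical frame derived from the cloud (centroid; covariance eigenvectors
ordered by descending eigenvalue, each sign fixed so the third central
moment of the projections is non-negative; right-handedness enforced on the
last axis). Because the frame is constructed from the data, labels, margins
and gap statistics are equivariant under rigid motions of the input — a
property the test suite checks to 1e-6.

**Separation projection.** Candidate axes on a Fibonacci sphere at the
requested angular resolution (default 3°) are scored by the 1D margin
between the projected supports of the two classes (ambiguous excluded);
the best axis is refined by alternating golden-section search on its two
spherical angles. Ties break toward the lexicographically smallest axis;
there is no randomness. The margin is floored at 0, with the number of
points inside the overlapping interval reported. Note that the margin of
any axis is bounded by the minimum inter-class point distance — used as an
independent oracle in tests. On generator output the margin is 0 by
geometry: the non-island field surrounds the island, so no half-space
separates the classes; the margin is meaningful for partially reconstructed
or slab-like clouds, and the slab construction is what the tests measure.

**Exclusion zone.** Rays are cast from the island boutons' centroid along a
uniform direction sample (default 300); along each ray the gap is the
distance from the last island bouton to the first non-island bouton within
a tube radius (default one bandwidth) of the ray. Rays that meet no
non-island bouton are excluded and counted. The median/min/max are
reported; a median below one bandwidth (≈ the resolvable inter-bouton
spacing) raises a `no_zone` flag. The measurement is radial from the
centroid, adequate for convex-ish islands and biased upward by roughly one
mean inter-bouton spacing per side (~1 µm at default densities) — the
recovery tolerance in the tests (0.8–1.3× the true width) covers this.
Concave islands would need a minimal-surface formulation; not implemented.

## Neurite taxonomy and zone crossings

Skeletons decompose into branch units: for TCs, the soma-adjacent subtrees
(the primary dendrites of the null model); for LINs, each soma-adjacent
subtree's trunk (the along-tree path to its farthest node) plus every side
subtree hanging off the trunk. A unit *crosses* the exclusion zone when its
polyline, sampled at ≤ 200 nm arc steps, enters the shell region — background
voxels within the labeling's component gap width of the island component.
Synapses attach to the unit containing their nearest non-soma node; retinal
inputs take their bouton's field label (so per-branch counts conserve the
cell-level profile exactly), non-retinal inputs are tallied separately.

LIN units classify in precedence order: **shaft** if the unit's along-tree
reach is ≥ 100 µm (field scale: shafts span hundreds of µm), regardless of
synapse density; **axon-like** if it carries outputs but no inputs;
**targeted** if its reach is within 2× the 20 µm targeted-neurite scale
*and* its synapse linear density is ≥ 0.2 per µm; otherwise unclassified.
The ordering resolves the overlap between "short and dense" and
"output-only" in favor of axon-like, matching the field taxonomy
(input/output targeted dendrites vs output-only axons). Increasing the
targeted reach can only promote unclassified units to targeted, never
convert targeted to shaft (monotonicity, tested). TC branches are split
proximal/distal by mean radius (≥ 800 nm) or the presence of retinal input,
since the proximal–distal transition is defined qualitatively in tissue.

`soma_synapse_vector` quantifies arbor asymmetry as the offset from the
soma-node centroid to the mean retinal-input position, plus its signed
projection onto the outward island normal nearest the soma (approximated
as the direction from the island centroid to the soma; positive = away
from the island). For fully segregated synthetic circuits the sign
separates island-captured from non-island-captured cells.

## Synthetic circuits

The generator builds what the analysis assumes and nothing more. Island
boutons are uniform in an ellipsoid (default semi-axes 15 × 12 × 10 µm);
non-island boutons are uniform in the surrounding box (70 µm cube) outside
the ellipsoid dilated by the exclusion width (default 12 µm); the shell is
exactly empty. Defaults — 1,500 island and 9,000 non-island boutons — were
chosen once so the regime matches the analysis' assumptions: island density
~6× field density, shell width ~7× the mean bouton spacing (the classifier
is specified for shells ≥ 3× spacing). These are self-consistent choices,
not measurements; no physical island size is published to calibrate
against. Every bouton becomes one synapse record (one bouton = one counted
input); boutons not wired to a reconstructed cell keep an anonymous
neuropil target, mirroring EM-labeled boutons whose postsynaptic partner
was not traced, and retinal axons are represented by boutons only (orphan
presynaptic ids).

Nine TC somata (default) sit on the mid-shell ellipsoid with primary
dendrite counts cycled from (2,2,3,4,4,4,5,5,7) and per-cell input counts
uniform on 0–118. Each cell draws a home field; each dendrite follows the
home field with probability `segregation`, otherwise flips a fair coin — at
segregation 0 this *is* the null model, which makes the generator an
end-to-end calibration harness for it (the observed capture count should
fall in the exact null's central 99% interval; tested over 100 seeds).
Dendrites are piecewise-linear paths from the soma through their sampled
boutons, drawn from the nearest available boutons of the assigned field so
that arbors are local and arbor-asymmetry vectors are meaningful;
tortuosity, branching angles and diameters are not modeled beyond a nominal
taper. LINs get a soma on the shell, two wandering shaft arms (115–150 µm,
reflected off the volume walls, the first forced through the island so
every shaft crosses the zone; synapses only placed ≥ 2 µm clear of the
shell), short targeted branches seeded strictly inside one field with ~8
nearby same-field boutons each, and one small output-only branch.
`degrade` drops synapses i.i.d. and jitters positions isotropically, as a
partial-reconstruction harness. All randomness flows from one
`numpy.random.default_rng(seed)`; identical configs produce byte-identical
datasets on disk.

**What passing tests do and do not show.** The generator reproduces the
*statistical* structure the analysis consumes — densities, shell geometry,
tree topology, synapse placement, the segregation/null dial — not
morphological realism (no tortuosity or branching statistics, no glomerular
ultrastructure, ellipsoidal rather than irregular island, no cortical
feedback synapses, no developmental dynamics). Recovery results on
synthetic data therefore validate the estimators under their stated
assumptions; they say nothing about tracing error or registration in real
volumes beyond what `degrade` emulates.

## Numerical choices and problem sizes

* Exact Poisson-binomial by convolution; agreement with full 2^Σk
  enumeration to < 1e-12 for Σk ≤ 16 (tested).
* Monte Carlo: 100,000 trials default. At the reference counts the exact
  CDF at the threshold (0.9916) is ~25 standard errors from 0.99, so the
  reported threshold is stable across seeds.
* Density classification: bandwidth 2× mean NN spacing, level 0.1 of peak,
  ambiguity margin = bandwidth/2, 26-connectivity, convex-hull support
  correction with the correction factor floored at 0.05.
* Degenerate inputs: single-component labelings return `no_split` rather
  than raising; empty projection classes and missing somata raise typed
  errors (`MissingSomaError` distinct from `NoRGCInputsError`); synapses
  farther than 500 nm from every skeleton node warn but are counted, since
  reconstructions are partial.
* Unit tests run on a scaled-down circuit (50 µm volume, 3,400 boutons)
  with the same geometric ratios as the defaults; end-to-end recovery and
  calibration checks use the full default circuit (10,500 boutons, 9 TCs;
  100 seeds for the null-calibration property).

## Known limitations

* The island boundary is a density isocontour; the optical definition it
  stands in for is qualitative, so absolute gap widths inherit a
  bandwidth-scale bias (quantified above).
* The radial gap measurement assumes a star-convex island.
* The separation margin is a linear (single-axis) notion of separation,
  reported as 0 whenever one field surrounds the other.
* The ambiguous-fraction cutoff (0.5) for `ambiguous_zone`, the 500 nm
  attachment tolerance, and the LIN thresholds (100 µm shaft, 2 × 20 µm
  targeted reach, 0.2/µm density) are configuration values with field-scale
  defaults, not measured quantities.
* One synapse record = one counted input; multi-contact boutons are not
  modeled (the counting convention is recorded in dataset provenance).
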