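# Methods

This note records the models, numerical conventions and design choices
behind the package, and what the synthetic-data tests do and do not
demonstrate about real imaging data.

## Vessel geometry

**Boundary curves.**  Wall points marked by a user are interpolated with
natural cubic splines (zero second derivative at the open ends) under the
centripetal parameterization: knot increments proportional to the square
root of chord length.  Centripetal knots suppress the loops and overshoot
that uniform parameterization produces on unevenly spaced marks.  The
two-point case degenerates exactly to the straight segment.

**Chains and sampling step.**  Each curve is evaluated at uniform parameter
steps (default 0.1 in centripetal knot units, final knot always included)
into a polygonal chain.  Because centripetal knot units scale with the
square root of point spacing, 0.1 corresponds to roughly two chain points
per pixel of boundary length for typically spaced marks — dense enough that
the resulting cross-vessel segments touch every pixel of the enclosed area
(verified as a property on every generated vessel).  The step is a
parameter; physical equivalents (steps per pixel, µm) depend on the imaging
geometry and are deliberately not hard-coded.

**Orthogonal segments and the medial axis.**  For each point on chain A the
Euclidean-nearest point on chain B is found, and vice versa (brute-force
with lowest-index tie-breaking below a size cutoff, kd-tree above it).
Pairs that are mutually nearest mark inflection points or straight
stretches.  Between consecutive mutual pairs, the segments emanating from
the locally longer boundary — compared by sub-chain arc length, ties
keeping chain A — are retained; this selects the outside of each bend and
avoids coverage holes.  Maximal runs of mutual segments are kept verbatim.
Mutual-pair detection uses exact index equality; mutual pairs that would
move backwards along chain B (possible with very noisy marks) are dropped
to keep monotone ordering.  Residual crossings after selection are removed
greedily (later segment dropped, logged as a warning); a strict interior
intersection predicate is used, so segments sharing a chain point do not
count as crossing.  Opposite chain orientations are detected by the
crossing of the first-to-first and last-to-last connectors and rejected.
The medial axis is the chain of segment midpoints; its quality is measured
by `medial_centrality`, the mean and SD over axis points of the absolute
difference between the distances to the two walls (both sub-pixel on all
generated vessels).

Coordinates are continuous, 0-based, pixel-centre; `x` is the image
column, `y` the row.

## Unwarping and standardization

Rows are recorded along each segment at the midpoints of `samples_per_row`
(default 40, the target width) equal subdivisions with bilinear
interpolation — midpoint sampling tiles the profile rather than
double-weighting its endpoints.  Length correction resamples rows so the
output row index is proportional to medial arc length, with the row count
equal to the total medial length rounded half-up.  Sections (delimited by
selected segment indices; the first and last close the region) are then
independently resampled to target lengths, every row to the target width,
using natural cubic interpolants (linear precision; ramp reproduction
within 0.05 is asserted in tests).  Section `s` covers input rows
[c_s, c_{s+1}) with the final section closed on the right, so a map already
at target geometry passes through bit-identically — this fixes the
otherwise ambiguous off-by-one in stacking sections that share a boundary
segment.

Defaults: section lengths 50, 50, 50, 50, 200 px (the four arch sections
are kept large relative to their physical size so the strongly bent arch
is not under-represented), width 40 px, Gaussian smoothing σ = 3 px with
reflective borders (avoids edge darkening on small maps; preserves the map
mean within 1%).

**Order of operations** is record → length-correct → section rescale →
width rescale → smooth → background-normalize.  Smoothing is applied after
standardization and before normalization: normalization is a scalar
division, so it commutes with smoothing, and placing smoothing last in the
geometric chain means σ is expressed in standardized-map pixels.  The
applied order is recorded in each map's metadata so the alternative can be
distinguished downstream.  Background normalization divides by the mean
over a configured region (a section index — e.g. an uninflamed reference
artery — optionally restricted to row/column ranges); a non-positive mean
is rejected as a corrupt background.  Normalized maps are invariant to
global multiplicative rescaling of the input image (asserted exactly).

## Permutation testing

Assignments: unpaired designs admit C(n, k) label exchanges, paired
designs 2^(n/2) within-pair swaps.  Enumeration is exhaustive up to
`max_permutations` (default 5000; 1000 is generally sufficient), beyond
that a seeded Monte-Carlo sample — without replacement among distinct
assignments when the total is ≤ 10× the cap, with replacement otherwise —
always force-including the original labelling first, so the observed
statistic is ranked within its own null and the attainable p is bounded
below by 1/n.

Per-pixel normalization uses the population SD (divisor n) over the
difference maps of all assignments, original included (a flag allows
excluding it).  Pixels with zero SD — constant across subjects — are
defined to have normalized value 0: no evidence of difference.  The zero
test uses a relative floor (~1e4 machine epsilons of the largest
difference) so that accumulation rounding cannot turn constant pixels into
O(1) statistics.

Thresholds: with n permutation maxima sorted ascending, the upper
threshold is the ceil((1−α)·n)-th order statistic and the lower threshold
the mirrored (n+1−ceil((1−α)·n))-th order statistic of the minima.  Under
exhaustive enumeration this makes the probability that the original
maximum strictly exceeds the threshold equal to (n − ceil((1−α)·n))/n ≤ α,
i.e. guaranteed FWER control; for 252 assignments (two groups of five) the
exact upper-tail level is 12/252 ≈ 4.76%.  The significance mask is +1/−1
where the original (optionally TFCE-enhanced) normalized map strictly
exceeds the upper / falls below the lower threshold.

With TFCE enabled, the enhancement is applied to the normalized difference
map of every permutation (original included) before taking extrema, so the
null distributions are built from enhanced values.

The paired scheme swaps images only within subjects and otherwise proceeds
exactly like the unpaired test (building the distribution from the
per-permutation extrema of the normalized, optionally enhanced maps).
Because every map is normalized to its own background, paired comparisons
of two different tracers are meaningful.

## TFCE

The enhanced value of pixel p is ∫_{h0}^{h_p} e(h)^E h^H dh with E = 0.5,
H = 2 by default, evaluated as a midpoint Riemann sum over `n_levels`
(default 500) equal bins between h0 and the map maximum; midpoint heights
minimize bias against a fine-level oracle (500 levels agree with 10,000
levels within 0.5% on smooth random maps).  The sum includes the bin width
Δh, making the result a true integral approximation; dropping Δh would
only rescale all values by a constant and leave thresholded results
unchanged.  Connectivity defaults to the 8-neighbourhood (flag for 4).
Constant maps enhance to zero (zero level range).

Normalized difference maps are signed while the integral is defined from
the lowest intensity upwards.  Default handling enhances the positive part
from h0 = 0 and the negated negative part symmetrically, recombining with
sign — this keeps the max/min test symmetric under group exchange
(enhance(−v) = −enhance(v)).  The literal variant (single integration from
the global minimum) is available with `signed=False`.  Enhancement scales
as c^(H+1) under input scaling by c > 0, and strict local maxima of the
input remain non-strict local maxima of the output (both asserted).

## Synthetic data

`make_vessel` renders a tube around a centerline composed of a circular
arc (radius 110 px, half-turn by default — an arch) joined to a straight
segment (150 px — a descending portion), with constant or varying half
width (16 px default), base intensity 100, background 5, additive Gaussian
noise (SD 2) and multiplicative Gaussian-profile lesions at known arc
positions.  Boundary marks are emitted every 20 px of wall — emulating
sparse manual annotation — alongside dense ground truth (centerline, mask,
lesion positions).  A zero-span arc degenerates to a straight vertical
tube.  `make_map_groups` draws standardized-map groups (default 400 × 40,
five per group, unit noise) with a rectangular effect region added to
group A and, in paired mode, shared per-subject baseline offsets.

What passing tests on these data show — and what they do not: the
generators exercise the geometric and statistical machinery under
controlled truth (sub-pixel medial centrality, complete coverage,
nominal FWER, recovery of planted effects).  They do not emulate
fluorescence physics (scattering, depth-dependent attenuation, spatially
correlated noise), anatomical variability between subjects, or annotation
error beyond mark sparsity; conclusions about a real tracer study still
require the usual controls on acquisition and annotation quality.

## Problem sizes in the test suite

The suite favours small, exactly checkable configurations: vessels of
radius 60–110 px in images around 200–360 px, map groups of 30 × 20 to
400 × 40, TFCE at 64–500 levels, and permutation runs of up to 500
assignments.  The null-calibration study uses 500 repetitions of the
five-vs-five 40 × 40 design, for which enumeration is exhaustive (252
assignments) and the exact upper-tail level is 12/252; the observed rate
is compared within two Monte-Carlo standard errors of the nominal 5%.

## Known limitations

- Geometry is strictly 2D; no orthogonal-slice construction for volumetric
  data.
- Vessel boundaries must be supplied; there is no automated segmentation.
- The "locally longer curve" rule is decided per stretch between mutual
  pairs by sub-chain arc length; other notions of local (curvature-based
  switching) are conceivable and would differ on pathological chains.
- Monte-Carlo sampling with replacement (very large designs) can duplicate
  assignments; the original labelling is counted once.
- Inner/outer-curvature sub-regions of sections are not implemented.
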