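# spam — Statistical Permutation-based Artery Mapping

`spam` analyses planar molecular-imaging signal (e.g. fluorescence
reflectance imaging of tracer uptake) in the wall of curved arteries.  It
addresses a concrete problem in cardiovascular molecular imaging: tracer
distributions along an atherosclerotic vessel vary regionally, vessels are
curved and anatomically variable across subjects, and naive region-of-interest
quantification either misses patterns or accumulates alpha errors.  The
package is aimed at imaging scientists who have 2D vessel images plus
manually marked wall boundaries and want pixel-wise group comparisons with
family-wise error control.

The pipeline has three stages:

1. **Unwarping and standardization.**  Natural cubic splines (centripetal
   parameterization) through the marked wall points give two boundary
   curves.  Dense sampling and mutual-nearest-neighbour matching yield a set
   of non-crossing cross-vessel segments — between inflection points the
   segments from the locally longer (outer) boundary are kept — whose
   midpoints form the medial axis.  Recording intensities along each segment,
   stretching by medial arc length, resampling anatomical sections to fixed
   lengths (default L₁..L₄ = 50 px, L₅ = 200 px) and every profile to a fixed
   width (W = 40 px), smoothing (Gaussian, σ = 3 px) and dividing by the mean
   background intensity produce standardized 400 × 40 maps that are
   pixel-wise comparable across subjects.

2. **Max-statistic permutation testing.**  For two groups of maps, group
   labels are permuted (exhaustively when ≤ 5000 assignments — C(n, k)
   unpaired, 2^(n/2) paired — otherwise a seeded Monte-Carlo sample
   containing the original labelling).  Each permutation's mean difference
   map is normalized per pixel by the SD of that pixel over all permutation
   difference maps; the per-permutation maximum (and minimum) forms the null
   distribution, whose (1−α) percentile thresholds the original map.  Because
   the null is built from image-wise extrema, a single threshold controls the
   probability of *any* false-positive pixel (FWER).

3. **Threshold-free cluster enhancement (TFCE).**  Before taking extrema,
   each normalized map can be enhanced per pixel as
   ∫₀^{h_p} e(h)^E · h^H dh (E = 0.5, H = 2, 500-level Riemann sum), where
   e(h) is the extent of the connected suprathreshold component containing
   the pixel.  Spatially coherent signal is boosted relative to isolated
   noise peaks while local maxima are retained.

## Worked example

```python
import numpy as np
from spam import (MapGroupSpec, TFCEParams, make_map_groups, run_test)

# two groups of 8 standardized maps; group A carries a +4.0 effect in a
# 10x10 region over noise of SD 0.5
design = make_map_groups(MapGroupSpec(
    shape=(30, 20), n_per_group=8, effect_region=(8, 18, 5, 15),
    effect_size=4.0, noise_sd=0.5, seed=5))
result = run_test(design, max_permutations=500, seed=5,
                  use_tfce=True, tfce_params=TFCEParams(n_levels=64))
print(result.summary())
```

prints

```
Permutation test of two map groups
============================================
design                      unpaired
group sizes                 8 vs 8
map shape                   (30, 20)
permutations                500 (original included)
alpha                       0.05
cluster enhancement         TFCE
seed                        5
--------------------------------------------
max statistic (original)    157.551
min statistic (original)    -5.22339
upper threshold             22.4463
lower threshold             -22.4463
pixels above threshold      101
pixels below threshold      0
============================================
```

The original labelling's enhanced maximum (157.6) far exceeds the 95th
percentile of the permutation null (22.4): the planted region is flagged
significant (101 pixels, covering the 100-pixel effect plus one adjacent
pixel pulled in by cluster support), with nothing in the negative
direction.

The same analysis is available from the shell:

```sh
spam synth maps --n 8 --effect 4.0 --seed 5 --out data/
spam test --manifest data/manifest.csv --tfce --seed 5 --out results/
spam tfce --in map.tif --E 0.5 --H 2 --levels 500 --out enhanced.tif
spam synth vessel --seed 1 --out vessel/      # image + boundaries + truth
spam validate --seed 1 --out sweeps/          # step-size / sigma sweeps
```

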