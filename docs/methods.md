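# Methods

`seedmorph` quantifies seed shape in populations of grape (*Vitis*) seeds
and classifies cultivar-level average shapes against geometric reference
models. This note documents the models, the parameters that matter, the
synthetic data the tests run on, and the numerical choices.

## Shape representation

A seed outline is a simple closed polygon in mm coordinates (y up,
counterclockwise). Outlines come from binary images (sub-pixel
marching-squares tracing at the 0.5 level, border-touching components
excluded) or from TPS outline files. Stairstep pixel chains are avoided
deliberately: perimeter-dependent descriptors such as circularity are
strongly biased by them.

Each outline is expanded in elliptic Fourier descriptors (Kuhl–Giardina):
x(t) and y(t) as truncated Fourier series over the arc-length
parameterization of the polygon, eight harmonics, four coefficients
(A, B; C, D) per harmonic. Note that under arc-length parameterization only
the circle is exactly a one-harmonic curve; a stretched ellipse acquires
small odd-harmonic corrections. This matches the behaviour of the standard
outline-morphometry tools and is a property of the parameterization, not an
implementation artifact.

Coefficients are normalized through the first harmonic: start point moved
to the semi-major-axis crossing, shape rotated so the semi-major axis lies
on +x, scale divided out and kept as `size_mm`. The residual half-turn
ambiguity (start at one end of the major axis or the other) is resolved by
choosing the parameterization whose t=0 point has the larger x coordinate —
for a beaked seed, the beak tip. Reflection is *not* normalized away: seeds
are photographed in a consistent lateral view, and collapsing reflections
would silently merge chiralities. Averaging is linear in the coefficients,
so a population's average contour (Ac) is the element-wise coefficient
mean, and a reference model is the mean of two or more Acs.

## Shape descriptors

Eight per-seed measurements with ImageJ semantics: area A, perimeter P,
length L and width W (major/minor axes of the moment-equivalent ellipse
rescaled so πLW/4 = A — ImageJ's fitted-ellipse convention; a Feret-based
alternative is available behind `axis_mode="feret"`), circularity
C = 4πA/P², aspect ratio AR = L/W, roundness R = 4A/(πL²), and solidity
S = 1000·A/area(convex hull) rounded to integer. The convex hull is exact
(polygon vertices), which removes the resolution dependence a raster hull
would introduce.

## J-index

The J-index between a model and a seed is the area Jaccard index on the
percent scale: J = 100·|A∩B| / |A∪B| after a superposition maximizing
overlap. Registration replaces the study-style manual overlay with a
deterministic optimizer: centroid alignment, area-equalizing scale and
principal-axis rotation initialize the pose; a 1° rotation sweep over the
full turn (covering both principal-axis flips) and Nelder-Mead refinement
over (dx, dy, θ, log s) follow. The search runs on 120-point arc-length
resamplings for speed; the final candidate poses (refined, best-sweep,
principal-axis init, unrotated init) are re-scored on the exact input
polygons and the best is returned, so the returned pose never scores below
the initialization. Scale is optimized by default (`fixed_scale=True`
restricts to rigid motion); reflections are never searched. Overlap uses
exact polygon clipping (shapely); a raster mode emulating pixel counting
agrees with the exact mode to ≲0.02 J points at 50 px/mm.

## Classification

Populations are split into high/low aspect-ratio classes at AR = 1.575
(AR rounded to 2 decimals first, so 1.58 is high and 1.57 low) and ranked
by descending solidity within each class, high-AR block first, ties broken
alphabetically. Group assignment from the two population-mean J values
(thresholds 90 and 94, both strict, configurable):

* G1 — J < 90 with both models;
* G2 — J(Heben-type) > 94;
* G3 — J(Chenin-type) > 94;
* G4a/G4b — the remainder, by which model scores higher.

If both J values exceed 94 the larger one wins (G2 on an exact tie); no
observed case fixes this rule, so it is a package decision recorded here
and in the outputs.

## Curvature

The lower profile (sub-path between the horizontal extremes running under
the seed, ordered left→right; x-ties resolved by lowest y) is fitted with a
degree-10 Bezier curve — least squares, chord-length parameterization,
endpoints interpolated. Signed curvature
κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2}, in mm⁻¹, is evaluated on a 601-point
grid over t ∈ [0.2, 0.8]; the window excludes the endpoint regions where a
least-squares polynomial fit is unreliable. Reported statistics: max, min,
mean (t-uniform arithmetic mean of signed κ; an arc-length-weighted variant
would differ slightly for strongly non-uniform speed) and max/mean ratio.
Positive κ is convex; negative κ marks non-convex stretches such as the
flanks of the beak. Calibration: a circle of radius 1 mm gives κ = 1 mm⁻¹,
radius 0.1 mm gives 10 mm⁻¹, a straight line gives 0. Extrema are taken
over grid values without root polishing; at this grid density the
difference is below the 2-decimal reporting precision. Degree 10 is a
configuration knob and is reported in outputs; degree must stay well below
the profile's point count or the fit is rejected as underdetermined.

## Statistics

Group comparisons use the two-sided Mann-Whitney U test at α = 0.05 with no
multiple-testing correction: exact null distribution when min(n) ≤ 8
without ties, normal approximation with tie correction otherwise. Pairwise
decisions are summarized as a compact letter display (groups sharing no
significant difference share a letter). PCA runs on centered, unscaled
coefficients (columns A1..D8 share a unit after normalization;
correlation-mode is available via `scale=True`). Group ellipses are 95%
confidence ellipses for the *mean* (χ² quantile on the covariance of the
mean), not data ellipses — they may legitimately contain few or no
observations. Simulated coverage at n = 50 per group is ~94–95%.

## Synthetic populations

The generator emulates populations of seed-like closed contours of three
morphotypes, standing in for reference material that would otherwise
require the original image archive:

| template | AR | solidity (×1000) | length | morphology |
|---|---|---|---|---|
| `heben_like` | 1.62 | 975 | 6.5 mm | triangular body, wide beak |
| `chenin_like` | 1.68 | 955 | 6.8 mm | narrower, straighter beak, deeper flank concavities |
| `sylvestris_like` | 1.35 | 985 | 5.5 mm | wild-type: rounder, blunter, more solid |

Template coefficients are frozen constants produced once by
`scripts/tune_templates.py`: a hand-designed pyriform outline (ellipse body
+ Gaussian beak bump − symmetric flank dips, in polar form) is transformed
to 8 normalized harmonics, and the body elongation and dip depth are tuned
by root finding until the reconstruction *measures* the target AR and
solidity. Target values follow the reference morphotypes; lengths are
typical grape-seed sizes (the 6.5 mm template has area ≈ 21 mm²).

Per-seed variation: multiplicative Gaussian noise (default CV 0.05) on
harmonics 2–8 and an independent size factor (default CV 0.03) on harmonic
1, so size and gross shape vary separately. No per-seed variance is
published for the reference material; the defaults are package choices
producing within-population descriptor CVs under 1%, comparable to the
low CVs reported for cultivar solidity. Draws whose reconstruction
self-intersects are rejected (≤100 retries). Rasterization places seeds on
a non-touching grid (default 20 px/mm; each seed must span ≥100 px);
round-trip contour extraction recovers areas within 0.1%.

What the generator does **not** emulate: dorsoventral asymmetry of real
seeds (templates are mirror-symmetric about the major axis, and
multiplicative noise preserves that symmetry, so the B/C coefficient
columns stay ≈0 and the PCA of synthetic data is lower-dimensional than
real data); outline texture/roughness; lighting, segmentation and
calibration errors; and between-cultivar diversity beyond three
morphotypes. Passing tests therefore demonstrate the correctness of the
machinery and the recoverability of morphotype contrasts at realistic
noise, not field performance on photographs.

## Pipeline and problem sizes

The default synthetic run mirrors the study design: two reference
populations per model (30/20 seeds for the first model's two harvests,
20/20 for the second's two cultivars) plus one 25-seed test population per
morphotype; models are built from reference Acs, and only test populations
are J-scored (`score_populations`). The end-to-end morphotype-recovery
check uses 10 replicate datasets with 25-seed test populations and 15-seed
reference populations, a size at which each replicate completes in seconds
while the group contrasts (solidity, minimum curvature, max/mean ratio)
remain unambiguous. Reruns with the same config and RNG seed are
bit-identical on all CSV outputs; per-population child seeds derive from
one root seed.

## Known limitations

* Registration is a local optimizer over a 1° sweep; pathological shape
  pairs could in principle hold better poses between grid points, though
  the refinement stage makes this unlikely for seed-like outlines.
* Curvature statistics depend mildly on the Bezier degree; degree is
  reported in every output row for that reason.
* TPS support covers outline records (LM/POINTS blocks with optional
  SCALE); curves-within-specimen variants are not parsed.
* The classification thresholds (90/94) and AR boundary (1.575) are fixed
  conventions of the reference analysis, exposed in configuration rather
  than estimated from data.
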