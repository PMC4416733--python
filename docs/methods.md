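# Methods

This note documents the models and procedures implemented in `soalbp`,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic benchmarks do and do not show.

## Scale estimation

The scale-space is the family of Gaussian-smoothed images `L(·; σ)`
sampled on an exponential grid `σᵢ = c·2^{kᵢ}` with `c = 2.1214` and
exponents from −4 to 8 in steps of 0.25 (49 levels). The constant `c` is
chosen so that the spatial extent `σ·√2` of the level at exponent `k = 0`
equals an LBP radius of 3 pixels; exponential spacing gives fine
resolution at small scales while still covering the large intrinsic
scales of natural textures.

The response profile is `ξ(σᵢ) = Σ_z σᵢ²·|ΔL(z; σᵢ)|`, the image-summed
scale-normalized Laplacian magnitude. Using the full distribution rather
than sparse scale-space extrema makes the estimate usable for textures,
where interest points are unreliable. The first local maximum of ξ
(strictly rising into the point, not rising out of it; plateaus take
their leftmost index; grid endpoints never qualify) seeds a 3-parameter
Gaussian fit `a·exp(−(i−μ)²/2u²)` in level-index space, restricted to
±round(0.10·n) = ±5 levels around the seed and initialized at
`(ξ_seed, seed, 2)`. The fitted mean `s̃` maps to a spatial scale by
exponential interpolation `s = c·2^{k(s̃)}` with `k` linear in the level
index, which keeps ratios between fractional levels meaningful. The
estimate is rejected when `u/n` exceeds `t = 20/n ≈ 0.4082` (i.e. when
`u > 20` levels), or when the fit fails; rejected images use the
fixed-radius fallback. The threshold rule is implemented literally as
stated and is deliberately permissive; it is configurable
(`threshold_t`).

Numerical choices: Gaussian smoothing and the 5-point Laplacian stencil
use reflective boundary handling (zero padding would inject artificial
edge responses), and border pixels are included in ξ.

Two properties worth knowing:

* For an **isolated** same-sign Gaussian blob of scale σ₀ the summed
  profile is `ξ(σ) ∝ σ²σ₀²/(σ₀²+σ²)` — monotone in σ with no interior
  maximum, so the global estimator is *not* a blob detector for a single
  structure (the pointwise normalized-Laplacian response at the blob
  center does peak at σ₀, and that is what the characteristic-scale test
  asserts). The estimator is designed for textures: fields of many
  structures with roughly zero-mean fluctuations, where ξ has a proper
  interior peak.
* White sensor noise contributes a genuine sub-pixel bump to ξ (rising as
  σ² at first, decaying as 1/σ in the continuum): at high noise levels
  the *first-local-maximum* rule can lock onto it. This is a property of
  the rule, not an implementation artifact; the synthetic generator's
  default noise level is chosen below that regime (see below).

## Orientation estimation

Local orientation comes from multi-scale second-moment matrices
(structure tensors): Gaussian-derivative gradients at the *local scale*
(set to the estimated global scale of the image, or to `σ = c` when the
scale estimate is invalid), with tensor components integrated at twice
the local scale. The orientation at a pixel is the angle between the
tensor's major eigen-axis and the vertical image axis, reduced modulo π
(the axis is unsigned). Pixels whose largest eigenvalue is below
`1e−12 ×` the image variance carry no orientation signal and are
excluded.

The global orientation is the mean of a Gaussian fitted to the histogram
of local orientations (1° bins over [0°, 180°); bin width preserves the
claimed angular resolution). The histogram is rolled circularly so its
mode sits at 90°, bins beyond ±15° of the mode are discarded, and the
fit is performed on the remaining window — the roll avoids wrap-around
inside the window. If the fit does not converge the mode itself is used
and the fit std reported as infinite. The field is computed densely (one
tensor per pixel); a `stride` option subsamples for speed.

## Adaptive LBP extraction

The adapted radius is `λ(s, l, ρ) = ρ·s/s̄ₗ`, with `s̄ₗ` the median valid
estimated scale of class `l`'s training images. Linearity of λ in `s` is
what makes the representation scale-invariant; both `s` and `s̄ₗ` are in
σ units so common rescalings cancel.

Sampling supports are matched to the radius by a separable filter with
radius `g_r = λπ/n` (half the arc between adjacent neighbors) and
`σ_g = g_r/(√2·erf⁻¹(P))`, `P = 0.99`, so 99% of the Gaussian mass falls
in `[−g_r, g_r]`. The discrete taps integrate the Gaussian over unit
pixel bins, `w(x) ∝ erf((x+½)/√2σ_g) − erf((x−½)/√2σ_g)` for
`x ∈ [−⌈g_r⌉, ⌈g_r⌉]`, normalized to sum 1 — stabler than point-sampling
a sub-pixel Gaussian. Note the kernel is a *truncated* Gaussian: its
discrete standard deviation converges to the truncated-Gaussian value
(≈ 0.962·σ_g for P = 0.99), not to σ_g itself.

Patterns use `n = 8` neighbors and raw 256-bin histograms. No
uniform/rotation-invariant encoding is applied because alignment happens
at the extraction level: the sampling circle starts at the estimated
orientation `o`. Codes are accumulated over orientation offsets
`o ± 20°` in 5° steps (9 offsets per start; compensates orientation
errors up to about 20°) and over both antipodal starts `o` and `o + π`
(the tensor orientation is ambiguous by π). The orientation-adaptive
mode uses the adaptive sign threshold `T = √std(I_g)` of the filtered
image to damp interpolation-induced bit flips; the pure scale-adaptive
mode uses `T = 0`. With an even `n`, accumulating the antipodal start
permutes bit labels (codes rotate by n/2), so the dual-start histogram
equals the average of the two single-start histograms — the
`dual_orientation` flag exposes the single-start form, which reduces
bin-for-bin to standard LBP on the filtered image when `o = 0`,
`Δo = 0`, `T = 0` and `s = s̄ₗ`.

Neighbors are sampled by bilinear interpolation in the factored form
(exact on lattice points and exactly constant-preserving; near-integer
offsets are snapped at 1e−9 to avoid spurious sign flips at zero
contrast). Pixels closer than `⌈λ⌉+1` to a border produce no pattern.
Intensities are processed as reals in the 8-bit range [0, 255], so `T`
has 8-bit units. One filtered image is computed and cached per unique
adapted radius.

## Meta-descriptor and distance

Training descriptors hold the three base-radius histograms
(`ρ ∈ {1.5, 3, 4.5}`, chosen to bracket the default radius 3 in equal
steps within the discriminative interval) against the image's own class
only; evaluation descriptors hold them against every trained class,
since the true class is unknown and features adapted to a wrong base
scale are uninformative.

Comparing two descriptors for a class keeps a base radius only if both
adapted radii lie in `[1, 5.44]` and differ by at most a factor 3; with
one image at the trained base scale this admits relative scale factors
up to exactly 3 (at factor 3 the pair `(1.5, 4.5)` is still valid). The
surviving histograms are concatenated and renormalized to total mass 1
(divide by the number of survivors) so the histogram-intersection
distance `d = 1 − Σ min` stays in [0, 1] regardless of subset size.
The descriptor distance is the minimum of `d` over classes; it is ∞
when no class retains a valid pair (the descriptors are incomparable in
a scale-adaptive sense), and features referenced to different classes
never enter the same `d`.

Fallback descriptors (failed scale estimation) store plain fixed-radius
LBP at the base radii; they are compared with both radii treated as the
fixed values, under the same subset rules.

## Classification protocol

kNN with the meta-descriptor distance: infinite distances rank last,
distance ties break by training order, vote ties by the smaller mean
distance among the tied classes. Queries whose distances are all
infinite are "unclassifiable" and counted as errors. The
scale-constrained cross-validation draws, per iteration, a stratified
75% of the training images (fixed camera scale) and 25% of the
evaluation images (probe scale), classifies for every `k` from 1 to the
per-class training count (capped at 20), and reports the mean accuracy
over all k values and iterations with the across-iteration std.
Stratification guarantees every class in every training subset; the
subsets are drawn from a single seeded generator, so a seed fixes the
entire experiment.

## Synthetic textures

The generator emulates gray-level material patches with controllable
dominant scale and orientation; `transform` emulates evaluation-set
construction (resample by `q`, rotate, center-crop to 128×128 — the
patch size used throughout the benchmarks).

`dominant_scale` is defined as the characteristic scale at which ξ
peaks. For white noise filtered by a Gaussian of width σ_f the expected
profile is `ξ(σ) ∝ σ²(σ_f²+σ²)^{−3/2}`, peaking at `σ = √2·σ_f`, so the
blob and oriented-noise kinds filter with `σ_f = dominant_scale/√2`; a
grating's profile `σ²·exp(−(2πfσ)²/2)` peaks at `√2/(2πf)`, fixing the
wavelength at `√2·π·dominant_scale`. `dominant_orientation` is the angle
(from the vertical axis, mod π) the structure-tensor estimator reports;
the oriented-noise kind uses an 8:1 anisotropic smoothing rotated into
place on an oversized canvas. Additive white sensor noise defaults to
0.002 of the 8-bit range (≈ 0.5 gray level, a good sensor); well above
roughly 1% the noise bump in ξ begins to capture the first-local-maximum
search at large texture scales (see Scale estimation).

What passing synthetic tests shows — and does not. The generator
produces stationary Gaussian random fields and clean sinusoids: it
exercises the full pipeline (estimation, adaption, alignment,
selection, classification) under exactly known scalings and rotations,
but it has none of the non-Gaussian structure, illumination variation,
shadowing, specularity or perspective of photographed materials.
Accuracy numbers on these fixtures therefore validate invariance
mechanics, not real-world discriminative power.

## Known limitations

* The scale estimate is global: images mixing several dominant scales
  get the first (smallest) one by construction, and per-region scale
  maps are out of scope.
* The uncertainty rule `u > 20` levels is permissive; truly ambiguous
  profiles can pass it. It is exposed as a parameter.
* The orientation estimate degrades gracefully but is meaningless for
  isotropic textures (broad histogram, large fit std); downstream code
  still aligns to it, relying on the ±20° accumulation to absorb error.
* Evaluation descriptors cost `O(classes × radii)` extractions per
  image; the per-radius filtered-image cache helps only within one
  image.
* With an even neighbor count the antipodal accumulation is a histogram
  permutation average; for odd `n` it genuinely adds sampling positions.
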