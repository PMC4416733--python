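# soalbp — scale- and orientation-adaptive Local Binary Patterns

Local Binary Patterns (LBP) describe a texture as the histogram of binary
codes obtained by thresholding, at every pixel, the intensities of `n`
equidistant neighbors on a circle of radius `r` against the center pixel.
Plain LBP is highly discriminative but breaks down as soon as the camera
zooms or the sample rotates: the fixed radius probes structures at the
wrong spatial scale and rotation scrambles the codes.

`soalbp` implements the scale- and orientation-adaptive extension of LBP
(SOA-LBP) for texture classification — e.g. material surfaces or biological
imagery captured at varying magnification and orientation:

* **Global scale estimation.** A Gaussian scale-space `L(·; σᵢ)` is built
  over an exponential grid `σᵢ = c·2^{kᵢ}` (`c = 2.1214`, `kᵢ = −4 … 8`
  step 0.25, 49 levels) and the response profile
  `ξ(σᵢ) = Σ_z σᵢ²·|ΔL(z; σᵢ)|` is summed over the image. The first local
  maximum of ξ seeds a least-squares Gaussian fit; the fitted mean `s̃` is
  the dominant scale level and the fitted std `u` its uncertainty. When
  `u/n > t` (`t = 20/n ≈ 0.4082`) the estimate is rejected and features
  fall back to fixed-radius LBP.
* **Intrinsic-scale adaption.** Each class gets a trained base scale `s̄ₗ`
  (median estimated scale of its training images). An image with estimated
  scale `s` is probed at the adapted radius `λ(s, l, ρ) = ρ·s/s̄ₗ`, so the
  unknown intrinsic texture scale cancels and only the camera scale
  remains. Base radii `ρ ∈ {1.5, 3, 4.5}` give a multi-resolution
  representation.
* **Adaptive sampling support.** Before sampling, the image is filtered
  with a separable Gaussian of radius `g_r = λπ/n`,
  `σ_g = g_r / (√2·erf⁻¹(0.99))`, discretized by integrating the Gaussian
  over unit pixel bins (via `erf`), so every neighbor averages a support
  area matched to its radius.
* **Global orientation and extraction-level alignment.** Structure tensors
  (multi-scale second-moment matrices, integration scale twice the local
  scale) computed at the estimated global scale yield per-pixel
  orientations mod π; a Gaussian fitted to their trimmed histogram gives
  the global orientation `o`. The LBP sampling circle starts at `o`,
  accumulating codes over offsets ±20° (step 5°) and over both antipodal
  starts `o` and `o+π`, with an adaptive sign threshold `T = √std(I_g)`.
* **Meta-descriptor and distance.** All per-class, per-radius histograms
  of an image form a meta-descriptor. Comparing two descriptors keeps only
  radius pairs inside the discriminative interval `[1, 5.44]` with ratio
  ≤ 3, concatenates the survivors, and scores them by histogram
  intersection `d = 1 − Σ min(H₁, H₂)`; cross-class features are
  incomparable (distance ∞). A kNN classifier with a scale-constrained,
  iterated 75%/25% cross-validation protocol evaluates the pipeline.

A seeded synthetic-texture generator (blob noise, gratings, oriented
band-pass noise with known dominant scale and orientation, plus exact
rescale/rotate transforms) provides the test and benchmark imagery.

## Worked example

`examples/05_crossval.py` trains on three synthetic texture classes at the
base camera scale and classifies evaluation images magnified by `2^0.75`
(≈ 1.7×):

```
adaptive (SOA-LBP) accuracy at relative scale 2^0.75: 1.000 +- 0.000
fixed-radius multi-resolution LBP accuracy:          0.717 +- 0.170
```

The adaptive pipeline is unaffected by the 1.7× magnification because the
adapted radii follow the estimated scale, while fixed-radius LBP probes
the wrong structures and loses about a third of its accuracy. The other
example scripts demonstrate one stage each — scale estimation
(`01`, prints `s = 4.29 px` for a texture generated at 4 px), orientation
estimation (`02`, tracks a 60° rotation to within a degree), adaptive
extraction (`03`, shows the radius/kernel bookkeeping and the exact
reduction to standard LBP), and descriptor distances (`04`, same-class
distance 0.04 vs cross-class 0.52).

A thin CLI mirrors the pipeline for shell use:

```sh
soalbp synth --kind blobs --scale 4 --n 8 --seed 1 --out fixtures/
soalbp estimate-scale fixtures/blobs_s4_o0_000.png
soalbp train --images fixtures/ --labels fixtures/labels.csv --out train.jsonl
soalbp extract query.png --train-db train.jsonl --out query.jsonl
soalbp classify query.jsonl --train-db train.jsonl --k 3
```

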