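# Methods

This note records the model, the conventions and the genuinely open design
choices behind `uwenhance`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Image model and pipeline

All stages operate on H×W×3 float arrays in [0, 1] (sRGB primaries, D65
white for CIELab, hue as a fraction of a turn). Files are read through
standard codecs; 8-bit writes quantize round-half-up so outputs are
platform-independent.

### Adaptive colour compensation

The channel means are ranked and two scalar coefficients
`m = (Ī_max − Ī_min)/(Ī_max + Ī_min)` and `n = (Ī_max − Ī_mid)/(Ī_max + Ī_mid)`
boost the attenuated channels per pixel by the corresponding fraction of
the dominant channel. The coefficients are deliberately *scalars built
from channel means*: ranking only makes sense at channel level, and scalar
coefficients keep the stage linear in the mean (the boosted channel's mean
is exactly `Ī_min + m·Ī_max` when nothing clips). Output is clipped to
[0, 1]; ties in the ranking are broken by fixed channel priority R, G, B;
an all-black image is flagged degenerate and passed through.

### Retinex with rolling-guidance illumination

Reflectance per channel and scale is `log(I+ε) − log(L+ε)` where the
illumination L comes from a rolling guidance filter rather than a plain
Gaussian surround: first a Gaussian pass (kernel truncated at ⌈3σₛ⌉,
reflected borders) erases small-scale texture, then `t` joint-bilateral
iterations — input always the original channel, range kernel always on the
*previous iterate* — restore large-scale edges. Multi-scale output is the
weight-averaged reflectance over the surround scales.

Defaults: scales (15, 80, 250) px with equal weights (the classic surround
triple), σ_r = 0.1, t = 4, ε = 1/255. All configurable; for small images
the scales should be reduced proportionally to the width (the benchmark
grid at 160×120 uses 6/32/100).

**Numerics.** The joint bilateral step has two evaluation paths that agree
to well under visible levels (a regression test bounds them against each
other at 1e-3, and 16 bins measure ~4e-5 on smooth guides):

* *exact*: shift-wise accumulation over the full truncated window — the
  textbook double sum, verified against a brute-force double loop at
  1e-10. Cost grows with the window area, so it is selected automatically
  only when `window_area × n_pixels` is small.
* *interp*: the range kernel is sampled at `range_bins` (default 16)
  evenly spaced guide levels; each level needs only two separable Gaussian
  filters, and the result is piecewise-linearly interpolated at each
  pixel's own guide value. Spatial resolution is never reduced — this is
  a range-sampling scheme, not a bilateral grid — and the result converges
  to the exact path as the bin count grows.

The log-domain reflectance is mapped to a displayable image by one linear
stretch shared by all three channels (pooled 1st → 0, 99th percentile → 1,
clipped; a flat map becomes 0.5). The bounds are pooled on purpose:
per-channel stretching would re-introduce an arbitrary cast right after
the Retinex stage removed the per-channel illumination. A flat guide in
the bilateral step degenerates exactly to the Gaussian pass, and σ_r → ∞
recovers classical MSR; both limits are tested.

Scale behaviour worth knowing: reflectance is invariant to a global
intensity scaling *only if σ_r is scaled along with the image* — the range
kernel is not scale-equivariant on its own. The joint form is what the
property test asserts.

### CLAHE and adaptive gamma

CLAHE runs on the V channel only (H and S are untouched end to end), with
an 8×8 tile grid, clip limit 2.0 (as a multiple of the uniform bin height)
and 256 bins — values from the CLAHE/AGCWD literature. Histogram clipping
caps bins at `ceil(clip·total/bins)` and spreads the excess uniformly,
iterating while the residual excess exceeds one count; mass is conserved
exactly at every step, and an unsatisfiable cap (below the mean bin
height) simply stops when the excess stalls. Each pixel is remapped by
bilinear interpolation between the four surrounding tile cdfs; edge pixels
use the tiles that exist.

Adaptive gamma correction builds a weighted histogram
`pdf_w = pdf_max·((pdf − pdf_min)/(pdf_max − pdf_min))^α` (α = 0.5), its
normalized cdf, and applies `T(l) = l_max·(l/l_max)^{1−cdf_w(l)}` on the
256-level quantization of V. A uniform histogram (the 0/0 case of the
weighting) degenerates to the plain cdf; `T(0) = 0` always, including when
`cdf_w(0) = 1`. T is provably nondecreasing whenever cdf_w is.

Note that "identity-like on constants" means *spatially constant in,
spatially constant out*: equalizing a single-spike histogram legitimately
moves the constant's value (a flat image has no contrast to preserve).

### Multi-weight fusion

The paper-level description names only the weight side of the fusion, so
the open choices were settled as follows and are part of this package's
definition: the two fused inputs are the normalized Retinex image and the
contrast-enhanced image; per input, contrast (|3×3 Laplacian| of
luminance), brightness (RMS deviation of R,G,B from luminance) and
saliency (|Gaussian-smoothed luminance − global mean|, σ = 5 px, absolute
value because a weight must be nonnegative) are *summed* — a product would
zero out on flat regions — and normalized across inputs with a δ = 1e-3
regularizer. Inputs are decomposed into 5-level Laplacian pyramids
(5-tap binomial kernel; upsampling uses mirror extension so constants
reconstruct exactly), weights into Gaussian pyramids, blended per level
and collapsed. Because decimated smoothing preserves a pointwise-unit
weight sum, fusing an image with itself returns it to within 1e-6.

## Quality metrics

The four no-reference scores have several circulating dialects; the ones
fixed here are:

* **Entropy**: Shannon entropy (bits) of the 256-bin histogram of the
  8-bit-quantized luminance (= channel mean).
* **AG**: on the 0–255 scale, per channel, mean over interior pixels of
  `sqrt((Gx² + Gy²)/2)` with forward differences, averaged over channels.
  The forward-difference grid is anchored at the top-left corner, so AG is
  exactly invariant under transposition and only approximately (boundary
  band) under flips.
* **UCIQE** = 0.4680·σ_chroma + 0.2745·con_lum + 0.2576·μ_sat in CIELab,
  with chroma and L* on their native scales and L* divided by 100 for the
  contrast term only; saturation is chroma/√(chroma² + L*²) with 0/0 → 0.
* **UIQM** = 0.0282·UICM + 0.2953·UISM + 3.5753·UIConM on the 0–255
  scale. UICM uses α-trimmed (α = 0.1 per tail) means/variances of
  R−G and (R+G)/2−B with sub-coefficients (−0.0268, 0.1586); UISM is the
  EME (2/(k₁k₂)·Σ ln(max/min) over 8×8 blocks) of Sobel-magnitude-weighted
  channels under BT.601 weights; UIConM is a PLIP-free logAMEE: the mean
  over 8×8 blocks of −w·ln w with w = (max−min)/(max+min). Blocks with
  zero dynamic range or zero sum contribute 0.

Because of dialect spread, scores are comparable only within one
implementation; the package therefore reports *changes* under enhancement
rather than chasing any published absolute table.

## Detection-side math

Boxes are corner-format with continuous coordinates (no +1 widths). The
ECIoU loss adopts the CIoU aspect term `v = (4/π²)(atan(w^gt/h^gt) −
atan(w/h))²` and trade-off `α = v/((1−IoU)+v)` (0 when v = 0), plus EIoU's
separate width/height distance ratios over the enclosing box. The loss is
zero iff the boxes coincide, translation- and scale-invariant, and each
penalty ratio individually lies in [0, 1].

AP is all-point interpolated (the integral reading of the area under the
precision-recall curve), not 11-point; ties in score keep input order.
Greedy matching walks detections per class by descending score and takes
the best-IoU unmatched ground truth at threshold 0.5.

The BRA forward pass reads the attention call as Attention(Q, K^g, V^g)
(the Q is an evident typo target in the source description), scales logits
by 1/√C, breaks top-k ties toward the lower region index, and implements
the local context term as a caller-supplied depthwise 5×5 cross-correlation
with zero padding. With k = S² it provably equals dense attention, which a
loop-based oracle verifies for S ∈ {1, 2, 4}.

## Synthetic data: what it does and does not emulate

Scenes are procedural (gradient + band-limited texture + high-chroma discs
and stars) and degradation follows the attenuation–backscatter model with
channel-wise β, blue-green veiling light (0.08, 0.45, 0.55), optional line
motion blur and seeded Gaussian noise. The fixture grid cycles five
conditions (mild cast, strong cast, haze, noise, strong cast + blur);
strong-cast settings (β = (0.9, 0.35, 0.12), d = 2) produce channel-mean
spreads ≥ 0.1 by construction.

This emulates the *first-order physics* of underwater degradation — wavelength-dependent attenuation, additive haze, contrast loss — but not
forward-scattering blur kernels, depth-varying transmission within a
scene, flicker/caustics, or the texture statistics of real benthos.
Passing the end-to-end checks therefore shows the pipeline reverses the
modelled degradations, not that it matches human preference on real
footage.

## Benchmark problem sizes

The end-to-end benchmark (`uwenhance.benchmark`, also used by
`scripts/acceptance.py`) runs 20 fixture pairs at 160×120 with surround
scales (6, 32, 100) — the classic triple scaled to the fixture width.
These sizes keep the exact-within-tolerance filtering tractable on a
single CPU while leaving every stage (multi-scale surround, tiling,
pyramid depth 5) meaningfully exercised; the improvement criterion
(each metric up on ≥ 18/20 images, cast strictly shrunk on every
strong-cast fixture) does not depend on the resolution choice.

## Known limitations

* The interp bilateral path is an approximation with a measured, bounded
  error; pathological guides (near-discrete histograms with σ_r far below
  the bin spacing) would need more range bins.
* UCIQE/UIQM absolute values are dialect-specific (see above).
* CLAHE's tile cdf mapping sends a flat tile to its histogram cdf value
  (1.0), as plain equalization dictates; callers who want value-preserving
  behaviour on flat regions should rely on the gamma stage's endpoint
  conventions rather than CLAHE.
* The dynamic-blur (camera/subject motion) side of underwater degradation
  is out of scope; only the synthetic generator's line-blur kernel touches
  it.
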