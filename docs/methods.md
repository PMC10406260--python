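# Methods

`contexseg` studies how contrast- and texture-based image modifications,
applied at training and/or test time, change the performance and the
spatial attention of small U-Nets segmenting brain tissue (CSF, gray
matter, white matter) across simulated MR acquisition protocols. This
note documents the models, the numerical choices, and what the
synthetic data does and does not emulate.

## Phantom simulation

Anatomy is a 2D nested-ring head: a background border, a CSF rim, a GM
ribbon, a WM core and a ventricle-like CSF interior, warped by a smooth
random displacement field (two white-noise fields blurred with a
Gaussian of sigma = H/8, rescaled so the peak displacement is
`0.04 * H * variability` pixels, applied with nearest-neighbour
resampling so labels stay crisp). A phantom is rejected if any tissue
class vanishes after warping. `variability` defaults to 0.5, i.e. a
peak displacement of ~2% of the image height — enough that subjects are
visibly distinct while every anatomy keeps the same topology.

Tissue intensity under a spin-echo protocol (TR, TE in ms) follows

    S = PD * (1 - exp(-TR/T1)) * exp(-TE/T2)

with 1.5T-like defaults: CSF (T1=2400, T2=160, PD=1.0), GM (900, 90,
0.85), WM (600, 75, 0.75). These are plumbing defaults chosen from
standard relaxometry ranges, configurable via `TissueNMR`. Over the
42-protocol grid (TR 300..800 step 100, TE 10..40 step 5) they produce
the qualitative behaviour that matters for the study: tissue contrast
varies strongly with (TR, TE), and at short-TR/long-TE corners GM and
WM approach iso-intensity.

Acquisition noise is additive Gaussian, clipped at zero, with
`noise_sigma = 0.03` by default — roughly the GM-WM signal difference
at mid-grid protocols, so protocols genuinely differ in difficulty. An
optional low-order polynomial multiplicative bias field (off by
default) emulates intensity non-uniformity.

What the phantoms do **not** emulate: real cortical folding and
partial-volume mixing, 3D anatomy (the pipeline is 2D by design, as the
segmentation model is a 2D U-Net; `select_slices` supports percentile
slice picking — nearest-rank rule — for users bringing 3D volumes),
scanner-specific artefacts, and pathology. Passing tests therefore show
that the *mechanisms* (filter mathematics, grid bookkeeping, training
determinism, attribution arithmetic) are correct and that the
qualitative train/test-modification phenomena are reproducible on
controlled data — not that effect sizes transfer to clinical images.

## Modification filters

**Contrast** (gain G, integers 2 <= |G| <= 21 on the study grid): with
`h(G) = (1 - e^{-G/2}) / (1 + e^{-G/2}) = tanh(G/4)` and m = max
foreground intensity,

    G > 0:  f_c = m * h(f/m * G) / h(G)
    G < 0:  f_c = (2m/G) * ln[(m + f h(G)) / (m - f h(G))]

The negative branch is the analytic inverse of the positive one, so
`apply(G)` then `apply(-G)` is the identity; both branches fix 0 and m
and are strictly increasing bijections of [0, m]. Since h is concave on
[0, inf), the G > 0 branch lies above the identity: it steepens the
dark end of the intensity range (raising CSF relative to GM/WM) and
compresses the bright end. A numerical guard clamps `f*|h(G)|` to
`(1 - 1e-12) m` before the logarithm. Foreground means labelled tissue
when labels are available, else positive intensities; `max(f)` is
computed per 2D slice.

**Texture** (weight alpha, same integer range): TV smoothing solves

    argmin_u  TV(u) + alpha * sum (f - u)^2

with isotropic discrete TV (forward differences, Neumann boundaries).
Smaller alpha smooths more. Sharpening for alpha < 0 reflects the
smoothed image about the original: `f_t = 2 f - u(-alpha)`, which holds
as an exact pointwise identity in the implementation. Solver:
split-Bregman with penalty lambda = 2 alpha, the linear u-subproblem
solved exactly per iteration by a type-II DCT (which diagonalizes the
Neumann Laplacian), isotropic shrinkage for the auxiliary gradient
field, stopping when the relative change of u falls below 1e-4 or after
200 iterations (a warning reports the achieved residual otherwise).
Intensities are normalized to [0, 1] by the maximum foreground value
before the solve and rescaled after, so alpha is scale-free. Tests
verify the minimizer against an independent convex solver (smoothed-TV
L-BFGS) on 8x8 instances and against scikit-image's split-Bregman
implementation via objective dominance.

Modifications are applied to raw non-negative intensities *before*
z-score normalization: the contrast filter requires f in [0, max(f)]
and its log branch requires f h(G) < max(f), both violated by z-scored
images.

## Segmentation model and training

A plain 2D U-Net (two 3x3 conv + ReLU per level, dropout before each
2x2 max-pool, nearest-neighbour upsampling with skip concatenation, 1x1
softmax head over 4 classes — background is an explicit class so the
softmax label set is exhaustive). The network, its backpropagation and
Adam are implemented directly in numpy: the package needs gradients
with respect to the *input image* for attribution, training runs are
bit-deterministic given a seed, and the training problems are small
enough that one CPU suffices.

One training trial fixes a modification setting, applies it to every
training **and** validation image (then z-score: foreground mean 0 /
population SD 1, background set to the minimum normalized value),
minimizes the mean per-class cross-entropy (per-class pixel means
averaged over classes present, so background does not swamp the
tissues) with Adam, evaluates validation loss each epoch, and returns
the parameters of the epoch with the lowest validation loss (ties:
earliest epoch). Dropout is active only during training steps;
prediction and saliency run deterministically.

Reference-scale settings (250 epochs, learning rate 1e-4, dropout 0.5,
288x288 inputs) remain expressible through `ModelConfig`/`TrainConfig`.
The scaled-down study defaults are 48x48 phantoms, depth 2, 8 base
channels, dropout 0.1, Adam 5e-3 for 60 epochs, batch 8: at 8 base
channels a 0.5 dropout rate removes half of a drastically smaller
feature budget and made a sizeable fraction of runs collapse, so the
rate is scaled with capacity; the learning rate and epoch count were
chosen so the unmodified baseline trains to a stable plateau within a
desk-scale compute budget.

## The train x test modification grid

Axes hold one modification kind plus the unmodified "Ori" setting at
the center (scaled-down default strengths: -21, -11, -4, Ori, 4, 11,
21). For each train setting and each of `n_runs` repeats (run r seeds
with `base_seed + r`), a model is trained and evaluated under every
test setting: per-tissue Dice per test image, averaged within protocol,
then over runs and protocols, giving one CSF/GM/WM heatmap each. The
per-protocol tensor is retained and its protocol-mean reproduces the
heatmap exactly (asserted). Completed (setting, run) pairs are cached
on disk (evaluations plus model checkpoints), so interrupted grids
resume; a failed training marks its cells missing and the grid
continues. Extremes: best/argmax and worst/argmin of the unweighted
CSF/GM/WM mean (row-major tie-break), plus the point reflection of the
worst cell through the center ("opposite bad"). The relative
improvement of any cell is `(value - original) / original` against the
(Ori, Ori) cell. The default scaled grid trains 7 x 3 = 21 models and
performs 7 x 7 x 6 = 294 protocol-level evaluations; 41 x 41 axes at
reference scale would enumerate 1,681 models and 70,602 evaluations.

## Integrated Gradients for segmentation

For class l the attribution of input pixel i sums IG over all output
pixels, which collapses to one path integral of the gradient of the
*summed* class-l probability map:

    IG_i = (x_i - x'_i) * ∫_0^1 d[ Σ_mn F^l(x' + β (x - x'))_mn ] / dx_i dβ

The path runs from the baseline x' (all-zeros in network input space by
default; configurable) to the input x. Note the interpolation is
`x' + β (x - x')` — the convention in which β = 1 reaches the input,
which is the form completeness requires. Quadrature is trapezoidal
with n_steps = 16 (Δβ = 1/16; weights (1/2, 1, ..., 1, 1/2)/n, n+1
gradient evaluations), exact for models linear in the input at any
n_steps >= 1. Maps are rescaled by the affine transform sending their
own 5th/95th percentiles (numpy linear-interpolation percentiles,
per map) to -1/+1, then clipped to [-1, 1]; values that land inside
(-1, 1) are not re-clipped. Rescaled maps are averaged across the
models of a grid cell and differenced between cells (best, original,
worst, opposite-bad) on one image of the representative protocol
(nearest grid protocol to TR = 500, TE = 25) to visualize attention
shift. No scalar attention-shift statistic is asserted — the
phenomenon is reported qualitatively, via difference maps and the
foreground/background activity fractions the acceptance script prints.

## Determinism

Every operation is a pure function of its arguments including seeds;
all randomness flows through explicit numpy Generators; training,
evaluation and attribution contain no unordered reductions beyond
numpy's deterministic ones. Two pipeline runs with the same seed
produce bit-identical heatmap CSVs (asserted in the tests).

## Known limitations

- Phantom geometry is far simpler than cortical anatomy; absolute Dice
  values are not comparable to values reported on real brain data, and
  the package deliberately does not claim them.
- The numpy U-Net is small; at reference scale (288x288, depth 4+) a
  GPU framework would be the right tool. The module boundary
  (`train_model` / `predict_probs` / input gradients) is framework
  agnostic.
- TV smoothing is not invertible, so the texture round trip is not an
  identity — only the 2f - u reflection identity is asserted.
- The per-map percentile rescaling choice (rather than per-label or
  per-model-set) affects difference-map magnitudes; it is flagged in
  the code and kept fixed throughout.
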