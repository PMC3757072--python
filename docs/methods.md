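# Methods

## Model

The package implements population sparse coding of image patches as a
dynamical system. A patch **x** (P×P pixels, P = 16 by default) is encoded
by rates **a** that minimize the energy
E(**a**) = ½‖**x** − Φ**a**‖² + λΣ|aᵢ|, where the columns of Φ are
unit-energy spatial elements interpreted as classical receptive fields.
The Locally Competitive Algorithm computes the code: each unit is a leaky
integrator with membrane potential uᵢ, driven feedforward by ⟨φᵢ, **x**⟩
and recurrently by −Σ_{j≠i}⟨φᵢ, φⱼ⟩aⱼ, with rate aᵢ = T_λ(uᵢ) (soft
threshold). Competition is inhibitory between units with positively
overlapping CRFs and excitatory otherwise. With a mirrored dictionary
[Φ, −Φ] and the nonnegative threshold, rates are interpretable as firing
rates; a mirrored pair is never jointly active at a minimizer (verified as
a test invariant).

Assumptions worth stating: there is no contrast-saturation mechanism, so
contrast-response curves grow without saturating; all nonlinearity beyond
thresholding comes from recurrent competition; the simulated visual field
is a single patch, so effects requiring long-range interactions are out of
reach.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| λ | 0.1 | — | sparsity/fidelity tradeoff and rate threshold |
| τ | 10 | ms | membrane time constant (low end of the 10–100 ms physiological range) |
| dt | 10/7.5 ≈ 1.33 | ms | Euler step; 25 steps span one 1/30 s video frame |
| steps/frame | 25 | — | integration steps per movie frame |
| static steps | 1000 | — | steps for static (steady-state) protocols |
| contrast | 0.3 | — | peak-to-trough stimulus intensity range, unless a protocol sweeps it |
| temporal frequency | 3 | Hz | drift rate of gratings (10 frames/cycle at 30 fps) |

τ at the low end of the physiological range means 25 steps per frame reach
only partial convergence; this partial convergence is what keeps the
population's suppression statistics in the physiological regime (full
convergence — the `high_sparsity` CLI preset — drives most units to
complete surround suppression). dt < τ/2 is enforced; dt ≥ τ raises.

Integration records the rate vector at every Euler step; drifting-grating
statistics (mean rate, F1 amplitude at the drift frequency) are computed
over all steps of one full temporal cycle with equal weighting, starting
from the zero network state per condition. The Gram matrix ΦᵀΦ is computed
once per dictionary and cached; mutating elements requires an explicit
cache invalidation.

## Whitening and stimuli

Images and stimuli pass through the radially symmetric frequency-domain
gain f·exp(−(f/f₀)⁴), zero at DC, with f₀ = 200·(side/512) cycles/image so
the filter shape is resolution invariant (f₀ = 6.25 on the 16-px stimulus
grid). Whitened training images are rescaled to unit variance (makes the
training λ scale-free); stimulus preparation applies no data-dependent
rescaling, so prepared stimuli are exactly linear in contrast above DC.

Stimuli are rendered with hard-edged apertures at pixel centers on a gray
background equal to the sinusoid mean: grating discs, 2-px-thick annuli
(inner radius = center radius + optional gap), light/dark bars, and plaids
(sum of two grating fields minus one background). Orientation is degrees
counterclockwise from horizontal on [0, 180); the sinusoid phase argument
is sf·(Δrow·sinθ + Δcol·cosθ) + φ. Drifting gratings are discretized as
static frames at phase increments 2π·f_t/f_frame with center and surround
(or test and mask) phase-locked.

## Protocols

The optimal-grating search sweeps the printed grids (size 1–16 px step
0.5, orientation 0–175° step 5°, SF 0.5–2 rad/px step 0.25, phase 0–2π
step π/4) and maximizes the unit's steady-state rate. The default
implementation is two-pass: (orientation, SF, phase) at the middle grid
size, then all sizes and phases with orientation/SF restricted to one grid
step around the coarse winner; the coarse pass must sweep phase because at
a pessimal phase the mirror partner absorbs the response and the target
reads zero at its own orientation. A single-pass brute-force mode exists
for verification. Ties break to the first candidate in lexicographic
order. Protocol-internal static sweeps run batched in single precision
(rate error ~1e−5, far below any grid spacing); oracle comparisons use
double precision throughout.

End-stopping: 2-px-wide bar at the optimal orientation, location optimized
over a 5×5-pixel neighborhood of the grating center, length swept 1–16 px,
steady-state rate. Size tuning: drifting discs, sizes 1–16 px, contrasts
{0.05, 0.15, 0.25, 0.35, 0.45, 0.5}, F1 statistic; SI and peak sizes are
read at 0.5 (high) and 0.05 (low). Orientation tuning: drifting
optimal-size disc, 0–180° step 5°, contrasts 0.1–0.5 step 0.1, mean rate;
half-width = 1.17σ of a circular Gaussian fit (wrapped distance on the
180° domain), with fits that fail or pin σ at the 90° bound recorded as
exclusions. The half-width slope is fit against contrast rescaled to
[0, 100]. Center–surround: center fixed at the optimal orientation,
2-px-thick annulus swept in orientation, both drifting phase-locked;
facilitation ratio = max of the surround tuning over the center-alone
optimum, measured with center and surround at the same contrast (0.5 and
0.05). Contrast response: center contrast on the logarithmic scale
(0, 0.03, 0.06, 0.12, 0.25, 0.5) with surround fixed at 0.5, or the
surround swept with the center at 0.3. Cross-orientation: plaid = optimal
test + mask in the same disc, mask drifting phase-locked; ratios compare
plaid to test-alone F1 at test contrasts 0.5/0.1 with mask contrast equal
to the test contrast.

## Synthetic data

The image generator replaces a natural-scene corpus with two seeded
models: dead leaves (opaque disks composited until coverage, radii from a
power law with exponent 3 on [2, side/4] px, uniform intensities) and
1/f-spectrum Gaussian noise. Dead-leaves ensembles share natural images'
scale-invariant power spectra and occlusion edges — the features that
drive the emergence of localized, oriented, band-pass elements — but lack
textures, shading and higher-order structure; passing tests therefore
demonstrate the mechanism, not photometric realism. The Gabor fixture
dictionary (default 5×5 centers × 8 orientations × 2 phases on 16×16)
provides ground-truth CRFs so protocol tests close the loop in seconds;
the test and acceptance batteries use a reduced 3×3-center lattice (288
effective units) and record 10 units so the full battery completes in
minutes on one CPU.

Sparse generative sampling draws patches Φ**a**\* + ε with k active
|N(0, amp_sd)| coefficients and i.i.d. Gaussian pixel noise, the harness
for planted-basis recovery and single-atom identification tests.

## Dictionary learning

Learning alternates exact ℓ1 inference (coordinate descent per patch) with
an element-wise gradient step on the reconstruction error,
φⱼ += lr·gⱼ·(X − ΦA)aⱼᵀ with per-element gain gⱼ = 1/Σaⱼ², applied in
three inner sweeps per minibatch. The gain equalizes update magnitude
across elements with unequal coefficient energy — heavily used elements
take proportionally smaller steps — which keeps usage balanced; a plain
averaged gradient step without it stalls on mixtures (≈0.6 correlation on
the planted-basis problem versus ≈0.999 with the gain). Elements are
initialized from random training patches, unused elements are re-seeded
from the worst-reconstructed patch of the batch, and every element is
renormalized to unit energy. The mean per-patch energy is logged per
epoch; divergence raises with diagnostics. Desk-scale study conditions
fixed once: planted recovery uses 600 patches, k = 3, noise 0.01, 20
epochs; dead-leaves training uses 10 images at 128 px, 5000 patches of
8×8, 64 elements, λ_train = 0.5, 10 epochs.

## Numerical choices

- Euler integration in u-space; the batched integrator optionally freezes
  columns whose per-step ‖Δu‖∞ falls below a tolerance (used only where a
  converged steady state is the target; protocol sweeps always run the
  full 1000 steps because early stopping measurably biases slow-mode
  amplitudes).
- Oracle comparisons run the LCA at dt = τ/4 with a 1e−12 stopping
  tolerance; stability requires the step × the largest active-submatrix
  Gram eigenvalue to stay below 2, which rules out dt near τ for coherent
  dictionaries.
- The energy-descent property is checked at dt = τ/10, where the
  discretized trajectory is conservative.
- Localization selection: ≥90% (80% at the 8×8 desk scale) of squared
  amplitude within the central window (¾ of the patch side by default).
- CRF centers are the maximum-|amplitude| pixel of each element
  (config-overridable); fixture dictionaries carry exact ground truth.
- Degenerate stimuli: a zero-SF "grating" renders as a uniform light patch
  (the uniform-surround control); apertures clipped by the patch edge log
  one warning per geometry.

## Design choices and limitations

The SI direction is fixed so non-suppressive cells score 0 and complete
suppression scores 1; the expansion ratio is low-over-high contrast so
values > 1 mean expansion at low contrast (an inversion flag exists).
Surround facilitation at the default center radius is weak in the fixture
population (medians near 1); facilitation grows with the center-radius
offset, which is exposed. The fixture population is small (10 recorded
units) and geometrically regular, so population statistics are coarser
than a learned 4×-overcomplete dictionary would give; the full-scale
replication (16×16 patches, 1024 effective learned elements, all
well-localized units) runs through exactly the same code path via
`SparseCoding.from_images` + `run_population` but takes hours and is not
part of the test battery. Unstated protocol details follow the defaults
recorded here: units reset to the zero state between conditions, bars are
light by default (polarity flag), the optimal-search phase grid step is
π/4, and plaid masks drift phase-locked with the test.
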