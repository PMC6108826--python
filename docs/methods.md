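# Methods

## The model

The core object is a temporal prediction network: a fully connected
feedforward network with one hidden layer that maps the recent past of
a sensory clip to an estimate of its immediate future. Hidden unit *j*
computes *s_j = h(b_j + Σ_i w_ji u_i)* with a monotone nonlinearity
*h* (logistic by default; tanh, linear and relu are supported), and
output unit *k* computes *v̂_k = b_k + Σ_j w_kj s_j*. The cost is the
mean squared prediction error over clips and output variables plus an
L1 penalty of strength λ on both weight matrices; biases are not
penalized. Because the input weights of a hidden unit act as a linear
template ahead of a static nonlinearity — the standard LN description
of sensory neurons — those weights, reshaped onto the stimulus grid,
are read directly as the unit's receptive field (RF).

Optimization is minibatch Adam (defaults lr = 1e-3, β₁ = 0.9,
β₂ = 0.999, ε = 1e-8, batch ≈ 200) on analytic backprop gradients. The
L1 term is handled by plain subgradient (sign, with 0 at 0), not a
proximal step; this keeps the optimizer exactly "backprop on the cost"
and is tested against central finite differences for all four
nonlinearities. Weights initialize i.i.d. Gaussian with sd
1/√fan-in, biases at zero, all seeded; training is bit-reproducible
given the seed. Reported validation MSE always excludes the penalty
term, so it is a pure prediction error. Epoch counts are configurable;
convergence, not a fixed iteration count, is the criterion that
matters, and the desk-scale defaults (tens of epochs) are chosen so
the training curves have flattened on the synthetic corpora.

### Sign convention

For the logistic nonlinearity, h(a) = 1 − h(−a), so negating a hidden
unit's input weights, output weights and bias while adding its output
weights to the readout bias leaves every prediction unchanged. Each
unit's RF sign is therefore arbitrary, and we fix it by leading
excitation: a unit is flipped when the sum of its RF coefficients over
the most recent quarter of time steps is negative. For tanh and linear
units the flip is the odd-symmetry version (readout bias unchanged);
for relu no sign symmetry exists and the flip is refused.

### Inactive units

With many hidden units and L1 pressure, some units disconnect. A
unit's strength is the sum of its squared input weights; units below
1% of the population maximum are marked inactive and excluded from RF
analyses (they remain in the network).

## Data pipeline

**Visual.** Movies are square-cropped (centered along the longer
dimension), each frame band-pass filtered in the frequency domain with
gain R(f) = f·exp(−(f/f₀)⁴), f₀ = 0.4 × Nyquist — zero at DC, rising
with radial frequency (whitening the ~1/f spectrum of natural scenes),
rolling off quartically — then bilinearly downsampled to 180 × 180
(cell-centered sampling, which makes same-size resampling an exact
identity). Non-overlapping 20 × 20 patches tile a central 100 × 100
region and are cut into 8-frame clips at stride 1. Whitening precedes
downsampling, following the processing order of the frontend's
description; the two orders differ only through the resampling kernel's
stopband. The network sees 7 past frames (I = 2800) and predicts the
last (K = 400).

**Auditory.** Waveforms at 44.1 kHz become power spectrograms (10 ms
Hamming windows, 5 ms hop), aggregated into 32 channels by triangular
windows that are symmetric on the log2-frequency axis with a 1/3-octave
base, linearly interpolated onto FFT bins and normalized to unit
column sum. The printed channel endpoints (500 and 17,827 Hz) are not
exactly consistent with uniform 1/6-octave steps; we place the 32
centers geometrically so both endpoints are hit exactly (step
log2(17827/500)/31 ≈ 0.16632 oct). Each band is divided by its
training-set median (medians under 1e-12 are clamped, so silent test
fixtures never divide by zero) and compressed with h(x) = cx/(1+cx),
c = 0.02, emulating auditory-nerve intensity compression. Clips are 43
steps; the first 40 (200 ms) are the past (I = 1280), the last 3 the
future (K = 96). We note the 43-step/5-ms arithmetic (215 ms per clip)
as the operative definition.

**Normalization and noise.** Datasets are z-scored with scalar mean/sd
computed on the training portion and reused verbatim for validation.
Gaussian noise at 6 dB SNR is added after z-scoring, so "6 dB" is
defined against unit signal variance (noise variance 10^(−0.6)); the
noise is seeded and the empirical SNR over ≥ 1e5 entries is tested to
±0.1 dB. Flattening order is fixed (time slowest, then row/frequency,
then column) and enforced by round-trip tests.

## Sparse coding control

The control model reconstructs the same flattened clips as Φa with
unit-norm basis columns and an L1 penalty on the code. Inference is
FISTA with step 1/L (L the top eigenvalue of ΦᵀΦ) and early stop at
relative objective change < 1e-6; it is tested against the closed-form
soft-threshold solution for an identity basis and an independent
cyclic coordinate-descent solver. Dictionary learning alternates
batched inference with a residual-driven gradient step on Φ and
renormalizes columns after every update — the standard recipe for this model family, in
which only the inference algorithm and learning rate are canonical.
Basis functions are reshaped and sign-normalized exactly like network
RFs for comparison.

## RF metrics

**Auditory.** An STRF splits into an excitatory (positive part) and
inhibitory (negative part) subfield — an exact partition; inhibitory
subfields with < 5% of the excitatory power are treated as absent.
Spans come from the first singular-vector pair of each subfield: the
count of entries exceeding 50% of the vector's maximum. Absolute
values are used and the vector sign is fixed so its largest-magnitude
entry is positive, removing SVD sign ambiguity (the choice only aids
determinism). Spans are reported in bins (5 ms or nominal 1/6 oct).
Population similarity is the mean of the four two-sample KS statistics
(excitatory/inhibitory × temporal/spectral spans); empty components
are dropped from the mean with a warning. MDS is classical Torgerson
scaling — deterministic eigendecomposition of the double-centred
squared-distance matrix — rather than iterative stress minimization,
and is exact on planar configurations. Model RFs are trimmed by their
two least recent bins to match latency-trimmed 38-step neural grids.
STRF estimation from a response time series solves
min_w Σ(r_t − w·history_t)² + λ‖w‖₁ by cyclic coordinate descent with
soft-thresholding.

**Visual.** The optimal time step maximizes spatial mean-square power
(ties break toward the most recent bin). Gabor fitting is two-stage:
the FFT magnitude of the frame (a Gaussian lobe pair for a Gabor, DC
excluded) gives moment-based estimates of orientation, spatial
frequency and envelope scale; L-BFGS-B then refines all 8 parameters
of A·exp(−(x′/2σx)² − (y′/2σy)²)·cos(2πf x′ + φ) in the spatial
domain, multi-started over 4 initial phases. Exclusions: pixelwise
correlation < 0.7, center outside the 0-based pixel grid, or envelope
sd < 0.5 px. The fitted rotation/translation is applied to every time
slice (bilinear resampling with zero padding; `grid-constant` mode so
edge samples interpolate against the padding rather than snapping to
it) and summed along the new y-axis to give the 20 × 7 space-time RF;
the collapsed x-axis direction is defined modulo π. Separability is
the s₂/s₁ ratio of the 400 × 7 SVD, inseparable at ≥ 0.5. The tilt
direction index takes Rp as the 2D Fourier amplitude peak over the
positive temporal-frequency half-plane and Rq at the time-mirrored
point; near-equal peaks break toward lower frequency, and a peak on
the zero-temporal-frequency line defines TDI = 0 with a static flag.
Peak temporal frequency converts cycles/bin at 25 bins/s (40 ms
frames). Signed r² values are reported as sign(r)·r². Gabor fitting is
phase-symmetric, so no sign flip is applied to visual RFs.

## Synthetic data

The generators emulate the statistical structure the pipeline needs,
not the corpora themselves:

- **Movies** are sums of Gaussian textures with isotropic power-law
  amplitude spectra (default exponent −1, the natural-image slope),
  a configurable fraction replaced by hard luminance edges, each layer
  translating rigidly with circular wraparound. Wraparound keeps
  translation exactly testable and gives the movies genuine temporal
  predictability (consecutive-frame correlation strictly above
  shuffled-frame correlation).
- **Sounds** are harmonic stacks (amplitudes 1/h) with random
  fundamentals and raised-sinusoid amplitude envelopes, plus a
  low-passed noise floor.
- **Planted STRFs** are separable: a Gaussian spectral bump times a
  biphasic temporal kernel with a brief positive lobe near the present
  and a longer negative lobe further back, unit total power.
- **Simulated neurons** are linear in the planted STRF with Gaussian
  output noise (optional half-wave rectification); linear ground truth
  gives a clean recovery oracle for the linear STRF estimator.
- **RF populations** with controlled span distributions are built from
  plateau profiles whose above-half-max count equals the drawn span
  exactly, with excitatory and inhibitory time supports kept disjoint
  so sign-splitting recovers the planted subfields bin-for-bin.

What these generators do **not** capture: the higher-order statistics
of natural scenes (occlusion, scale mixing), vocal-tract structure in
sounds, and the corpus composition of real training sets. Tests that
pass on them certify the pipeline's mechanics and the emergence of
prediction-driven RF structure under controlled conditions, not
quantitative agreement with cortical data.

## Experiment scales and numerical choices

Desk-scale experiments (the test suite and `scripts/acceptance.py`)
use 12 × 12-pixel patches, 7 + 1 frames, ~20k clips and J = 64 hidden
units for the visual model, and 43 × 32 cochleagram clips with small
(J, λ) grids for the auditory model. λ = 2e-4 for the visual runs was
selected by validation prediction error — the model family's own
hyperparameter criterion — over a coarse λ grid at this scale. At
these sizes the emergent RFs reproduce the qualitative signatures
(recent-past power concentration, Gabor-like spatial structure, a mix
of separable and inseparable units); their quantitative distributions
depend on corpus scale and are not compared against neural data.

Numerical conventions worth knowing: degenerate inputs (all-zero RFs,
constant datasets, empty span samples) raise or return flagged
missing values rather than NaNs; the FISTA and coordinate-descent
tolerances are 1e-6 on relative objective change; child seeds for
pipeline stages are crc32 hashes of (master seed, stage name, index),
so grid cells are reproducible in isolation; HDF5 is the on-disk
format for datasets, parameters and bases, CSV for metric tables.

## Known limitations

- Purely feedforward, single-layer; no recurrent or multi-layer
  variants.
- The sparse-coding control runs at small dictionary sizes; corpus-scale
  overcomplete sweeps (thousands of units) are out of scope for tests.
- The visual frontend handles grayscale arrays only (no codec I/O).
- Vinje–Gallant sparsity requires nonnegative responses; tanh
  activities are rectified by absolute value, linear by half-wave,
  which is a convention rather than a measurement.
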