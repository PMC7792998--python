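# Methods

`cdinvert` inverts oversampled single-particle coherent X-ray diffraction
patterns into complex real-space images, combining a learned inverter with
classical iterative phase retrieval. This note documents the models, the
numerical choices, and what the desk-scale tests do and do not demonstrate.

## Forward model

A particle is a voxelized complex density rho(r) = s(r) exp(i phi(r)) on a
cubic grid of n^3 voxels (default n = 64), with the shape function s in
[0, 1] and the interior phase phi in [-pi, pi]. The measured intensity is
I(Q) = |F rho|^2 on the conjugate reciprocal grid, computed with the
unnormalized centered DFT (zero frequency at the array center, the detector
image convention); Parseval then reads sum(I)/n^3 = sum(|rho|^2).

A 2D detector that records only the central slice of the 3D intensity
measures, by the Fourier slice theorem, exactly the 2D diffraction of the
complex line-sum (projection) of the particle along the slice normal. The
identity central_slice(diffract_3d(rho)) == diffract_2d(project(rho)) is
exact for the DFT, holds to machine precision in the implementation, and is
the package's primary oracle: it also fixes the choice of ground truth for
the learned inverter — the 2D targets are complex projections, which are the
only images consistent with the recorded slice. Whether "ground truth" means
the projection or a central object slice is ambiguous in general; the
projection is the self-consistent reading and is used throughout.

Particles are confined to the central n/2 cube, so every pattern is
oversampled by at least a factor two per dimension — the condition under
which the 2D phase problem is generically uniquely solvable up to the
trivial ambiguities (translation, global phase, conjugate twin).

## Synthetic particles

The simulator emulates a corpus of strong-phase single particles:

* **Shape**: superellipsoids in the standard two-exponent implicit form
  ((|x/a|^(2/e) + |y/b|^(2/e))^(e/n) + |z/c|^(2/n)) <= 1. The printed
  source of the shape equation is ambiguous about exponent placement; this
  form is validated by its two exact limits, the ellipsoid at e = n = 1 and
  the octahedron at e = n = 2, both asserted voxel-for-voxel in tests.
  Semi-axes a, b, c are drawn uniformly from [4, n/4] voxels (the
  oversampling bound), roundedness exponents e, n from [0.5, 3].
* **Interior phase**: a Gaussian-correlated random field — white Gaussian
  noise convolved with the separable kernel exp(-x^2/L_x^2 - y^2/L_y^2 -
  z^2/L_z^2), correlation lengths drawn from [2, n/4] voxels. The
  convolution gives the field a Gaussian autocorrelation with 1/e
  half-width sqrt(2) L per axis; tests recover that constant numerically.
  The field is affinely rescaled per object so its values span the
  configured phase_span (default 2 pi, the strong-phase regime) centered on
  zero; the span attained inside a given particle is at most phase_span and
  approaches it as the particle grows. The normalization of the source
  field is not specified anywhere authoritative; per-object rescaling is
  our choice because it guarantees the strong-phase regime for every
  particle regardless of L.
* **Orientation**: uniform random rotations (Shoemake quaternion sampling),
  applied to amplitude and phase by identical trilinear resampling about
  the grid center (n-1)/2, which maps lattice rotations onto exact array
  quarter-turns. Trilinear resampling loses a few percent of |amplitude|^2
  (measured: < 10%, typically ~4%); it never overshoots the phase range.
* **Edge smoothing**: the binary mask is blurred with a Gaussian of sigma =
  1 voxel (amplitude only — the phase field is already smooth; whether the
  original filter touched the phase is unknown, and blurring a wrapped
  phase would be ill-defined at the boundary). Amplitude outside the
  central half-cube is zeroed so the oversampling bound holds exactly even
  for near-maximal shapes; shapes whose circumscribed sphere would leave
  the half-cube under rotation (possible for boxy exponents e, n < 1) are
  isotropically shrunk at sampling time, with the final semi-axes recorded
  in the provenance.

Training targets: the projection's modulus is renormalized to max 1; its
phase is mapped by the fixed affine map (phi + pi) / (2 pi) to (0, 1) and
set to 0 outside the projected support (pixels below 1e-3 of the peak
modulus). A fixed map rather than per-sample min-max scaling keeps phase
values comparable across samples. Targets are n/2 x n/2, half the pattern
size per dimension, keeping the inversion overdetermined.

What the generator does **not** emulate: photon statistics and detector
noise, partial coherence, Bragg-geometry distortion of the reciprocal grid
(patterns live on an object-aligned grid), and faceted crystal shapes beyond
the superellipsoid family. Passing tests therefore demonstrate correctness
of the machinery and the relative merits of the methods on clean,
in-distribution data — not robustness to experimental artefacts.

## Two-branch CNN inverter

A convolutional encoder-decoder: the encoder applies, per level, a 3x3
convolution block and a separable 3x1 + 1x3 block (each followed by a leaky
ReLU, slope 0.1, and batch normalization), then 2x2 max pooling, doubling
channels per level; after `depth` levels (default 3) a final convolution
block forms the bottleneck, whose channels are split equally between two
independent decoders (upsample 2x + the same two block types, halving
channels), one emitting the amplitude image and one the scaled phase. The
final convolution of each head is followed by a softplus, so amplitude and
scaled phase are always >= 0. A ReLU head is a trap here: one whose
pre-activation drifts uniformly negative is an absorbing state that
receives zero gradient forever, and such mid-training head collapses were
observed with some training seeds; softplus has strictly positive gradient
everywhere and removes the state entirely. (A leaky ReLU clipped at
inference is no fix either — the reciprocal loss term is invariant under
an amplitude sign flip absorbed into the phase, so training can park the
amplitude negative and the clip then destroys the image.) Input n x n,
outputs n/2 x n/2: the decoders upsample one level less than the encoder
pooled.

The network input is the per-pattern max-normalized modulus sqrt(I)/max —
the modulus is the physical quantity the forward model constrains, and
max normalization makes inference invariant to the overall intensity scale
(asserted in tests).

**Loss.** Three terms, weighted: a pixel-mean real-space error on the
amplitude head, the same on the scaled-phase head, and a reciprocal-space
consistency term — the
normalized quadratic misfit between the Fourier modulus of the predicted
complex image (amplitude times exp(i(2 pi p - pi)), zero-embedded to the
full frame) and the measured modulus, both L2-normalized. The term is zero
exactly when the prediction reproduces the data and penalizes any
support-violating artefact. The real-space norm defaults to the mean
squared error; mean absolute error is available (`real_norm="l1"`) but is a
poor default here because the targets are sparse — most amplitude pixels
are zero at any given location — so the L1-optimal output of a weakly
trained network is the near-zero per-pixel median, and in practice the
amplitude head shrank toward zero under L1 (its predicted maximum decayed
while the MAE "improved"). Defaults w_amp = w_phase = 1, w_recip = 1;
the weights were selected by validation performance at desk scale (the
reciprocal term conditions the modulus-domain error that all comparisons
use). All gradients, including the FFT-loss gradient, are analytic and are
verified against central finite differences in the test suite.

**Backend.** No deep-learning framework is used: layers, backward passes
and the Adam optimizer (lr 1e-3, default betas) operate directly on NumPy
arrays, channels-last, with convolutions evaluated as one BLAS matrix
product per kernel tap. Training is single-threaded CPU and exactly
deterministic given the seed. 95% of the corpus trains, 5% is held out; the
best-validation weights are kept.

## Iterative phase retrieval

Error reduction (ER) and hybrid input-output (HIO, feedback beta = 0.9)
with the per-iteration error chi^2 = sum((|F x| - m)^2) / sum(m^2) recorded
before each modulus projection. The default algorithm switch schedule is
20 ER then five cycles of (100 HIO + 20 ER), 620 iterations — standard CDI
practice; the exact published schedule is not legible in the source, so the
schedule is fully configurable. Shrink-wrap support refinement (Gaussian
blur of |iterate|, threshold at 0.1 of the blurred maximum, sigma annealed
from 3.0 by 0.95 per event to a floor of 1.0, every 30 iterations) is
available but off by default in the synthetic benchmarks, where each arm's
support is the quantity under study. No real-space positivity constraint is
applied: the objects are complex with strong phase, for which positivity is
simply wrong.

Initializations: random Fourier phase (uniform per pixel, seeded) applied
to the measured modulus; a rectangle support (the central n/2 square, the
generic oversampling support); a support binarized from the CNN amplitude
at 10% of its maximum; the CNN complex image itself; or the NNS match.

Numerical notes: the first iterate of a random-phase start satisfies the
modulus constraint exactly, so its recorded chi^2 is ~0 and ER monotonicity
is asserted from the second iterate on; "starting chi^2" in the benchmark
is likewise the error after the first full iteration. At the true solution
of a support-consistent instance both ER and HIO are exact fixed points.
On strong-phase instances the iterations routinely reach modulus chi^2 ~
1e-4 while retaining ~20% complex real-space error concentrated at high
spatial frequencies — the chi^2 metric is dominated by the intense central
speckles. This stagnation is the behaviour that motivates seeding the
iterations from the learned prediction.

## Baselines and metrics

* **chi^2**: sum((calc - meas)^2) / sum(meas^2) on moduli and on real-space
  images; scale-invariant under common rescaling of both arguments. For
  CNN outputs, moduli are compared after matching L2 norms (the network
  predicts in normalized units). CNN outputs live in the fixed centered
  training frame and are compared without alignment; iterative
  reconstructions are first aligned.
* **Alignment**: the trivial ambiguities — integer cyclic translation
  (exact FFT cross-correlation), global phase, conjugate twin, and the
  modulus-preserving sub-pixel translation (local simplex refinement of
  the cross-correlation peak) — are removed before real-space comparison.
* **NNS**: brute-force lookup of the query against all training moduli
  (max-normalized, same chi^2), returning the matched ground truth as a
  candidate initialization. No dimensionality reduction or indexing; the
  measured lookup error decreases monotonically with library size.
* **Gamma fits**: error histograms are summarized by maximum-likelihood
  Gamma fits (location fixed at 0); the reported mean is shape x scale.
* **Phase unwrapping**: reliability-ordered region-growing 2D unwrapping
  (scikit-image implementation) on masked domains, used for presentation
  of phase images; the output differs from the input by exact multiples of
  2 pi inside the mask.

## Desk-scale study sizes

Full-scale training in the original setting (150,000 patterns, order a day
of GPU time) is out of scope; the package's own study sizes are chosen so
every suite runs on one CPU in minutes:

* unit/property tests: 32^3 grids, corpora of tens of samples;
* the learned-inversion study (tests and the acceptance script): 64^3
  grid, 700–900 patterns, base 12 channels, depth 3, 14–16 epochs,
  batch 32.

At these sizes the absolute errors are far from the full-scale figures
(e.g. modulus chi^2 of a few 1e-2 rather than ~0.019), but the qualitative
findings replicate: the CNN typically inverts held-out patterns better
than a nearest-neighbour lookup over the same corpus; the phase error
exceeds the amplitude error; the CNN seed starts the iterations one to two
orders of magnitude below a random-phase start; and CNN-seeded refinement
ends far below the CNN alone. On these noiseless, exactly
support-consistent instances a random start inside the generous generic
box support can itself converge to very low chi^2, and any imperfection in
the CNN-derived support caps the floor the learned-support arms reach — so
the seed's value at desk scale is the low, reliable start rather than the
ultimate floor. One caveat is seed-to-seed training variance: at this small epoch
budget an unlucky optimization trajectory can leave the CNN's mean modulus
error near — occasionally slightly above — the NNS level (e.g. 0.066 vs
0.052 on one corpus/seed combination), where a healthy run lands well
below it (0.036 vs 0.045). The orderings involving the hybrid benchmark
arms are insensitive to this.

## Known limitations

* 2D only; the 3D machinery exists solely to generate central slices.
* No noise model: conclusions about method ordering under Poisson noise or
  partial coherence require extending the simulator.
* The NumPy training backend is practical up to ~10^3–10^4 samples at 64^2;
  the architecture is framework-agnostic and scales past that only with a
  GPU backend.
* Real-space agreement of classical retrieval on strong-phase objects is
  limited by stagnation (see above); reported chi^2 values are modulus-
  domain unless stated otherwise.
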