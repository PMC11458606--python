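# Methods

## Problem and model

The pipeline classifies 2-D grayscale vessel cross-section images into
high- and low-risk coronary artery disease (CAD) categories.  A case is
high-risk iff at least one of four criteria holds: stenosis fraction
≥ 0.70 (inclusive boundary), two or more diseased vessels, positive
remodeling together with at least one spotty calcification, or a history
of myocardial infarction / recurrent angina (collapsed into a single
`prior_mi` flag, since symptom history and infarction are listed
together as one criterion).  Low risk is the negation — no separate
operationalization of the low-risk class exists, so the complement is
used.

The classifier itself never sees these tabular features.  Images are
preprocessed in the frequency domain, an adversarial generator/
discriminator pair is trained on them, intermediate discriminator
activations become feature vectors, and a naive Bayes model over those
features produces the posterior and the posterior-odds risk score
`S = P(high|x) / P(low|x)`.

## Synthetic phantoms

Real CCTA data are not available, so the `phantom` module generates the
study cohort.  Each image contains one vessel: an annulus (wall) of
configurable outer radius, a lumen disk at 0.65 of that radius, and a
plaque rendered as a circular segment of the lumen eccentric in a random
direction.  The chord offset of the segment is found by bisection
directly on the pixel-counted occluded fraction (48 iterations over a
bracket that includes the 0% and 100% ends), so the measured stenosis
matches the requested one to within pixel quantization — the generator
contract is agreement within 0.05, and at the default 32 px / radius 12
geometry the typical error is below 0.02.  Spotty calcifications are
3×3-clipped bright speckles at uniformly chosen plaque pixels.  Positive
remodeling adds a 15% outward bulge of the wall on the plaque side.

Default tissue intensities (background 0.10, wall 0.55, lumen 0.85,
plaque 0.40, calcification 0.95) were chosen for separability of the five
classes and are configurable.  Gaussian pixel noise (default sd 0.02) is
added to the image only; masks are noise-free, so mask areas are exactly
invariant to the noise level.

Cohorts are built label-first: `generate_cohort(n, class_mix)` draws
exactly `round(n·class_mix)` high-risk specs.  High-risk cases are
stenosis-driven — stenosis uniform on (0.75, 0.92), optionally with
additional qualifying findings (multivessel disease, remodeling plus
calcification, prior infarction) that do not change the label; low-risk
cases draw stenosis uniform on (0.05, 0.62) with no other criterion
firing.  The margins around the 0.70 threshold guarantee that the label
recomputed from *measured* features equals the intended one, so class
balance is exact by construction.  What the phantoms do **not** emulate:
CT acquisition physics (beam hardening, motion), anatomical context
around the vessel, 3-D structure, or multiple rendered vessels
(multivessel disease is a tabular feature only).  Passing the end-to-end
benchmark therefore demonstrates that the pipeline machinery works and
that discriminator features carry stenosis information — not clinical
performance on real CCTA.

## Fourier preprocessing

The forward transform is the unnormalized double sum (exactly
`numpy.fft.fft2`); spectra carry an explicit `shifted` flag so the
shift/filter/unshift bookkeeping cannot be misapplied.  Filters are ideal
{0,1} radial indicators on the centered grid with radius measured from
`(⌊M/2⌋, ⌊N/2⌋)` and **inclusive** cutoff boundaries; a Gaussian-rolloff
variant (edge width 1 px) is available for ringing-sensitive use.  The
band-pass condition is two-sided, `D1 ≤ r ≤ D2`; the default chain uses a
band filter with `(D1, D2) = (2, image_size/4)`, a choice the user can
override since no canonical downstream filter is prescribed.  After the
inverse transform the real part is taken; because radially symmetric real
masks preserve conjugate symmetry of a real image's spectrum, the
imaginary residual is numerical noise, and a residual above 1e-8 of the
signal raises.  Min–max normalization maps to [0, 255]; a constant image
maps to all zeros with a warning (degenerate-range convention).

## Adversarial model

No autodiff framework is used: `ganb.nn` implements dense, strided
convolution (im2col), transposed convolution (the conv adjoint via
col2im), leaky-ReLU/ReLU/sigmoid layers and SGD/Adam with analytic
backprop, verified against central finite differences in the tests.  The
generator is latent-32 → dense 128 → dense → reshape → two stride-2
transposed-conv blocks → sigmoid image; the discriminator is two stride-2
conv blocks → dense 64 → dense 1 → sigmoid, structured as K = 4
addressable blocks.  Sigmoid outputs are clipped to
[1e-7, 1 − 1e-7] so probabilities are strictly inside (0, 1) and the
loss gradients stay finite.

The losses are the standard binary cross-entropy pair (both terms of
`L_D` negative — the objective is minimized for both networks, with the
discriminator maximizing the minimax value through its own loss).
Updates are descent steps; one discriminator step then one generator step
per mini-batch.  The default optimizer is plain SGD, matching the stated
update rules; Adam is available and is the pipeline default
(lr 2e-3) because it converges faster at small batch counts.  Training is
bit-reproducible for a fixed seed under single-threaded numpy.

## Features and naive Bayes

`extract_features` runs discriminator blocks 1..i and flattens; the
default i = K−1 (penultimate, 64-d) since the last block is a single
saturating probability.  Spatial maps wider than 512 values are
global-average-pooled first to keep naive-Bayes estimates
well-conditioned.  Synthetic augmentation draws per-class generators
(one GAN per class), pushes their samples through the same discriminator
prefix, and labels rows by the generating class; an unconditional GAN
yields unlabeled samples unusable for supervised fitting, so augmentation
simply requires the class-conditional mode.

The classifier supports Gaussian likelihoods (per-class feature means and
variances, floor `1e-9·(global variance + 1e-12)`) and multinomial counts
with pseudo-count smoothing.  Two smoothing denominators are exposed:
`standard` Lidstone `(count+α)/(total+αV)`, which normalizes over the
V-item vocabulary, and `unnormalized` `(count+α)/(total+α)`, whose
per-class conditionals sum to `(total+Vα)/(total+α)` — kept for
comparison, asserted in the tests, never the default.  All arithmetic is
in log space with log-sum-exp normalization; classification ties break to
the earlier class in declared order (high before low for binary models);
odds below machine range report an `inf` sentinel.  Continuous features
can be discretized per-feature (quantile or uniform bins, edges fitted on
training data, out-of-range values clamped to the end bins, constant
features falling back from quantile to uniform with a warning).

## Metrics and baseline segmenter

Dice and IoU binarize one class at a time; empty-vs-empty pairs score 1.0
(agreement on absence) and empty-vs-nonempty 0.0, both logged.  mIoU
averages only the classes present in the reference mask (absent classes
would be 0/0).  ROC sweeps unique scores with tied scores sharing a
threshold; AUC is trapezoidal and equals the concordant-pair fraction for
ties-free inputs.  Aggregate rows are unweighted means rounded half-up to
2 decimals — rounding applies only in the aggregate report, never to
stored values.

The pipeline's segmentation metrics are exercised by `threshold_segment`,
a deliberately simple baseline: one Otsu cut separates vessel from
background, a second cut inside the foreground isolates the brightest
(contrast-filled) tissue, and the largest bright connected component is
reported as the lumen.  An adversarially *learned* segmenter is out of
scope: the adversarial model here synthesizes images from noise and has
no mechanism producing masks, so segmentation quality is measured against
the phantom ground truth with this intensity baseline instead, and that
gap is deliberate.

## Pipeline, determinism, problem sizes

The train/test split is stratified by label at the patient level (default
0.7/0.3) before any adversarial training, so no test image influences the
discriminator features.  Every stage draws from its own
`numpy.random.Generator` seeded by `stage_seed(global_seed, stage_name)`
(a CRC32-based derivation), making full runs reproducible byte-for-byte.

Default study conditions: 200 phantoms at 32×32, balanced classes,
150 training epochs with batch 32.  These sizes keep a full pipeline run
under a minute on a single CPU core while leaving the benchmark
non-trivial; the acceptance script additionally runs a 300-epoch
degenerate-target training (64 constant-0.7 images) whose generated mean
pixel intensity lands near 0.7, a moment-matching sanity check of the
adversarial dynamics.

## Known limitations

- The phantoms are intensity-separable by design; real CCTA features
  would not yield near-perfect held-out accuracy.
- Batch normalization is not implemented; at these network sizes it is
  unnecessary and omitting it keeps training strictly deterministic.
- The multinomial family treats integer feature codes as counts; this is
  the conventional bag-of-counts reading and is documented rather than
  enforced semantically.
- No GPU path, no Wasserstein/spectral-norm variants, no image-quality
  scores (FID), no survival analysis.
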