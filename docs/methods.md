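# Methods

This note documents the models, estimators, parameter choices, and synthetic
study conditions behind `freqlens`, and states what the desk-scale results do
and do not establish.

## Spectral statistics

All spectra are squared magnitudes of the unnormalized 2-D DFT, fftshifted so
the DC bin sits at `(H//2, W//2)`. Power (not amplitude) is used because the
downstream statistics are defined on power fractions; an amplitude option
exists. Multichannel images contribute the average of their per-channel
spectra — the analyses never treat color channels separately, matching how
RGB perturbation spectra are normally reported.

Two frequency normalizations are carried explicitly and never converted
silently: **sampling** units (cycles/pixel, axes in [−0.5, 0.5)) are used for
perturbation spectra, **Nyquist** units (axes in [−1, 1)) for hybrid mixing
frequencies. Bin-for-bin the Nyquist radii are exactly twice the sampling
radii, so `f_0.5` in one convention is exactly twice the other.

The radial profile accumulates power over distinct grid radii (grouped after
rounding to 12 decimals to absorb float noise), DC included at `r = 0`
because adversarial perturbations may carry mean offsets. `f_0.5` is the
smallest distinct radius at which the cumulative fraction reaches one half —
the median of the power-weighted radius distribution. This quantile ("step")
convention is the default because it returns exact answers on degenerate
spectra (a pure tone at radius `r` gives `f_0.5 = r`; a flat spectrum gives
the median grid radius); linear interpolation between adjacent distinct radii
is available as an option. The spread reported by `half_power_frequency` is
the standard deviation of per-image `f_0.5` values.

## Hybrid probe

Hybrids are built per channel in the frequency domain with a binary radial
mask at `f_mix` (Nyquist units) and are **not** clipped to [0, 1]: clipping
would break the exact spectral-split property (the hybrid's in-mask power
equals the low seed's, out-mask the high seed's — a Parseval identity the
tests verify), and linearity is what makes the probe interpretable. Clipping
is applied only on PNG export.

`p_low` / `p_high` are top-1 indicator frequencies (fraction of hybrids
classified as the corresponding seed class), with argmax ties resolved to the
lowest class id; mean softmax mass is available as an option. The same pair
list is reused at every `f_mix`, making the curve a paired comparison and
reducing variance without changing the estimand. `f_rev` is the first
crossing of `d = p_low − p_high` from ≤ 0 to > 0, linearly interpolated
between the bracketing grid points; a curve that never crosses returns NaN
with a censoring flag rather than a fabricated value. The default grid is 17
evenly spaced values on [0, √2]. Uncertainty comes from re-drawing the pair
list (`probe_experiment`), not from resampling a fixed curve.

## Defenses

The blur layer is a fixed convolution with a unit-sum isotropic Gaussian,
truncated at radius ⌈3σ⌉ (≥ 99.7% of the mass; no truncation rule is
canonical, this one is conventional). Reflect padding avoids dark-frame
artifacts that would themselves be a low-frequency cue. Default σ = 1.5 px,
the value at which a 32×32 classifier behind the blur retains clean accuracy
around 90% on natural-image benchmarks. For gradient purposes the operator is
materialized once per image shape as a dense matrix, so the adjoint used in
composed gradients is the exact transpose — reflect-padded convolution is not
self-adjoint at borders, and finite-difference checks would fail otherwise.

The PCA layer projects the flattened (channel-interleaved) image onto the
span of the top-K principal components of a training set, with the mean
subtracted before and re-added after projection, making K = N the exact
identity. Written as a filtering matrix, the layer's weights are the N×N
orthogonal projector `V_Kᵀ V_K`; K = 512 is the default retention for 32×32
RGB (N = 3072). Components are sign-fixed (largest-magnitude entry positive)
for reproducibility. Both layers are linear, so composed models expose exact
chain-rule input gradients and remain attackable — no gradient masking.

## Minimal-perturbation search

The per-image statistic is the smallest targeted L∞ perturbation over a pool
of attack-engine candidates. The built-in engine is targeted PGD: step size
2.5·ε/steps, uniform random start in the ε-ball, projection onto ball ∩
[0, 1] each step. An outer bisection on ε (bracket [0, 0.5], tolerance
0.5/255) localizes the smallest successful budget; each successful candidate
is then refined by a binary search on the perturbation *scale* (shrinking
toward the original while the target class holds — valid because [0, 1] is
convex), which removes the bisection-tolerance floor from the reported
`ε_min`. Engines are pluggable callables so external attack libraries can be
pooled; pooling can only shrink the result. Defaults are 100 steps and 5
restarts (config-exposed); the test suite and acceptance script use 25–50
steps and 1–2 restarts, which the linear-oracle comparison shows is already
within 2% of the exact margin at these problem sizes. Censored attacks
(no success at ε = 0.5) count as failures at every budget in success-rate
curves; dropping them would bias ε₅₀ downward. ε is stored in [0, 1] units
and reported ×255.

A batched variant runs the bisection synchronously across images (each with
its own bracket) so every PGD step is one vectorized forward/backward pass;
it is equivalent to the per-image search with the built-in engine and is what
the directional experiments use.

## Corruption suite

Thirteen procedural corruption families with documented five-level severity
tables (see `SEVERITY_PARAMS`), deterministic given the spec seed. The three
weather families carry a `_like` suffix: they are parameterized low-frequency
overlays (smoothed-noise fields), not reproductions of asset-based textures;
their defining property — a low-frequency difference spectrum — is verified
by test, not assumed. Two canonical mid-band blur families (zoom, glass) are
omitted as redundant mid-group members; the analyses depend only on the
grouping and severity ordering, which are preserved. The low/mid/high
grouping is hard-coded (noise families high; blur/digital mid;
weather/brightness/contrast low) and independently checked by computing
difference-image spectra on 1/f synthetic images: the group-mean `f_0.5`
ordering high > mid > low holds across seeds.

## Synthetic study conditions

The band dataset generator is the package's stand-in for natural image
datasets. Each class template is a sum of bin-aligned sinusoid atoms (exact
DFT bins, no spectral leakage), placed stratified across the class band so
every template covers its declared range; samples are randomly translated
(circularly) copies plus noise, affinely rescaled to [0, 1].

Two parameters emulate the natural-image statistics that frequency-bias
phenomena depend on, and their defaults define the study conditions:

* **amplitude slope 1.0** — atom amplitudes fall as 1/f, the canonical
  natural amplitude spectrum. High-frequency class content is therefore
  *weak but present*.
* **noise exponent 1.5** — intra-class variability is pink (1/f^1.5
  amplitude), concentrated at low frequencies, as lighting/pose/background
  variation is in photographs. High-frequency content is therefore *clean*.

Under these conditions (4 classes, 32×32, 10 atoms per class on a shared
full-range band, noise σ = 0.2) an unconstrained classifier prefers the many
clean-but-weak high-frequency cues — each cheap to flip under an L∞
adversary — while a blur-composed classifier is forced onto the strong,
noisy low-frequency cues. This is the regime in which the package's
directional results reproduce the full-scale phenomena: the blur model
requires larger minimal perturbations, its perturbation spectra and `f_rev`
shift to lower frequencies, and it resists high-frequency corruptions better.
With equal-amplitude atoms in white noise (both parameters 0) the task is so
easy that both models sit far from their decision boundaries and the
robustness ordering can even invert; passing the directional tests under the
default conditions therefore shows that the *mechanism* behaves as in natural
data when natural spectral structure is present — it does not show that any
synthetic dataset whatsoever exhibits it, nor does it reproduce the absolute
full-scale numbers (those require CIFAR-scale models and data).

The band-template oracle scores classes by the maximum circular
cross-correlation between the mean-centered input and unit-norm ideally
low-passed class templates (softmax over scores, β = 10; β does not affect
top-1 behavior). The shift maximum makes it invariant to the generator's
random translations; the gradient is the shifted filter at the argmax
(exact almost everywhere). Its response to any hybrid image is computable
directly from the seed spectra by frequency-domain bookkeeping, which is the
independent oracle the probe pipeline is validated against (agreement to
float precision; tolerance 0.05 in the tests).

The tiny CNN (two 5×5 conv blocks, ~7k parameters, Adam, seeded and
bit-reproducible) is the desk-scale stand-in for full-size networks; training
falls back to a warning flag rather than failing silently if train accuracy
stays below 80%.

Synthetic V1 responses are inner products with random Gabor filters whose
carrier frequencies lie in a declared band (default (0.05, 0.25) Nyquist,
mimicking the low-frequency receptive-field structure of mouse V1
populations), plus Gaussian noise. Filters are projected onto the ideal
low-pass band after construction so the planted structure is exactly
band-limited — discrete Gabors otherwise leak ~10% of their power outside
the band, which would contaminate recovery bounds.

## Representational geometry

Similarity is row-wise cosine; eigendecomposition uses a symmetric solver
with descending eigenvalues and a deterministic sign convention. The linear
receptive-field map of a component is the ridge regression of its
per-stimulus scores onto pixels; the default penalty is `1e-3 ×
trace(X Xᵀ)` (the raw stimulus Gram matrix). This strength matters: with
more pixels than stimuli, weaker penalties let least squares place spurious
coefficients on low-variance high-frequency pixel directions while barely
improving score prediction (r² stays ≥ 0.93 at the default), and those
spurious coefficients would mask the low-frequency structure the analysis is
meant to reveal. The leading eigenvector of a cosine-similarity matrix of
broadly positive responses is a near-uniform "norm" component with no
spatial tuning; recovery analyses read the structured components that follow
it.

## Numerical choices and degenerate inputs

* All-zero spectra, single-class hybrid datasets, zero response rows,
  non-finite pixels, out-of-range severities and unknown corruption names
  raise errors rather than producing numbers.
* Hybrid inverse transforms assert an imaginary residue below 1e-8 before
  discarding it.
* Radii are grouped after rounding to 12 decimals; argmax ties resolve to the
  lowest class id (recorded behavior, not an accident of sort order).
* Every generator and training routine is a pure function of its seed;
  the acceptance script derives all seeds from its `--seed` argument.

## Problem sizes

The shipped experiments use 4-class 32×32 datasets (300–500 images/class),
100-image attack sets (25–50 PGD steps, 1–2 restarts), 150–200 probe pairs ×
17 mixing frequencies × 2 permutations, 15 reference images for corruption
spectra, and 120 stimuli × 30 neurons for receptive-field recovery. These
sizes were chosen so the full pipeline — training included — runs in minutes
on a single CPU while leaving every statistic's sampling error well inside
the margins the tests assert.

## Known limitations

* Absolute values of `f_rev`, `f_0.5` and ε are specific to the synthetic
  conditions and the tiny CNN; only directions and invariants transfer.
* The corruption families are procedural re-creations, not pixel-exact
  benchmark reproductions; severity tables are this package's own.
* The attack pool ships with a single engine (PGD + bisection + shrink);
  decision-based engines can be plugged in but are not included.
* The blur operator's dense-matrix adjoint is exact but memory-bound; it is
  intended for inputs up to roughly 64×64, which covers the desk scale.
* Stochastic defenses (and expectation-over-transformation attacks on them)
  are out of scope; all models here are deterministic.
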