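"""Synthetic inputs with analytically known frequency structure.

Natural image datasets carry class-discriminative content at uncontrolled
spatial frequencies, so nothing about a probe's ground truth can be derived
from them. The generators here replace them with inputs whose frequency
content is controlled by construction:

* band-structured image classes (each class template lives in a declared
  radial frequency band, built from bin-aligned sinusoid atoms so there is
  no spectral leakage);
* an analytic band-limited template-matching classifier whose behavior on
  hybrid images can be predicted exactly by frequency-domain bookkeeping;
* tiny trainable CNNs as desk-scale stand-ins for full-size networks;
* 1/f "naturalistic" noise images for corruption-spectrum analyses;
* stimulus x neuron response matrices generated by planted low-frequency
  linear receptive fields (a synthetic stand-in for V1 population data,
  which is not redistributable).

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .hybrid import lowpass_mask
from .models import ClassifierHandle, LinearSoftmaxClassifier, softmax
from .nn import TinyCNN
from .repgeom import NeuralResponseSet

__all__ = [
    "BandDatasetSpec",
    "BandDataset",
    "make_band_dataset",
    "make_pink_noise_images",
    "BandOracleClassifier",
    "make_oracle_classifier",
    "predicted_probe_curve",
    "train_tiny_cnn",
    "make_synthetic_v1",
    "make_random_linear_model",
    "rgb_to_gray",
]

GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


def rgb_to_gray(images: np.ndarray) -> np.ndarray:
    """Luminance conversion with fixed weights; no-op on grayscale input."""
    images = np.asarray(images, dtype=float)
    if images.shape[-1] != 3:
        return images
    return images @ GRAY_WEIGHTS


@dataclass(frozen=True)
class BandDatasetSpec:
    """Recipe for a band-structured multi-class image dataset.

    ``class_bands`` gives each class a radial frequency interval
    ``(f_lo, f_hi)`` in Nyquist units; the class template is a sum of
    ``template_components`` random sinusoid atoms whose frequencies are DFT
    bins inside that interval (one atom per equal sub-band). Samples are
    randomly translated copies of the template plus noise, affinely rescaled
    to [0, 1].

    Two parameters emulate natural-image statistics, which the frequency-bias
    phenomena depend on: ``amplitude_slope`` makes atom amplitudes fall as
    ``f^-slope`` (the canonical 1/f amplitude spectrum, so high-frequency
    class content is weak but clean), and ``noise_exponent`` shapes the
    additive noise as pink ``1/f`` noise (intra-class variability lives at
    low frequencies, as lighting/pose variation does in photographs). Setting
    both to 0 recovers equal-amplitude atoms in white noise.

    Defaults are the desk-scale study conditions used throughout the package:
    four 32x32 grayscale classes sharing a full-range band, so classes share
    the naturalistic spectral envelope and differ in *which* frequency atoms
    they contain — one strong low-frequency atom degraded by the pink noise,
    and many clean weak high-frequency atoms. 500 images per class.
    """

    n_classes: int = 4
    images_per_class: int = 500
    size: tuple[int, int] = (32, 32)
    channels: int = 1
    class_bands: tuple[tuple[float, float], ...] = (
        (0.05, 1.0),
        (0.05, 1.0),
        (0.05, 1.0),
        (0.05, 1.0),
    )
    template_components: int = 10
    noise_std: float = 0.2
    amplitude_slope: float = 1.0
    noise_exponent: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if len(self.class_bands) != self.n_classes:
            raise ValueError("need one (f_lo, f_hi) band per class")
        for lo, hi in self.class_bands:
            if not 0 <= lo < hi <= np.sqrt(2) + 1e-12:
                raise ValueError(f"invalid band ({lo}, {hi})")


class BandDataset(NamedTuple):
    images: np.ndarray  # (n, H, W) or (n, H, W, 3), values in [0, 1]
    labels: np.ndarray  # (n,)
    templates: np.ndarray  # (n_classes, H, W), zero-mean class templates
    spec: BandDatasetSpec


def _band_bins(H: int, W: int, f_lo: float, f_hi: float) -> np.ndarray:
    """Non-DC DFT bins (ky, kx) whose Nyquist-mode radius lies in (f_lo, f_hi]."""
    fy = np.fft.fftfreq(H) * 2
    fx = np.fft.fftfreq(W) * 2
    r = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    ky, kx = np.nonzero((r > f_lo) & (r <= f_hi))
    keep = ~((ky == 0) & (kx == 0))
    return np.stack([ky[keep], kx[keep]], axis=1)


def make_band_dataset(spec: BandDatasetSpec) -> BandDataset:
    """Generate a labeled band-structured dataset (balanced, reproducible).

    Atoms are bin-aligned cosines, so each class template's spectral power
    lies entirely inside its band; translations are circular rolls, which
    change phases only. Per-image affine rescaling maps samples to [0, 1].
    """
    H, W = spec.size
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    templates = np.zeros((spec.n_classes, H, W))
    for k, (f_lo, f_hi) in enumerate(spec.class_bands):
        if len(_band_bins(H, W, f_lo, f_hi)) == 0:
            raise ValueError(f"class {k}: band ({f_lo}, {f_hi}) contains no DFT bins")
        # Stratified atom placement: one atom per equal sub-band, so every
        # template covers its full declared band rather than clumping.
        edges = np.linspace(f_lo, f_hi, spec.template_components + 1)
        chosen = []
        for a in range(spec.template_components):
            sub = _band_bins(H, W, edges[a], edges[a + 1])
            if len(sub) == 0:
                sub = _band_bins(H, W, f_lo, f_hi)
            chosen.append(sub[rng.integers(len(sub))])
        for ky, kx in chosen:
            phase = rng.uniform(0, 2 * np.pi)
            r = np.hypot(np.fft.fftfreq(H)[ky] * 2, np.fft.fftfreq(W)[kx] * 2)
            amp = r ** (-spec.amplitude_slope)
            templates[k] += amp * np.cos(2 * np.pi * (ky * yy / H + kx * xx / W) + phase)
        templates[k] -= templates[k].mean()
        templates[k] /= np.sqrt((templates[k] ** 2).mean()) + 1e-12

    # Shared power-law noise shaping filter (amplitude ~ f^-noise_exponent).
    fy = np.fft.fftfreq(H)
    fx = np.fft.fftfreq(W)
    rr = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    noise_amp = np.zeros_like(rr)
    noise_amp[rr > 0] = rr[rr > 0] ** (-spec.noise_exponent)

    def shaped_noise() -> np.ndarray:
        white = np.fft.fft2(rng.standard_normal((H, W)))
        n = np.fft.ifft2(white * noise_amp).real
        return n / (n.std() + 1e-12)

    images, labels = [], []
    for k in range(spec.n_classes):
        for _ in range(spec.images_per_class):
            dy, dx = rng.integers(H), rng.integers(W)
            sample = np.roll(templates[k], (dy, dx), axis=(0, 1))
            sample = sample + spec.noise_std * shaped_noise()
            lo, hi = sample.min(), sample.max()
            sample = (sample - lo) / (hi - lo + 1e-12)
            if spec.channels == 3:
                sample = np.repeat(sample[:, :, None], 3, axis=2)
            images.append(sample)
            labels.append(k)
    order = rng.permutation(len(images))
    return BandDataset(
        np.stack(images)[order], np.array(labels)[order], templates, spec
    )


def make_pink_noise_images(
    n: int, size: tuple[int, int] = (32, 32), alpha: float = 2.0, seed: int = 0
) -> np.ndarray:
    """Random-phase 1/f^alpha power-law images rescaled to [0, 1].

    ``alpha = 2`` matches the canonical natural-image power spectrum slope.
    """
    H, W = size
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(H)
    fx = np.fft.fftfreq(W)
    r = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    amp = np.zeros_like(r)
    amp[r > 0] = r[r > 0] ** (-alpha / 2.0)
    out = []
    for _ in range(n):
        white = np.fft.fft2(rng.standard_normal((H, W)))
        img = np.fft.ifft2(white * amp).real
        lo, hi = img.min(), img.max()
        out.append((img - lo) / (hi - lo + 1e-12))
    return np.stack(out)


class BandOracleClassifier(ClassifierHandle):
    """Translation-invariant matched filter on ideally low-passed inputs.

    Class scores are the maximum circular cross-correlation between the
    (mean-centered) input and unit-norm low-passed class templates
    ``q_k = L_c (t_k - mean) / ||.||`` with ``L_c`` the ideal radial low-pass
    at ``cutoff`` (Nyquist units); probabilities are a softmax of the scores.
    The maximum over shifts makes the oracle insensitive to the random
    translations the generator applies, while every score remains a plain
    inner product at the best shift — so the oracle's behavior on any hybrid
    image is predictable by frequency-domain bookkeeping alone
    (:func:`predicted_probe_curve`) and its input gradient is the shifted
    filter itself (exact almost everywhere).
    """

    def __init__(self, templates: np.ndarray, cutoff: float, beta: float = 10.0):
        templates = np.asarray(templates, dtype=float)
        k, H, W = templates.shape
        mask = np.fft.ifftshift(lowpass_mask(H, W, cutoff).values)
        filters = []
        for t in templates:
            t = t - t.mean()
            q = np.fft.ifft2(np.fft.fft2(t) * mask).real
            norm = np.linalg.norm(q)
            if norm < 1e-10:
                raise ValueError("template has no power below the cutoff")
            filters.append(q / norm)
        self.filters = np.stack(filters)
        for i in range(k):
            for j in range(i + 1, k):
                if np.abs(self.filters[i] - self.filters[j]).max() < 1e-10:
                    raise ValueError(f"templates {i} and {j} are degenerate (identical)")
        self.templates = templates
        self.cutoff = float(cutoff)
        self.beta = float(beta)
        self.n_classes = k
        self.input_shape = (H, W)
        # Conjugate filter spectra for cross-correlation via FFT.
        self._fconj = np.conj(np.fft.fft2(self.filters))

    def _corr_maps(self, images: np.ndarray) -> np.ndarray:
        x = self._check_batch(images)
        x = x - x.mean(axis=(1, 2), keepdims=True)
        X = np.fft.fft2(x)
        # (B, k, H, W) correlation maps
        return np.fft.ifft2(X[:, None] * self._fconj[None]).real

    def scores(self, images: np.ndarray) -> np.ndarray:
        return self._corr_maps(images).max(axis=(2, 3))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return softmax(self.beta * self.scores(images))

    def loss_gradient(self, images: np.ndarray, targets: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        targets = np.atleast_1d(np.asarray(targets, dtype=int))
        maps = self._corr_maps(images)
        B, k, H, W = maps.shape
        probs = softmax(self.beta * maps.max(axis=(2, 3)))
        probs[np.arange(B), targets] -= 1.0
        grad = np.zeros((B, H, W))
        flat = maps.reshape(B, k, -1)
        for b in range(B):
            for c in range(k):
                dy, dx = np.unravel_index(int(flat[b, c].argmax()), (H, W))
                # d max-corr / dx = filter rolled to the argmax shift
                grad[b] += probs[b, c] * self.beta * np.roll(self.filters[c], (dy, dx), axis=(0, 1))
        return grad.reshape(images.shape)


def make_oracle_classifier(
    gallery: np.ndarray, cutoff: float, beta: float = 10.0
) -> BandOracleClassifier:
    """Band-limited template-matching oracle over a gallery of class templates."""
    return BandOracleClassifier(gallery, cutoff, beta=beta)


def predicted_probe_curve(
    oracle: BandOracleClassifier,
    images: Sequence[np.ndarray],
    labels: Sequence[int],
    pairs: Sequence[tuple[int, int]],
    f_mix_grid: Sequence[float],
):
    """Analytic p_low - p_high curve for the oracle, without building hybrids.

    For each pair the hybrid's spectrum is ``A`` below ``f_mix`` and ``B``
    above, so every class correlation map is an inverse transform of masked
    seed spectra — evaluated here directly in the frequency domain, never
    constructing a hybrid image or calling the classifier. This is the
    brute-force bookkeeping oracle used to validate the probe pipeline.
    """
    from .spectral import frequency_grid

    labels = np.asarray(labels)
    H, W = oracle.templates.shape[1:]
    radius = np.fft.ifftshift(frequency_grid(H, W, "nyquist").radius)
    Qc = np.conj(np.fft.fft2(oracle.filters))
    d_curve = np.zeros(len(f_mix_grid))
    for gi, f_mix in enumerate(f_mix_grid):
        in_mask = radius <= f_mix
        n_low = n_high = 0
        for lo, hi in pairs:
            A = np.fft.fft2(np.asarray(images[lo], dtype=float))
            B = np.fft.fft2(np.asarray(images[hi], dtype=float))
            X = np.where(in_mask, A, B)
            X[0, 0] = 0.0  # mean-centering of the hybrid
            scores = np.fft.ifft2(X[None] * Qc).real.max(axis=(1, 2))
            pred = int(np.argmax(scores))
            n_low += pred == labels[lo]
            n_high += pred == labels[hi]
        d_curve[gi] = (n_low - n_high) / len(pairs)
    return np.asarray(f_mix_grid, dtype=float), d_curve


def train_tiny_cnn(
    dataset: BandDataset,
    epochs: int = 10,
    seed: int = 0,
    preprocess=None,
    lr: float = 3e-3,
) -> ClassifierHandle:
    """Train the desk-scale CNN on a band dataset, optionally behind a defense.

    With ``preprocess`` given, the network is trained on preprocessed images
    and the composed handle (defense + network) is returned, mirroring how a
    fixed preprocessing layer is attached in front of a full-size model.
    """
    images, labels = dataset.images, dataset.labels
    n_classes = int(labels.max()) + 1
    if n_classes < 2:
        raise ValueError("need at least two classes")
    x = images
    if preprocess is not None:
        x = preprocess.apply(images)
    cnn = TinyCNN(x.shape[1:], n_classes, seed=seed)
    cnn.fit(x, labels, epochs=epochs, lr=lr)
    if preprocess is None:
        return cnn
    from .defenses import compose

    composed = compose(preprocess, cnn)
    composed.converged = cnn.converged
    return composed


def make_synthetic_v1(
    stimuli: Sequence[np.ndarray],
    n_neurons: int,
    rf_band: tuple[float, float] = (0.05, 0.25),
    noise_std: float = 0.1,
    seed: int = 0,
) -> NeuralResponseSet:
    """Stimulus x neuron responses from planted Gabor receptive fields.

    Each neuron responds with ``<g_j, x> + N(0, noise_std)``, where ``g_j``
    is a random Gabor whose carrier radial frequency lies in ``rf_band``
    (Nyquist units). Each filter is projected onto the ideal low-pass band
    ``||f|| <= f_hi`` after construction, so the planted structure is exactly
    band-limited — the generator's contract, not an approximation. The
    filters are kept on the result for recovery tests; they emulate the
    low-spatial-frequency receptive-field structure of mouse V1 populations.
    """
    if n_neurons < 1:
        raise ValueError("need at least one neuron")
    stimuli = np.stack([np.asarray(s, dtype=float) for s in stimuli])
    n, H, W = stimuli.shape[0], stimuli.shape[1], stimuli.shape[2]
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    filters = np.zeros((n_neurons, H, W))
    for j in range(n_neurons):
        cy, cx = rng.uniform(0.25 * H, 0.75 * H), rng.uniform(0.25 * W, 0.75 * W)
        r_nyq = rng.uniform(*rf_band)
        u = r_nyq / 2.0  # cycles/pixel
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        sigma_env = max(2.0, 0.35 / max(u, 1e-3))
        envelope = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_env**2))
        carrier = np.cos(
            2 * np.pi * u * ((xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)) + phase
        )
        g = envelope * carrier
        g = g - g.mean()
        # enforce exact band-limiting: discrete Gabors leak outside the band
        band = np.fft.ifftshift(lowpass_mask(H, W, rf_band[1]).values)
        g = np.fft.ifft2(np.fft.fft2(g) * band).real
        filters[j] = g / (np.linalg.norm(g) + 1e-12)
    responses = stimuli.reshape(n, -1) @ filters.reshape(n_neurons, -1).T
    responses = responses + noise_std * rng.standard_normal(responses.shape)
    return NeuralResponseSet(responses, stimuli, ground_truth_filters=filters)


def make_random_linear_model(
    input_shape: tuple[int, ...] = (4, 4), seed: int = 0, weight_scale: float = 1.0
) -> LinearSoftmaxClassifier:
    """Random two-class linear softmax model for attack-oracle tests."""
    rng = np.random.default_rng(seed)
    n = int(np.prod(input_shape))
    w = rng.normal(0, weight_scale, size=(2, n))
    b = rng.normal(0, 0.1, size=2)
    return LinearSoftmaxClassifier(w, b, input_shape)
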