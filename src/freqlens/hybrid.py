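"""Hybrid-image construction and classifier frequency probing.

A hybrid image takes its Fourier components below a mixing frequency
``f_mix`` from one seed image (the *low* seed) and above it from another (the
*high* seed), the two seeds belonging to different classes:

    I_hybrid = IFFT( FFT(I_low) * M + FFT(I_high) * (1 - M) ),
    M(f) = 1 if ||f|| <= f_mix else 0.

Sweeping ``f_mix`` from 0 to sqrt(2) (Nyquist units) morphs the stimulus from
the high seed to the low seed while keeping every intermediate image an exact
spectral split of the pair. Probing a classifier with such a sweep yields the
probability curves ``p_low(f_mix)`` / ``p_high(f_mix)`` and their crossing,
the reversal frequency ``f_rev`` — the mixing frequency at which the model is
equally likely to report either seed's class. Models that rely on low spatial
frequencies reverse earlier (smaller ``f_rev``).

Hybrids are deliberately not clipped to [0, 1]: clipping would break the
linear spectral-split construction (and the Parseval bookkeeping built on
it). Clipping is applied only when exporting previews.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .spectral import FrequencyGrid, frequency_grid

__all__ = [
    "HybridImage",
    "LowpassMask",
    "ProbeCurve",
    "ReversalEstimate",
    "lowpass_mask",
    "make_hybrid",
    "build_hybrid_dataset",
    "probe_classifier",
    "reversal_frequency",
    "sample_pairs",
    "probe_experiment",
    "default_fmix_grid",
]


@dataclass(frozen=True)
class LowpassMask:
    """Binary radial low-pass indicator on the centered Nyquist-mode grid."""

    grid: FrequencyGrid
    f_mix: float
    values: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class HybridImage:
    """A mixed image together with its construction metadata."""

    pixels: np.ndarray
    f_mix: float
    low_label: int
    high_label: int
    low_seed_id: int = -1
    high_seed_id: int = -1


@dataclass(frozen=True)
class ProbeCurve:
    """p_low / p_high versus mixing frequency for one hybrid dataset."""

    f_mix_grid: np.ndarray
    p_low: np.ndarray
    p_high: np.ndarray
    n_images: np.ndarray
    f_rev: float
    censored: bool


class ReversalEstimate(NamedTuple):
    f_rev: float
    censored: bool


def default_fmix_grid(n: int = 17) -> np.ndarray:
    """Evenly spaced mixing frequencies covering [0, sqrt(2)] Nyquist units."""
    return np.linspace(0.0, np.sqrt(2.0), n)


def lowpass_mask(height: int, width: int, f_mix: float) -> LowpassMask:
    """Binary mask selecting all bins with ``||f|| <= f_mix`` (Nyquist units)."""
    if f_mix < 0:
        raise ValueError("f_mix must be nonnegative")
    grid = frequency_grid(height, width, "nyquist")
    return LowpassMask(grid, float(f_mix), (grid.radius <= f_mix).astype(float))


def make_hybrid(
    low: np.ndarray,
    high: np.ndarray,
    f_mix: float,
    low_label: int = -1,
    high_label: int = -1,
    low_seed_id: int = -1,
    high_seed_id: int = -1,
) -> HybridImage:
    """Mix the low frequencies of ``low`` with the high frequencies of ``high``.

    Works per-channel for RGB inputs, using the same binary mask on each
    channel. The inverse transform of the combined spectrum is real up to
    numerical residue, which is checked before the imaginary part is dropped.
    """
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    if low.shape != high.shape:
        raise ValueError(f"seed shapes differ: {low.shape} vs {high.shape}")
    squeeze = low.ndim == 2
    if squeeze:
        low, high = low[:, :, None], high[:, :, None]
    mask = lowpass_mask(low.shape[0], low.shape[1], f_mix).values
    # Work with unshifted transforms; shift the mask instead.
    m = np.fft.ifftshift(mask)[:, :, None]
    f_low = np.fft.fft2(low, axes=(0, 1))
    f_high = np.fft.fft2(high, axes=(0, 1))
    hybrid = np.fft.ifft2(f_low * m + f_high * (1.0 - m), axes=(0, 1))
    residue = float(np.abs(hybrid.imag).max())
    if residue > 1e-8 * max(1.0, float(np.abs(hybrid.real).max())):
        raise FloatingPointError(f"unexpected imaginary residue {residue:g} in hybrid")
    pixels = hybrid.real
    if squeeze:
        pixels = pixels[:, :, 0]
    return HybridImage(pixels, float(f_mix), low_label, high_label, low_seed_id, high_seed_id)


def sample_pairs(
    labels: np.ndarray, n_pairs: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Draw (low, high) index pairs uniformly subject to class(low) != class(high)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to build hybrid pairs")
    n = len(labels)
    pairs = []
    for _ in range(n_pairs):
        lo = int(rng.integers(n))
        others = np.flatnonzero(labels != labels[lo])
        hi = int(others[rng.integers(len(others))])
        pairs.append((lo, hi))
    return pairs


def build_hybrid_dataset(
    images: Sequence[np.ndarray],
    labels: Sequence[int],
    f_mix_grid: Sequence[float],
    n_pairs: int,
    seed: int,
) -> list[HybridImage]:
    """Build a probe dataset of ``n_pairs * len(f_mix_grid)`` hybrid images.

    The same pair list is reused at every mixing frequency, so curves over the
    grid are a paired comparison: they differ only through the mask. The
    construction is deterministic given ``seed``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    pairs = sample_pairs(labels, n_pairs, rng)
    out = []
    for f_mix in f_mix_grid:
        for lo, hi in pairs:
            out.append(
                make_hybrid(
                    images[lo],
                    images[hi],
                    f_mix,
                    low_label=int(labels[lo]),
                    high_label=int(labels[hi]),
                    low_seed_id=lo,
                    high_seed_id=hi,
                )
            )
    return out


def probe_classifier(
    model,
    hybrids: Sequence[HybridImage],
    mode: Literal["top1", "softmax"] = "top1",
    batch_size: int = 256,
) -> ProbeCurve:
    """Classify a hybrid dataset and estimate p_low / p_high per mixing frequency.

    With ``mode="top1"`` (default) the probabilities are indicator
    frequencies: the fraction of hybrids whose top-1 prediction equals the
    low/high seed label, with argmax ties broken toward the lowest class id.
    ``mode="softmax"`` averages the predicted probability mass instead.
    """
    if not hybrids:
        raise ValueError("empty hybrid dataset")
    fmix = np.array([h.f_mix for h in hybrids])
    grid = np.unique(fmix)
    p_low = np.zeros(len(grid))
    p_high = np.zeros(len(grid))
    n_images = np.zeros(len(grid), dtype=int)
    for gi, f in enumerate(grid):
        idx = np.flatnonzero(fmix == f)
        lows = np.array([hybrids[i].low_label for i in idx])
        highs = np.array([hybrids[i].high_label for i in idx])
        batch_scores_low, batch_scores_high = [], []
        for start in range(0, len(idx), batch_size):
            chunk = idx[start : start + batch_size]
            x = np.stack([hybrids[i].pixels for i in chunk])
            try:
                probs = model.predict_proba(x)
            except Exception as exc:  # pragma: no cover - propagation path
                raise RuntimeError(
                    f"model failed on probe batch starting at index {int(chunk[0])}"
                ) from exc
            if mode == "top1":
                pred = np.argmax(probs, axis=1)  # ties -> lowest class id
                batch_scores_low.append(pred == lows[start : start + batch_size])
                batch_scores_high.append(pred == highs[start : start + batch_size])
            elif mode == "softmax":
                rows = np.arange(len(chunk))
                batch_scores_low.append(probs[rows, lows[start : start + batch_size]])
                batch_scores_high.append(probs[rows, highs[start : start + batch_size]])
            else:
                raise ValueError(f"unknown probe mode {mode!r}")
        p_low[gi] = float(np.concatenate(batch_scores_low).mean())
        p_high[gi] = float(np.concatenate(batch_scores_high).mean())
        n_images[gi] = len(idx)
    est = _first_crossing(grid, p_low - p_high)
    return ProbeCurve(grid, p_low, p_high, n_images, est.f_rev, est.censored)


def _first_crossing(grid: np.ndarray, d: np.ndarray) -> ReversalEstimate:
    for i in range(len(grid) - 1):
        if d[i] <= 0.0 < d[i + 1]:
            t = (0.0 - d[i]) / (d[i + 1] - d[i])
            return ReversalEstimate(float(grid[i] + t * (grid[i + 1] - grid[i])), False)
    return ReversalEstimate(float("nan"), True)


def reversal_frequency(curve: ProbeCurve) -> ReversalEstimate:
    """Reversal frequency of a probe curve.

    ``f_rev`` is the first crossing of ``d(f) = p_low - p_high`` from <= 0 to
    > 0, located by linear interpolation between the bracketing grid points.
    If the curve never crosses, the estimate is NaN with ``censored=True`` —
    no number is fabricated for boundary-censored curves.
    """
    if len(curve.f_mix_grid) < 2:
        raise ValueError("need at least two grid points to locate a crossing")
    return _first_crossing(np.asarray(curve.f_mix_grid), curve.p_low - curve.p_high)


class ProbeExperimentResult(NamedTuple):
    f_rev: float
    spread: float
    curves: list[ProbeCurve]


def probe_experiment(
    model,
    images: Sequence[np.ndarray],
    labels: Sequence[int],
    f_mix_grid: Sequence[float] | None = None,
    n_pairs: int = 200,
    n_permutations: int = 4,
    seed: int = 0,
    mode: Literal["top1", "softmax"] = "top1",
) -> ProbeExperimentResult:
    """Full hybrid probe with uncertainty from re-drawn pairings.

    Runs ``n_permutations`` independent hybrid datasets (fresh pair draws from
    the same image pool), estimates ``f_rev`` on each, and reports the mean
    and standard deviation over the non-censored replicates.
    """
    if f_mix_grid is None:
        f_mix_grid = default_fmix_grid()
    curves = []
    estimates = []
    for k in range(n_permutations):
        hybrids = build_hybrid_dataset(images, labels, f_mix_grid, n_pairs, seed + k)
        curve = probe_classifier(model, hybrids, mode=mode)
        curves.append(curve)
        if not curve.censored:
            estimates.append(curve.f_rev)
    if not estimates:
        return ProbeExperimentResult(float("nan"), float("nan"), curves)
    spread = float(np.std(estimates, ddof=1)) if len(estimates) > 1 else 0.0
    return ProbeExperimentResult(float(np.mean(estimates)), spread, curves)
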