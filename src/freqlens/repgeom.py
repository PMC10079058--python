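"""Representational-similarity eigenanalysis and linear receptive-field maps.

Given a stimuli x neurons response matrix, the representational similarity
matrix holds the pairwise cosine similarity between population response
vectors. Its eigendecomposition exposes the dominant dimensions of the
representation; regressing each principal component's per-stimulus scores
onto the stimulus pixels (ridge least squares) yields a spatial map — a
linear receptive-field approximation of that component. For V1-like
populations these maps concentrate their spectral power at low spatial
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg
from sklearn.linear_model import Ridge

__all__ = [
    "NeuralResponseSet",
    "similarity_matrix",
    "eigendecompose",
    "linear_rf_approximation",
]


@dataclass
class NeuralResponseSet:
    """Stimulus x neuron responses with their stimulus images.

    ``similarity`` is computed lazily on first access. ``ground_truth_filters``
    is populated by the synthetic generator for recovery tests.
    """

    responses: np.ndarray
    stimulus_images: np.ndarray
    ground_truth_filters: np.ndarray | None = field(default=None, repr=False)
    _similarity: np.ndarray | None = field(default=None, repr=False)

    @property
    def similarity(self) -> np.ndarray:
        if self._similarity is None:
            self._similarity = similarity_matrix(self.responses)
        return self._similarity


def similarity_matrix(responses: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between population response rows."""
    R = np.asarray(responses, dtype=float)
    norms = np.linalg.norm(R, axis=1)
    zero = np.flatnonzero(norms == 0)
    if len(zero):
        raise ValueError(f"all-zero response row for stimulus {int(zero[0])}")
    unit = R / norms[:, None]
    S = unit @ unit.T
    np.fill_diagonal(S, 1.0)
    return np.clip(S, -1.0, 1.0)


def eigendecompose(similarity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spectral decomposition of a symmetric similarity matrix.

    Returns eigenvalues sorted descending and eigenvectors as columns, each
    sign-fixed so its largest-magnitude entry is positive.
    """
    S = np.asarray(similarity, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity must be square")
    if np.abs(S - S.T).max() > 1e-8:
        raise ValueError("similarity matrix is not symmetric")
    evals, evecs = linalg.eigh((S + S.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    flip = evecs[np.abs(evecs).argmax(axis=0), np.arange(evecs.shape[1])] < 0
    evecs[:, flip] *= -1.0
    return evals, evecs


def linear_rf_approximation(
    eigenvector: np.ndarray,
    stimulus_images: Sequence[np.ndarray],
    ridge: float | None = None,
) -> np.ndarray:
    """Ridge regression of per-stimulus component scores onto pixels.

    ``ridge=None`` uses the default ``1e-3 * trace(X X^T)`` (the raw stimulus
    Gram matrix) — a scale-free shrinkage that keeps the problem solvable
    when there are more pixels than stimuli and suppresses the spurious
    coefficients that plain least squares places on low-variance pixel
    directions. Returns the coefficient map reshaped to the stimulus image
    shape.
    """
    scores = np.asarray(eigenvector, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("component scores must be finite")
    images = np.stack([np.asarray(im, dtype=float) for im in stimulus_images])
    n = len(images)
    if scores.shape != (n,):
        raise ValueError("one score per stimulus required")
    X = images.reshape(n, -1)
    if ridge is None:
        ridge = 1e-3 * float(np.einsum("ij,ij->", X, X))
    model = Ridge(alpha=max(ridge, 1e-12), fit_intercept=True)
    model.fit(X, scores)
    return model.coef_.reshape(images.shape[1:])
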