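"""The classifier contract shared by the probe and attack harnesses.

Every model analyzed by this package — tiny trainable CNNs, analytic oracle
classifiers, linear toy models, and defense-composed versions of any of them
— satisfies the same minimal contract:

* ``n_classes`` and ``input_shape`` describe the interface;
* ``predict_proba(batch)`` maps a ``(B, *input_shape)`` array to ``(B, K)``
  probabilities (rows sum to one);
* ``loss_gradient(batch, targets)`` returns the gradient of the targeted
  cross-entropy loss ``-log p_target`` with respect to the input, shaped like
  the batch. Models without gradients raise :class:`GradientUnavailable`.

Gradients are exact analytic backprop, not finite differences, so composed
preprocessing layers must supply their true adjoint.
"""

from __future__ import annotations

import abc

import numpy as np

__all__ = [
    "ClassifierHandle",
    "GradientUnavailable",
    "LinearSoftmaxClassifier",
    "ConstantClassifier",
    "softmax",
]


class GradientUnavailable(NotImplementedError):
    """Raised when a model cannot provide input gradients."""


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class ClassifierHandle(abc.ABC):
    """Abstract base for all probe-able / attack-able classifiers."""

    n_classes: int
    input_shape: tuple[int, ...]

    @abc.abstractmethod
    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch of images, shape (B, n_classes)."""

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Top-1 labels; argmax ties resolve to the lowest class id."""
        return np.argmax(self.predict_proba(images), axis=1)

    def loss_gradient(self, images: np.ndarray, targets: np.ndarray) -> np.ndarray:
        """Gradient of -log p_target w.r.t. the input, shaped like ``images``."""
        raise GradientUnavailable(f"{type(self).__name__} provides no input gradient")

    def _check_batch(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.shape[1:] != tuple(self.input_shape):
            raise ValueError(
                f"batch shape {images.shape[1:]} does not match model input {self.input_shape}"
            )
        return images


class LinearSoftmaxClassifier(ClassifierHandle):
    """Multinomial logistic model ``p = softmax(W x + b)`` on flattened pixels.

    The workhorse for attack-oracle tests: for two classes the minimal
    L-infinity perturbation that flips the decision has the closed form
    ``margin / ||w_t - w_c||_1``, see :meth:`linf_margin`.
    """

    def __init__(self, weights: np.ndarray, bias: np.ndarray, input_shape: tuple[int, ...]):
        weights = np.asarray(weights, dtype=float)
        bias = np.asarray(bias, dtype=float)
        if weights.shape[1] != int(np.prod(input_shape)):
            raise ValueError("weight width must equal the flattened input size")
        if bias.shape != (weights.shape[0],):
            raise ValueError("bias shape mismatch")
        self.weights = weights
        self.bias = bias
        self.n_classes = weights.shape[0]
        self.input_shape = tuple(input_shape)

    def scores(self, images: np.ndarray) -> np.ndarray:
        x = self._check_batch(images).reshape(len(images), -1)
        return x @ self.weights.T + self.bias

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return softmax(self.scores(images))

    def loss_gradient(self, images: np.ndarray, targets: np.ndarray) -> np.ndarray:
        images = self._check_batch(images)
        targets = np.asarray(targets, dtype=int)
        p = self.predict_proba(images)
        p[np.arange(len(p)), targets] -= 1.0
        grad = p @ self.weights
        return grad.reshape(images.shape)

    def linf_margin(self, image: np.ndarray, target: int) -> float:
        """Exact minimal L-infinity perturbation flipping a 2-class decision.

        For the decision boundary ``(w_t - w_c) . x + (b_t - b_c) = 0`` the
        optimal unconstrained attack moves every pixel by the same amount in
        the direction ``sign(w_t - w_c)``, giving margin / l1-norm.
        """
        if self.n_classes != 2:
            raise ValueError("closed form applies to two-class models only")
        current = 1 - target
        dw = self.weights[target] - self.weights[current]
        db = self.bias[target] - self.bias[current]
        score = float(dw @ np.asarray(image, dtype=float).ravel() + db)
        if score > 0:
            return 0.0
        return -score / float(np.abs(dw).sum())


class ConstantClassifier(ClassifierHandle):
    """Always predicts one fixed class. Useful as a degenerate test model."""

    def __init__(self, n_classes: int, input_shape: tuple[int, ...], label: int = 0):
        self.n_classes = n_classes
        self.input_shape = tuple(input_shape)
        self.label = label

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        images = self._check_batch(images)
        probs = np.zeros((len(images), self.n_classes))
        probs[:, self.label] = 1.0
        return probs
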