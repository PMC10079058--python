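"""Minimal-L-infinity adversarial perturbation search and robustness curves.

The headline adversarial statistic is, per image, the size of the smallest
L-infinity perturbation that flips the classifier's prediction to a
predetermined wrong target class. The search protocol:

1. one or more *attack engines* propose adversarial candidates at a given
   budget epsilon (the built-in engine is targeted PGD with random starts);
2. an outer bisection on epsilon (bracket [0, 0.5], tolerance 0.5/255)
   localizes the smallest budget at which some engine succeeds;
3. candidates from all engines and random seeds are pooled and the smallest
   successful perturbation wins — enlarging the engine/seed set can only
   shrink the reported epsilon.

Epsilons are stored in [0, 1] pixel units; multiply by 255 for the
conventional n/255 display. Aggregates: the success-rate curve ``s(eps)``
(censored attacks count as failures at every budget, never dropped) and the
budget ``eps50`` giving 50% success.

The corruption-accuracy harness evaluates a classifier over a procedural
corruption suite and aggregates by severity and by frequency group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .corruptions import CorruptionSpec, apply_corruption
from .models import ClassifierHandle

__all__ = [
    "AttackResult",
    "AttackConfig",
    "pgd_targeted",
    "minimal_perturbation",
    "minimal_perturbations_batch",
    "make_targets",
    "success_curve",
    "SuccessCurve",
    "corruption_accuracy",
    "CorruptionReport",
]

BISECTION_TOL = 0.5 / 255.0


@dataclass(frozen=True)
class AttackResult:
    """Outcome of the minimal-perturbation search for one image."""

    image_id: int
    target_class: int
    epsilon_min: float
    adversarial: np.ndarray = field(repr=False)
    engine: str
    converged: bool

    @property
    def epsilon_255(self) -> float:
        return self.epsilon_min * 255.0


@dataclass(frozen=True)
class AttackConfig:
    steps: int = 100
    n_seeds: int = 5
    epsilon_max: float = 0.5
    tolerance: float = BISECTION_TOL


def pgd_targeted(
    model: ClassifierHandle,
    image: np.ndarray,
    target: int,
    epsilon: float,
    steps: int = 100,
    seed: int = 0,
) -> tuple[bool, np.ndarray]:
    """Targeted projected gradient descent inside an L-infinity ball.

    Minimizes ``-log p_target`` by signed-gradient steps of size
    ``2.5 * epsilon / steps`` from a uniform random start in the ball,
    projecting each iterate onto the ball intersected with [0, 1]. Returns
    (success, candidate); success means the final top-1 equals the target.
    """
    if not 0 < epsilon <= 0.5:
        raise ValueError("epsilon must be in (0, 0.5]")
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    x = image + rng.uniform(-epsilon, epsilon, size=image.shape)
    x = np.clip(np.clip(x, image - epsilon, image + epsilon), 0.0, 1.0)
    alpha = 2.5 * epsilon / steps
    tgt = np.array([target])
    for _ in range(steps):
        grad = model.loss_gradient(x[None], tgt)[0]
        x = x - alpha * np.sign(grad)
        x = np.clip(np.clip(x, image - epsilon, image + epsilon), 0.0, 1.0)
    success = int(model.predict(x[None])[0]) == target
    return success, x


def _pgd_engine(model, image, target, epsilon, seed, config: AttackConfig):
    return pgd_targeted(model, image, target, epsilon, steps=config.steps, seed=seed)


BUILTIN_ENGINES: dict[str, Callable] = {"pgd": _pgd_engine}


def minimal_perturbation(
    model: ClassifierHandle,
    image: np.ndarray,
    target: int,
    engines: Sequence[str | Callable] = ("pgd",),
    n_seeds: int = 5,
    config: AttackConfig | None = None,
    image_id: int = -1,
    seed: int = 0,
) -> AttackResult:
    """Smallest targeted L-infinity perturbation over engines x seeds x bisection.

    Engines may be built-in names ("pgd") or callables with signature
    ``(model, image, target, epsilon, seed, config) -> (success, candidate)``,
    which is the hook for plugging external attack libraries. The reported
    ``epsilon_min`` is the measured L-infinity norm of the best candidate
    found; if no engine succeeds at the maximal budget, the result carries
    ``converged=False`` and the best attempt.
    """
    config = config or AttackConfig(n_seeds=n_seeds)
    image = np.asarray(image, dtype=float)
    if int(model.predict(image[None])[0]) == target:
        return AttackResult(image_id, target, 0.0, image.copy(), "identity", True)

    resolved: list[tuple[str, Callable]] = []
    for eng in engines:
        if callable(eng):
            resolved.append((getattr(eng, "__name__", "custom"), eng))
        elif eng in BUILTIN_ENGINES:
            resolved.append((eng, BUILTIN_ENGINES[eng]))
        else:
            raise ValueError(f"unknown attack engine {eng!r}")

    best: tuple[float, np.ndarray, str] | None = None

    def try_eps(eps: float) -> bool:
        nonlocal best
        ok = False
        for name, engine in resolved:
            for s in range(n_seeds):
                success, cand = engine(model, image, target, eps, seed + 1000 * s, config)
                if success:
                    size = float(np.abs(cand - image).max())
                    if best is None or size < best[0]:
                        best = (size, cand, name)
                    ok = True
        return ok

    hi = config.epsilon_max
    if not try_eps(hi):
        fallback = best if best is not None else (hi, image.copy(), resolved[0][0])
        return AttackResult(image_id, target, fallback[0], fallback[1], fallback[2], False)
    lo = 0.0
    while hi - lo > config.tolerance:
        mid = 0.5 * (lo + hi)
        if try_eps(mid):
            hi = mid
        else:
            lo = mid
    assert best is not None
    size, cand, name = best
    cand = _shrink_candidate(model, image, cand, target)
    return AttackResult(
        image_id, target, float(np.abs(cand - image).max()), cand, name, True
    )


def _shrink_candidate(
    model: ClassifierHandle, image: np.ndarray, candidate: np.ndarray, target: int
) -> np.ndarray:
    """Scale a successful perturbation down as far as it stays adversarial.

    A successful candidate from a budget-eps PGD run typically sits on the
    ball surface even when the decision boundary is closer; a binary search
    on the scale of the perturbation tightens epsilon_min well below the
    outer bisection tolerance. Convexity of [0, 1] keeps every scaled
    candidate a valid image.
    """
    delta = candidate - image
    lo, hi = 0.0, 1.0
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if int(model.predict((image + mid * delta)[None])[0]) == target:
            hi = mid
        else:
            lo = mid
    return image + hi * delta


def minimal_perturbations_batch(
    model: ClassifierHandle,
    images: np.ndarray,
    targets: Sequence[int],
    config: AttackConfig | None = None,
    seed: int = 0,
) -> list[AttackResult]:
    """Vectorized minimal-perturbation search over a whole image set.

    Equivalent to calling :func:`minimal_perturbation` with the built-in PGD
    engine per image, but the outer bisection is run synchronously across
    images (each with its own bracket), so every PGD step is one batched
    forward/backward pass. ``n_seeds`` random restarts are folded into the
    batch as well.
    """
    config = config or AttackConfig()
    images = np.asarray(images, dtype=float)
    targets = np.asarray(targets, dtype=int)
    n = len(images)
    rng = np.random.default_rng(seed)
    already = model.predict(images) == targets

    n_seeds = config.n_seeds
    rep_img = np.repeat(images, n_seeds, axis=0)
    rep_tgt = np.repeat(targets, n_seeds)

    def pgd_batch(eps_per_image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Run PGD at per-image epsilon; returns per-image success and best candidate."""
        eps = np.repeat(eps_per_image, n_seeds)
        shape = (-1,) + (1,) * (images.ndim - 1)
        e = eps.reshape(shape)
        x = rep_img + rng.uniform(-1, 1, size=rep_img.shape) * e
        x = np.clip(np.clip(x, rep_img - e, rep_img + e), 0.0, 1.0)
        alpha = 2.5 * e / config.steps
        for _ in range(config.steps):
            grad = model.loss_gradient(x, rep_tgt)
            x = np.clip(np.clip(x - alpha * np.sign(grad), rep_img - e, rep_img + e), 0.0, 1.0)
        ok = model.predict(x) == rep_tgt
        success = ok.reshape(n, n_seeds).any(axis=1)
        # For each image keep the smallest successful candidate perturbation.
        best = np.empty_like(images)
        sizes = np.abs(x - rep_img).max(axis=tuple(range(1, images.ndim)))
        sizes = np.where(ok, sizes, np.inf).reshape(n, n_seeds)
        pick = sizes.argmin(axis=1)
        best = x.reshape(n, n_seeds, *images.shape[1:])[np.arange(n), pick]
        return success, best

    hi = np.full(n, config.epsilon_max)
    lo = np.zeros(n)
    success0, cand = pgd_batch(hi)
    converged = success0 & ~already
    best = np.where(
        converged.reshape((-1,) + (1,) * (images.ndim - 1)), cand, images
    )
    active = converged.copy()
    while active.any() and (hi[active] - lo[active]).max() > config.tolerance:
        mid = np.where(active, 0.5 * (lo + hi), hi)
        succ, cand = pgd_batch(np.maximum(mid, 1e-6))
        take = active & succ
        hi = np.where(take, mid, hi)
        lo = np.where(active & ~succ, mid, lo)
        best[take] = cand[take]
        active = active & ((hi - lo) > config.tolerance)

    results = []
    for i in range(n):
        if already[i]:
            results.append(
                AttackResult(i, int(targets[i]), 0.0, images[i].copy(), "identity", True)
            )
        elif not converged[i]:
            results.append(
                AttackResult(
                    i, int(targets[i]), float(np.abs(best[i] - images[i]).max()),
                    best[i], "pgd", False,
                )
            )
        else:
            cand_i = _shrink_candidate(model, images[i], best[i], int(targets[i]))
            results.append(
                AttackResult(
                    i, int(targets[i]), float(np.abs(cand_i - images[i]).max()),
                    cand_i, "pgd", True,
                )
            )
    return results


def make_targets(labels: Sequence[int], n_classes: int, seed: int = 0) -> np.ndarray:
    """Fixed random wrong-class target per image (drawn once, reproducible)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    offsets = rng.integers(1, n_classes, size=len(labels))
    return (labels + offsets) % n_classes


class SuccessCurve(NamedTuple):
    epsilon_grid: np.ndarray
    success_rate: np.ndarray
    eps50: float


def success_curve(
    results: Sequence[AttackResult], epsilon_grid: Sequence[float] | None = None
) -> SuccessCurve:
    """Attack success rate versus budget, and the budget at 50% success.

    ``s(eps)`` counts converged results with ``epsilon_min <= eps``; censored
    results stay failures at every budget (dropping them would bias eps50
    downward). ``eps50`` is linearly interpolated at the first upward 0.5
    crossing, NaN when the curve never reaches one half.
    """
    if not results:
        raise ValueError("no attack results")
    sizes = np.array([r.epsilon_min if r.converged else np.inf for r in results])
    if epsilon_grid is None:
        finite = sizes[np.isfinite(sizes)]
        top = float(finite.max()) if len(finite) else 0.5
        epsilon_grid = np.linspace(0.0, max(top, 1e-3), 256)
    epsilon_grid = np.asarray(epsilon_grid, dtype=float)
    rate = np.array([(sizes <= e).mean() for e in epsilon_grid])
    eps50 = float("nan")
    for i in range(len(rate)):
        if rate[i] >= 0.5:
            if i == 0 or rate[i] == rate[i - 1]:
                eps50 = float(epsilon_grid[i])
            else:
                t = (0.5 - rate[i - 1]) / (rate[i] - rate[i - 1])
                eps50 = float(epsilon_grid[i - 1] + t * (epsilon_grid[i] - epsilon_grid[i - 1]))
            break
    return SuccessCurve(epsilon_grid, rate, eps50)


@dataclass(frozen=True)
class CorruptionReport:
    """Accuracy per (corruption, severity) with frequency-group aggregates."""

    accuracy: pd.DataFrame  # index: corruption name, columns: severity
    group_means: pd.Series  # index: low / mid / high
    severity_means: pd.Series  # index: severity
    clean_accuracy: float


def corruption_accuracy(
    model: ClassifierHandle,
    images: Sequence[np.ndarray],
    labels: Sequence[int],
    suite: Sequence[CorruptionSpec],
    batch_size: int = 256,
) -> CorruptionReport:
    """Evaluate a classifier across a corruption suite.

    Group means average the member (corruption, severity) cells of each
    frequency group; severity means average over corruptions at fixed
    severity.
    """
    images = np.stack([np.asarray(im, dtype=float) for im in images])
    labels = np.asarray(labels, dtype=int)

    def acc(batch: np.ndarray) -> float:
        preds = []
        for start in range(0, len(batch), batch_size):
            preds.append(model.predict(batch[start : start + batch_size]))
        return float((np.concatenate(preds) == labels).mean())

    cells: dict[tuple[str, int], float] = {}
    groups: dict[str, str] = {}
    for spec in suite:
        corrupted = np.stack([apply_corruption(im, spec) for im in images])
        cells[(spec.name, spec.severity)] = acc(corrupted)
        groups[spec.name] = spec.group
    names = sorted({k[0] for k in cells})
    severities = sorted({k[1] for k in cells})
    table = pd.DataFrame(
        [[cells.get((n, s), np.nan) for s in severities] for n in names],
        index=names,
        columns=severities,
    )
    group_vals = {}
    for g in ("low", "mid", "high"):
        members = [n for n in names if groups[n] == g]
        if members:
            group_vals[g] = float(table.loc[members].to_numpy().mean())
    return CorruptionReport(
        accuracy=table,
        group_means=pd.Series(group_vals),
        severity_means=table.mean(axis=0),
        clean_accuracy=acc(images),
    )
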