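"""Reading and writing images, spectra, and analysis tables.

Images travel as float arrays in [0, 1]; PNG export rescales to 8-bit (and
clips, which matters for unclipped hybrid images — PNG previews are lossy by
design, NPZ archives are not).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .defenses import PcaBasis
from .hybrid import ProbeCurve
from .spectral import RadialProfile

__all__ = [
    "read_image",
    "write_image",
    "read_image_dir",
    "save_dataset",
    "load_dataset",
    "profile_to_csv",
    "curve_to_csv",
    "save_pca_basis",
    "load_pca_basis",
]


def read_image(path) -> np.ndarray:
    """Load a PNG (or any imageio-readable file) as floats in [0, 1]."""
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr / 255.0


def write_image(path, image: np.ndarray) -> None:
    """Save as 8-bit PNG; values are clipped to [0, 1] first."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (arr * 255.0).round().astype(np.uint8))


def read_image_dir(directory) -> np.ndarray:
    """Stack all PNG files in a directory, sorted by filename."""
    paths = sorted(Path(directory).glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG files in {directory}")
    return np.stack([read_image(p) for p in paths])


def save_dataset(path, images: np.ndarray, labels: np.ndarray, **extra) -> None:
    np.savez_compressed(path, images=images, labels=labels, **extra)


def load_dataset(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.load(path)
    return data["images"], data["labels"]


def profile_to_csv(path, profile: RadialProfile) -> None:
    pd.DataFrame({"radius": profile.radii, "cum_fraction": profile.cum_fraction}).to_csv(
        path, index=False
    )


def curve_to_csv(path, curve: ProbeCurve) -> None:
    pd.DataFrame(
        {
            "f_mix": curve.f_mix_grid,
            "p_low": curve.p_low,
            "p_high": curve.p_high,
            "n": curve.n_images,
        }
    ).to_csv(path, index=False)


def save_pca_basis(path, basis: PcaBasis) -> None:
    np.savez_compressed(
        path, mean=basis.mean, components=basis.components, eigenvalues=basis.eigenvalues
    )


def load_pca_basis(path) -> PcaBasis:
    data = np.load(path)
    comps = data["components"]
    return PcaBasis(
        data["mean"], comps, data["eigenvalues"], N=comps.shape[1], K=comps.shape[0]
    )
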