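"""Test and training phantoms.

Two generators cover everything the experiments need: the standard
Shepp-Logan head phantom (modified, high-contrast variant with values in
[0, 1]) for evaluation, and random binary-blob phantoms -- superpositions of
up to six constant-valued ellipses -- used to train the data-driven
correctors.  :func:`make_training_set` bundles phantoms with their
sensitivity-weighted sinograms and uncorrected FBP reconstructions into a
reproducible train/validation dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .geometry import GeometryConfig, SensitivityProfile

__all__ = [
    "BlobPhantomConfig",
    "TrainingSet",
    "shepp_logan",
    "random_blob_phantom",
    "make_training_set",
]

# Ellipses of the modified (high-contrast) Shepp-Logan phantom:
# (intensity, half-axis a, half-axis b, x0, y0, rotation in degrees),
# in the conventional [-1, 1]^2 coordinate frame, intensities additive.
_SHEPP_LOGAN_ELLIPSES = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


def _ellipse_mask(xx, yy, a, b, x0, y0, phi_deg):
    phi = np.deg2rad(phi_deg)
    c, s = np.cos(phi), np.sin(phi)
    xr = (xx - x0) * c + (yy - y0) * s
    yr = -(xx - x0) * s + (yy - y0) * c
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def shepp_logan(size: int = 400) -> np.ndarray:
    """Rasterize the modified Shepp-Logan phantom at ``size x size`` pixels.

    Deterministic; values lie in [0, 1] and the background outside the outer
    ellipse is exactly zero.
    """
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    coords = (2.0 * np.arange(size) - (size - 1)) / size
    xx, yy = np.meshgrid(coords, -coords)  # y up, matching the standard table
    img = np.zeros((size, size))
    for inten, a, b, x0, y0, phi in _SHEPP_LOGAN_ELLIPSES:
        img[_ellipse_mask(xx, yy, a, b, x0, y0, phi)] += inten
    return np.clip(img, 0.0, 1.0)


@dataclass(frozen=True)
class BlobPhantomConfig:
    """Random binary-blob phantom: up to ``max_blobs`` constant-gray ellipses.

    Blob radii are drawn uniformly from ``radius_range`` (defaults to
    ``(0.025, 0.2)`` of the image width, i.e. 10-80 px at 400), gray values
    uniformly from ``(value_min, value_max]``, and overlaps combine by taking
    the maximum so every connected component stays binary.
    """

    size: int = 400
    max_blobs: int = 6
    radius_range: Optional[Tuple[float, float]] = None
    value_range: Tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 8:
            raise ValueError("size must be >= 8")
        if self.max_blobs < 1:
            raise ValueError("max_blobs must be >= 1")
        lo, hi = self.radii
        if not 0 < lo <= hi:
            raise ValueError(f"degenerate radius range ({lo}, {hi})")
        vlo, vhi = self.value_range
        if not 0 <= vlo < vhi <= 1:
            raise ValueError(f"value range must satisfy 0 <= lo < hi <= 1, got {self.value_range}")

    @property
    def radii(self) -> Tuple[float, float]:
        if self.radius_range is not None:
            return self.radius_range
        return (0.025 * self.size, 0.2 * self.size)


def random_blob_phantom(config: BlobPhantomConfig) -> np.ndarray:
    """Draw one blob phantom; a pure function of the config (incl. its seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.size
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    img = np.zeros((n, n))
    n_blobs = int(rng.integers(1, config.max_blobs + 1))
    r_lo, r_hi = config.radii
    v_lo, v_hi = config.value_range
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0, n - 1, size=2)
        a, b = rng.uniform(r_lo, r_hi, size=2)
        phi = rng.uniform(0, np.pi)
        # uniform on (v_lo, v_hi]: blobs are never exactly zero-valued
        value = v_hi - rng.uniform(0, 1) * (v_hi - v_lo)
        mask = _ellipse_mask(cols, rows, a, b, cx, cy, np.rad2deg(phi))
        img[mask] = np.maximum(img[mask], value)
    return img


@dataclass
class TrainingSet:
    """Paired dataset of (ground truth, weighted sinogram, uncorrected FBP).

    ``images``, ``fbp`` have shape ``(n, N, N)``; ``sinograms``
    ``(n, n_angles, n_detector)``.  ``train_idx``/``val_idx`` partition
    ``range(n)`` disjointly.
    """

    images: np.ndarray
    sinograms: np.ndarray
    fbp: np.ndarray
    train_idx: np.ndarray
    val_idx: np.ndarray
    geometry: GeometryConfig
    profile: SensitivityProfile
    master_seed: int

    def __len__(self) -> int:
        return self.images.shape[0]


def make_training_set(
    n: int,
    split: float,
    config: BlobPhantomConfig,
    geometry: GeometryConfig,
    profile: SensitivityProfile,
) -> TrainingSet:
    """Generate ``n`` blob phantoms with sinograms and FBP reconstructions.

    Per-item seeds are ``config.seed + i`` (a counter off the master seed), so
    the dataset is bit-reproducible.  The first ``round(n * split)`` items are
    the training split, the rest validation.
    """
    from .classic import fbp as _fbp
    from .projector import weighted_forward_project

    if n < 2:
        raise ValueError("need at least 2 phantoms")
    if not 0 < split < 1:
        raise ValueError("split must lie in (0, 1)")
    if config.size != geometry.image_size:
        config = replace(config, size=geometry.image_size)

    images = np.empty((n, *geometry.image_shape))
    sinos = np.empty((n, geometry.n_angles, geometry.n_detector))
    recos = np.empty_like(images)
    for i in range(n):
        img = random_blob_phantom(replace(config, seed=config.seed + i))
        sino = weighted_forward_project(img, geometry, profile)
        images[i] = img
        sinos[i] = sino.values
        recos[i] = _fbp(sino)
    n_train = int(round(n * split))
    idx = np.arange(n)
    return TrainingSet(
        images=images, sinograms=sinos, fbp=recos,
        train_idx=idx[:n_train], val_idx=idx[n_train:],
        geometry=geometry, profile=profile, master_seed=config.seed,
    )
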