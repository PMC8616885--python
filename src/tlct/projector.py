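"""Sensitivity-weighted forward model, its exact adjoint, and Poisson noise.

The forward model is the weighted Radon transform: for each projection angle
``theta`` and detector position ``t`` the line integral of the object is taken
with every point on the ray multiplied by the interferometer sensitivity at
that point,

    p(theta, t) = integral  S(r) * x(r)  dr  along the ray,

discretized with a ray-driven projector (unit steps, bilinear interpolation;
see :mod:`tlct._kernels`).  The experiments use direct line-integral data, so
no derivative along ``t`` is applied.  :class:`WeightedSystem` exposes the
system as matrix-free operators ``B W`` (forward), ``W^T B^T`` (adjoint),
their single-angle rows, and the exact per-ray normalization
``b_i W W^T b_i^T`` used by the algebraic update rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .geometry import GeometryConfig, SensitivityProfile, ramp_weight

__all__ = [
    "Sinogram",
    "WeightedSystem",
    "weighted_forward_project",
    "unweighted_radon",
    "weighted_backproject",
    "unweighted_backproject",
    "row_norm",
    "add_poisson_noise",
]

#: positive floor for normalization factors of rays that miss the grid
ROW_NORM_FLOOR = 1e-12


@dataclass
class Sinogram:
    """An ``n_angles x n_detector`` array of (weighted) line integrals."""

    values: np.ndarray
    geometry: GeometryConfig

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_angles, self.geometry.n_detector)
        if self.values.shape != expected:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")

    @property
    def angles(self) -> np.ndarray:
        return self.geometry.angles

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.geometry)


def _step_weights(geometry: GeometryConfig, profile: Optional[SensitivityProfile]) -> np.ndarray:
    """Sensitivity weight per unit step along the beam, shared by all angles.

    The ray is sampled at ``L`` unit steps covering the grid diagonal; the
    ramp is centered on the rotation center and clamped outside its extent.
    ``profile=None`` yields unit weights (the plain Radon transform).
    """
    n = geometry.image_size
    L = 2 * int(np.ceil(0.5 * n * np.sqrt(2.0))) + 3
    sigma = np.arange(L, dtype=float) - 0.5 * (L - 1)
    if profile is None:
        return np.ones(L)
    return np.asarray(ramp_weight(sigma + 0.5 * (profile.extent - 1), profile))


def _check_image(image: np.ndarray, geometry: GeometryConfig) -> np.ndarray:
    image = np.ascontiguousarray(image, dtype=np.float64)
    if image.shape != geometry.image_shape:
        raise ValueError(f"image shape {image.shape} does not match geometry {geometry.image_shape}")
    return image


@dataclass
class WeightedSystem:
    """Matrix-free view of the weighted system ``min 1/2 ||B W x - p||^2``.

    ``B`` stacks the per-angle projection matrices, ``W`` the per-angle voxel
    sensitivities.  ``forward`` applies ``B W``, ``adjoint`` applies
    ``W^T B^T``; ``forward_one``/``adjoint_one`` expose the block of a single
    angle, and ``row_norms`` the exact squared row norms (sum of squared
    weighted interpolation coefficients along each ray), floored at
    ``ROW_NORM_FLOOR`` for rays that miss the grid.
    """

    geometry: GeometryConfig
    profile: Optional[SensitivityProfile] = None
    _weights: np.ndarray = field(init=False, repr=False)
    _cos: np.ndarray = field(init=False, repr=False)
    _sin: np.ndarray = field(init=False, repr=False)
    _row_norms: Optional[np.ndarray] = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self._weights = _step_weights(self.geometry, self.profile)
        angles = self.geometry.angles
        self._cos = np.cos(angles)
        self._sin = np.sin(angles)

    @property
    def tau_scale(self) -> float:
        return self.geometry.detector_spacing / self.geometry.pixel_spacing

    def forward_one(self, image: np.ndarray, i: int, out: Optional[np.ndarray] = None) -> np.ndarray:
        if out is None:
            out = np.empty(self.geometry.n_detector)
        _kernels.forward_angle(
            image, self._cos[i], self._sin[i], self._weights,
            self.geometry.n_detector, self.tau_scale, self.geometry.pixel_spacing, out,
        )
        return out

    def adjoint_one(self, row: np.ndarray, i: int, out: Optional[np.ndarray] = None) -> np.ndarray:
        if out is None:
            out = np.zeros(self.geometry.image_shape)
        _kernels.backproject_angle(
            np.ascontiguousarray(row, dtype=np.float64),
            self._cos[i], self._sin[i], self._weights,
            self.tau_scale, self.geometry.pixel_spacing, out,
        )
        return out

    def forward(self, image: np.ndarray) -> np.ndarray:
        image = _check_image(image, self.geometry)
        out = np.empty((self.geometry.n_angles, self.geometry.n_detector))
        for i in range(self.geometry.n_angles):
            self.forward_one(image, i, out[i])
        return out

    def adjoint(self, sino_values: np.ndarray) -> np.ndarray:
        sino_values = np.asarray(sino_values, dtype=np.float64)
        expected = (self.geometry.n_angles, self.geometry.n_detector)
        if sino_values.shape != expected:
            raise ValueError(f"sinogram shape {sino_values.shape} does not match geometry {expected}")
        out = np.zeros(self.geometry.image_shape)
        for i in range(self.geometry.n_angles):
            self.adjoint_one(sino_values[i], i, out)
        return out

    @property
    def row_norms(self) -> np.ndarray:
        """``b_i W W^T b_i^T`` for every ray, shape ``(n_angles, n_detector)``."""
        if self._row_norms is None:
            g = self.geometry
            n = g.image_size
            buf = np.zeros(n * n)
            norms = np.empty((g.n_angles, g.n_detector))
            for i in range(g.n_angles):
                _kernels.row_norms_angle(
                    self._cos[i], self._sin[i], self._weights,
                    g.n_detector, self.tau_scale, g.pixel_spacing, n, buf, norms[i],
                )
            self._row_norms = np.maximum(norms, ROW_NORM_FLOOR)
        return self._row_norms


def weighted_forward_project(
    image: np.ndarray, geometry: GeometryConfig, profile: SensitivityProfile
) -> Sinogram:
    """Sensitivity-weighted line integrals of ``image`` (the map ``B W x``)."""
    system = WeightedSystem(geometry, profile)
    return Sinogram(system.forward(_check_image(image, geometry)), geometry)


def unweighted_radon(image: np.ndarray, geometry: GeometryConfig) -> Sinogram:
    """Plain Radon transform (the sensitivity-free special case ``S == 1``)."""
    system = WeightedSystem(geometry, None)
    return Sinogram(system.forward(_check_image(image, geometry)), geometry)


def weighted_backproject(
    sinogram: Sinogram, geometry: GeometryConfig, profile: SensitivityProfile
) -> np.ndarray:
    """Exact adjoint ``W^T B^T p`` of :func:`weighted_forward_project`."""
    if sinogram.geometry != geometry:
        raise ValueError("sinogram geometry does not match")
    return WeightedSystem(geometry, profile).adjoint(sinogram.values)


def unweighted_backproject(sino_values: np.ndarray, geometry: GeometryConfig) -> np.ndarray:
    """Adjoint of the plain Radon transform (used by filtered back-projection)."""
    return WeightedSystem(geometry, None).adjoint(sino_values)


def row_norm(theta_index: int, geometry: GeometryConfig, profile: SensitivityProfile) -> np.ndarray:
    """Per-detector-bin normalization ``b_i W W^T b_i^T`` for one angle."""
    if not 0 <= theta_index < geometry.n_angles:
        raise ValueError(f"angle index {theta_index} out of range")
    return WeightedSystem(geometry, profile).row_norms[theta_index]


def add_poisson_noise(
    sinogram: Sinogram, photon_count: float, seed: int, mu_ref: float = 4.0
) -> Sinogram:
    """Simulate photon-counting (Poisson) noise on weighted line integrals.

    The line integrals are mapped to detector counts with a Beer-Lambert-style
    transduction: values are scaled so the maximum corresponds to an
    attenuation of ``mu_ref`` (transmission ``exp(-mu_ref)``), counts are
    drawn as ``Poisson(N0 * exp(-p_norm))`` with blank-scan count ``N0``, and
    the noisy integrals are recovered by the log transform (zero counts are
    clamped to one count).  The relative error per bin shrinks as
    ``1/sqrt(N0 * exp(-p_norm))``.
    """
    if photon_count <= 0:
        raise ValueError(f"photon_count must be positive, got {photon_count}")
    p = sinogram.values
    pmax = float(np.max(np.abs(p)))
    if pmax == 0.0:
        return sinogram.copy()
    scale = mu_ref / pmax
    rng = np.random.default_rng(seed)
    expected = photon_count * np.exp(-p * scale)
    counts = rng.poisson(expected).astype(np.float64)
    noisy = -np.log(np.maximum(counts, 1.0) / photon_count) / scale
    return Sinogram(noisy, sinogram.geometry)
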