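"""Acquisition geometry and the position-dependent interferometer sensitivity.

In a Talbot-Lau interferometer (TLI) the measured phase signal of a voxel is
scaled by a sensitivity factor that depends on the voxel's distance ``r`` from
the phase grating G1.  For an object mounted on a tomographic rotation stage
this turns the usual Radon transform into a *weighted* Radon transform: the
weight of a voxel changes with the rotation angle, because its distance to G1
changes.  This module defines

* :class:`GeometryConfig` -- the parallel-beam scan geometry (angles, detector),
* :class:`SensitivityProfile` -- the sensitivity along the beam axis, both in
  physical form (grating distances ``l``, ``d``, analyzer period ``p2``) and in
  the normalized linear-ramp form used by the simulation experiments,
* the functions mapping either form onto voxel weights.

Conventions
-----------
Images are square 2-D ``float`` arrays indexed ``[row, col]``.  The rotation
center is the geometric center ``((N-1)/2, (N-1)/2)`` of the grid.  The beam
(ray) direction for angle ``theta`` is the unit vector
``(cos(theta), sin(theta))`` in ``(col, row)`` coordinates, i.e. at
``theta = 0`` rays run along image rows and the sensitivity ramp varies along
the column axis.  The ramp is fixed in the laboratory frame along the beam
direction while the object rotates, so a voxel is weighted more strongly at
angles where it sits closer to G1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "GeometryConfig",
    "SensitivityProfile",
    "physical_sensitivity",
    "ramp_weight",
    "weight_map_for_angle",
]


@dataclass(frozen=True)
class GeometryConfig:
    """Parallel-beam scan geometry.

    Parameters
    ----------
    n_angles : int
        Number of projection angles.
    angular_range : float
        Total angular coverage in radians; ``pi`` for a short scan (default)
        or ``2*pi`` for a full scan.
    n_detector : int
        Number of detector bins.
    image_shape : (int, int)
        Reconstruction grid, must be square.
    pixel_spacing, detector_spacing : float
        Physical spacing in mm.
    angle_offset : float
        Angle of the first projection in radians.
    """

    n_angles: int = 400
    angular_range: float = math.pi
    n_detector: int = 400
    image_shape: Tuple[int, int] = (400, 400)
    pixel_spacing: float = 1.0
    detector_spacing: float = 1.0
    angle_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError(f"n_angles must be >= 1, got {self.n_angles}")
        if self.n_detector < 1:
            raise ValueError(f"n_detector must be >= 1, got {self.n_detector}")
        ny, nx = self.image_shape
        if ny != nx or ny < 1:
            raise ValueError(f"image_shape must be square and positive, got {self.image_shape}")
        if self.angular_range <= 0:
            raise ValueError("angular_range must be positive")
        if self.pixel_spacing <= 0 or self.detector_spacing <= 0:
            raise ValueError("spacings must be positive")

    @property
    def image_size(self) -> int:
        return self.image_shape[0]

    @property
    def angles(self) -> np.ndarray:
        """Projection angles, uniformly spaced and endpoint-exclusive."""
        k = np.arange(self.n_angles)
        return self.angle_offset + k * (self.angular_range / self.n_angles)

    def to_dict(self) -> dict:
        return {
            "n_angles": self.n_angles,
            "angular_range": self.angular_range,
            "n_detector": self.n_detector,
            "image_shape": list(self.image_shape),
            "pixel_spacing": self.pixel_spacing,
            "detector_spacing": self.detector_spacing,
            "angle_offset": self.angle_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeometryConfig":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


#: valid object placements relative to the gratings
REGION_G0_G1 = "between_G0_G1"
REGION_G1_G2 = "between_G1_G2"


@dataclass(frozen=True)
class SensitivityProfile:
    """Sensitivity of the interferometer along the beam axis.

    The experiments use the normalized form: a linear ramp from ``s_min`` to
    ``s_max`` over ``extent`` voxels, attaining both endpoints exactly
    (``ramp(0) = s_min``, ``ramp(extent - 1) = s_max``) and clamped to the
    endpoint values outside that range.

    The physical form (:func:`physical_sensitivity`) uses the grating
    distances: ``l`` (G0 to G1), ``d`` (G1 to G2), the analyzer period ``p2``
    and the object region relative to the gratings.
    """

    s_min: float = 0.1
    s_max: float = 0.9
    extent: int = 400
    l: float = field(default=1600.0)  # mm, G0-G1 distance
    d: float = field(default=200.0)  # mm, G1-G2 distance
    p2: float = field(default=0.005)  # mm, analyzer grating period
    region: str = REGION_G0_G1

    def __post_init__(self) -> None:
        if not (0 < self.s_min <= self.s_max):
            raise ValueError(f"need 0 < s_min <= s_max, got {self.s_min}, {self.s_max}")
        if self.extent < 2:
            raise ValueError(f"extent must be >= 2, got {self.extent}")
        if self.region not in (REGION_G0_G1, REGION_G1_G2):
            raise ValueError(f"unknown region {self.region!r}")

    @property
    def iso_center_weight(self) -> float:
        """Sensitivity at the rotation center, ``(s_min + s_max) / 2``."""
        return 0.5 * (self.s_min + self.s_max)

    def ramp(self) -> np.ndarray:
        """The full discrete ramp, shape ``(extent,)``."""
        return ramp_weight(np.arange(self.extent), self)

    def to_dict(self) -> dict:
        return {
            "s_min": self.s_min,
            "s_max": self.s_max,
            "extent": self.extent,
            "l": self.l,
            "d": self.d,
            "p2": self.p2,
            "region": self.region,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensitivityProfile":
        return cls(**d)


def physical_sensitivity(r, profile: SensitivityProfile):
    """Physical sensitivity ``S(r)`` at distance ``r`` (mm) from G1.

    ``S(r) = 2*pi*(d/p2) * (1 + r/l)`` for an object between G0 and G1 and
    ``S(r) = 2*pi*(d/p2) * (1 - r/d)`` for an object between G1 and G2.  In
    the parallel-beam limit ``l -> inf`` the G0-G1 branch becomes constant.
    """
    if profile.l <= 0 or profile.d <= 0 or profile.p2 <= 0:
        raise ValueError("grating distances l, d and period p2 must be positive")
    r = np.asarray(r, dtype=float)
    base = 2.0 * math.pi * profile.d / profile.p2
    if profile.region == REGION_G0_G1:
        out = base * (1.0 + r / profile.l)
    else:
        out = base * (1.0 - r / profile.d)
    return out if out.ndim else float(out)


def ramp_weight(index_along_ray, profile: SensitivityProfile):
    """Normalized sensitivity at a (possibly fractional) ray coordinate.

    Linear from ``s_min`` at index 0 to ``s_max`` at index ``extent - 1``;
    indices outside ``[0, extent - 1]`` are clamped to the nearest endpoint
    (the sensitivity is constant outside the ramp).
    """
    idx = np.clip(np.asarray(index_along_ray, dtype=float), 0.0, profile.extent - 1.0)
    out = profile.s_min + (profile.s_max - profile.s_min) * idx / (profile.extent - 1.0)
    return out if out.ndim else float(out)


def weight_map_for_angle(
    theta: float, geometry: GeometryConfig, profile: SensitivityProfile
) -> np.ndarray:
    """Per-voxel sensitivity weight at rotation angle ``theta``.

    The interferometer is fixed and the object rotates, so in the object frame
    the ramp direction rotates with ``-theta``.  Each voxel's weight is the
    ramp evaluated at the voxel's coordinate along the beam direction
    ``(cos(theta), sin(theta))``, measured from the rotation center and shifted
    so that the center of the ramp coincides with the rotation center.
    """
    n = geometry.image_size
    c = 0.5 * (n - 1)
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    # coordinate along the beam direction, in voxels, relative to the center
    sigma = (cols - c) * math.cos(theta) + (rows - c) * math.sin(theta)
    return np.asarray(ramp_weight(sigma + 0.5 * (profile.extent - 1), profile))
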