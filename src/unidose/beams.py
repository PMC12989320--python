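"""Beam geometry and beam-model physics tables.

Coplanar beams rotate about the z (superior–inferior) grid axis. For gantry
angle theta (degrees), the source sits at

    source = isocenter + SAD * (sin(theta), cos(theta), 0)

so gantry 0 places the source on the +y side of the isocenter. The beam's-eye
view (BEV) plane passes through the isocenter, perpendicular to the central
axis, with in-plane basis u (axial) and v (+z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BeamConfig:
    """Geometry of one static beam."""

    gantry_deg: float
    isocenter_mm: np.ndarray
    sad_mm: float = 1000.0
    couch_deg: float = 0.0  # non-coplanar hook; only 0 is supported

    def __post_init__(self) -> None:
        if not self.sad_mm > 0:
            raise ValueError(f"SAD must be positive, got {self.sad_mm}")
        if self.couch_deg != 0.0:
            raise NotImplementedError("non-coplanar couch angles are not supported")
        self.gantry_deg = float(self.gantry_deg) % 360.0
        self.isocenter_mm = np.asarray(self.isocenter_mm, dtype=float).reshape(3)

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (source, axis e, u_hat, v_hat).

        ``e`` points from source to isocenter; ``u_hat``, ``v_hat`` span the
        isocenter (BEV) plane.
        """
        t = np.deg2rad(self.gantry_deg)
        s_hat = np.array([np.sin(t), np.cos(t), 0.0])
        source = self.isocenter_mm + self.sad_mm * s_hat
        e = -s_hat
        u_hat = np.array([np.cos(t), -np.sin(t), 0.0])
        v_hat = np.array([0.0, 0.0, 1.0])
        return source, e, u_hat, v_hat


@dataclass
class BeamModel:
    """Physics tables shared by all beams of a plan.

    The default percentage-depth-dose (PDD) table is a synthetic 6 MV-like
    curve: linear build-up from the surface to d_max, then exponential decay
    exp(-mu * (d - d_max)). It is a configurable stand-in tabulated at 1 mm
    and linearly interpolated.
    """

    pdd_depth_mm: np.ndarray
    pdd_rel: np.ndarray
    kernel_sigma_mm: float = 3.0
    fluence_pixel_mm: float = 2.0
    inverse_square: bool = True

    def __post_init__(self) -> None:
        self.pdd_depth_mm = np.asarray(self.pdd_depth_mm, dtype=float)
        self.pdd_rel = np.asarray(self.pdd_rel, dtype=float)
        if self.pdd_depth_mm.shape != self.pdd_rel.shape:
            raise ValueError("PDD depth and value tables must have equal length")
        if np.any(self.pdd_rel < 0):
            raise ValueError("PDD values must be non-negative")
        if not self.kernel_sigma_mm > 0:
            raise ValueError("kernel_sigma_mm must be positive")
        if not self.fluence_pixel_mm > 0:
            raise ValueError("fluence_pixel_mm must be positive")

    def pdd(self, depth_mm: np.ndarray) -> np.ndarray:
        """Relative dose at water-equivalent depth (mm), linearly interpolated."""
        return np.interp(depth_mm, self.pdd_depth_mm, self.pdd_rel)

    def to_dict(self) -> dict:
        return {
            "pdd_depth_mm": self.pdd_depth_mm.tolist(),
            "pdd_rel": self.pdd_rel.tolist(),
            "kernel_sigma_mm": self.kernel_sigma_mm,
            "fluence_pixel_mm": self.fluence_pixel_mm,
            "inverse_square": self.inverse_square,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeamModel":
        return cls(
            pdd_depth_mm=np.asarray(d["pdd_depth_mm"], dtype=float),
            pdd_rel=np.asarray(d["pdd_rel"], dtype=float),
            kernel_sigma_mm=float(d.get("kernel_sigma_mm", 3.0)),
            fluence_pixel_mm=float(d.get("fluence_pixel_mm", 2.0)),
            inverse_square=bool(d.get("inverse_square", True)),
        )


def default_beam_model(
    d_max_mm: float = 15.0,
    mu_per_mm: float = 0.005,
    max_depth_mm: float = 400.0,
    **kwargs,
) -> BeamModel:
    """Synthetic 6 MV-like beam model: build-up to d_max, then exponential decay."""
    depths = np.arange(0.0, max_depth_mm + 1.0, 1.0)
    pdd = np.where(
        depths <= d_max_mm,
        depths / d_max_mm,
        np.exp(-mu_per_mm * (depths - d_max_mm)),
    )
    return BeamModel(pdd_depth_mm=depths, pdd_rel=pdd, **kwargs)


@dataclass
class FluenceMap:
    """Non-negative 2D intensity grid at the isocenter plane of one beam.

    ``origin_uv_mm`` is the (u, v) coordinate of the centre of pixel (0, 0).
    """

    values: np.ndarray
    pixel_mm: float
    origin_uv_mm: tuple[float, float] = (0.0, 0.0)
    beam_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("fluence map must be 2D")
        if not self.pixel_mm > 0:
            raise ValueError("pixel_mm must be positive")
        if np.any(self.values < 0):
            raise ValueError("beamlet intensities must be non-negative")

    def like(self, values: np.ndarray) -> "FluenceMap":
        return FluenceMap(values, self.pixel_mm, self.origin_uv_mm, self.beam_index)

    def pixel_centers_uv(self) -> tuple[np.ndarray, np.ndarray]:
        nu, nv = self.values.shape
        u = self.origin_uv_mm[0] + np.arange(nu) * self.pixel_mm
        v = self.origin_uv_mm[1] + np.arange(nv) * self.pixel_mm
        return u, v
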