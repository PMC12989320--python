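"""FCBB-style broad-beam dose engine.

The engine approximates per-beam dose as

    dose(x) = F_conv(u(x), v(x)) * PDD(d_rad(x)) * (SAD / r(x))^2

where ``F_conv`` is the fluence map convolved with a 2D Gaussian penumbra
kernel at the isocenter plane, ``(u, v)`` is the divergent (perspective)
projection of voxel ``x`` onto that plane, ``d_rad`` is the radiological
depth obtained by ray tracing the density from the source, and the last
factor is the optional inverse-square correction with ``r`` the
source-to-voxel distance. Dose is zero outside the body, and the operator is
linear in the fluence, with an explicitly available adjoint for optimization.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .beams import BeamConfig, BeamModel, FluenceMap
from .grid import VolumeGrid
from .structures import CaseBundle

__all__ = [
    "project_to_bev",
    "conformal_aperture",
    "convolve_fluence",
    "radiological_depth",
    "fcbb_beam_dose",
    "total_dose",
    "BeamDoseOperator",
    "CaseDoseOperator",
    "gaussian_kernel_2d",
]


def project_to_bev(points_mm: np.ndarray, beam: BeamConfig) -> np.ndarray:
    """Divergent projection of world points onto the beam's isocenter plane.

    Returns an array of shape (..., 2) with (u, v) coordinates in mm. The
    projection is a perspective through the source onto the plane normal to
    the central axis at the isocenter; the isocenter maps to (0, 0).
    """
    source, e, u_hat, v_hat = beam.basis()
    p = np.asarray(points_mm, dtype=float)
    rel = p - source
    t = rel @ e  # distance along the central axis from the source
    if np.any(np.abs(t) < 1e-9):
        raise ValueError("cannot project a point at the source")
    scale = beam.sad_mm / t
    plane = rel * scale[..., None]  # source-relative position on the BEV plane
    iso_rel = beam.isocenter_mm - source
    off = plane - iso_rel
    return np.stack([off @ u_hat, off @ v_hat], axis=-1)


def gaussian_kernel_2d(sigma_mm: float, pixel_mm: float, truncate: float = 4.0):
    """Discretely normalized 2D Gaussian kernel truncated at ``truncate``·sigma."""
    r = max(1, int(np.ceil(truncate * sigma_mm / pixel_mm)))
    ax = np.arange(-r, r + 1) * pixel_mm
    g1 = np.exp(-0.5 * (ax / sigma_mm) ** 2)
    k = np.outer(g1, g1)
    return k / k.sum()


def convolve_fluence(f: FluenceMap, kernel_sigma_mm: float) -> FluenceMap:
    """Convolve a fluence map with the normalized Gaussian penumbra kernel."""
    k = gaussian_kernel_2d(kernel_sigma_mm, f.pixel_mm)
    out = fftconvolve(f.values, k, mode="same")
    return f.like(np.maximum(out, 0.0))


def _clip_segment_to_grid(
    grid: VolumeGrid, source: np.ndarray, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Clip source->point segments to the grid bounding box.

    Returns (t0, t1, dirs, lengths) with the segment parametrized by distance
    from the source; the box extends half a voxel beyond outer voxel centres.
    """
    lo = grid.origin_mm - 0.5 * grid.spacing_mm
    hi = grid.origin_mm + (np.asarray(grid.shape) - 0.5) * grid.spacing_mm
    rel = points - source
    length = np.linalg.norm(rel, axis=-1)
    dirs = rel / np.maximum(length, 1e-12)[..., None]
    t0 = np.zeros_like(length)
    t1 = length.copy()
    for ax in range(3):
        d = dirs[..., ax]
        s = source[ax]
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = (lo[ax] - s) / d
            tb = (hi[ax] - s) / d
        near = np.minimum(ta, tb)
        far = np.maximum(ta, tb)
        parallel = np.abs(d) < 1e-12
        inside = (s >= lo[ax]) & (s <= hi[ax])
        near = np.where(parallel, np.where(inside, -np.inf, np.inf), near)
        far = np.where(parallel, np.where(inside, np.inf, -np.inf), far)
        t0 = np.maximum(t0, near)
        t1 = np.minimum(t1, far)
    return t0, t1, dirs, length


def radiological_depth(
    density: VolumeGrid,
    source_mm: np.ndarray,
    points_mm: np.ndarray,
    step_mm: float | None = None,
) -> np.ndarray:
    """Water-equivalent depth: line integral of density from source to points.

    Vectorized over points (shape (N, 3) or (3,)). Points must lie inside the
    grid bounding box. Density is sampled trilinearly at a fixed step along
    each clipped ray segment (midpoint rule), so a uniform density of 1 over a
    geometric path of length L yields a depth of L.
    """
    source = np.asarray(source_mm, dtype=float).reshape(3)
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    lo = density.origin_mm - 0.5 * density.spacing_mm
    hi = density.origin_mm + (np.asarray(density.shape) - 0.5) * density.spacing_mm
    if np.any(pts < lo - 1e-9) or np.any(pts > hi + 1e-9):
        raise ValueError("point outside the density grid")
    if step_mm is None:
        step_mm = density.spacing_mm
    t0, t1, dirs, _ = _clip_segment_to_grid(density, source, pts)
    seg = np.maximum(t1 - t0, 0.0)
    n_steps = max(1, int(np.ceil(seg.max() / step_mm))) if seg.max() > 0 else 1
    h = seg / n_steps
    depth = np.zeros(len(pts))
    for k in range(n_steps):
        t = t0 + (k + 0.5) * h
        sample_pts = source + dirs * t[:, None]
        idx = density.index_coords(sample_pts)
        vals = ndimage.map_coordinates(
            density.values, idx.T, order=1, mode="nearest"
        )
        depth += vals * h
    out = depth
    if np.asarray(points_mm).ndim == 1:
        return out[0]
    return out


def conformal_aperture(
    ptv: VolumeGrid,
    beam: BeamConfig,
    margin_mm: float = 5.0,
    pixel_mm: float = 2.0,
    pad_mm: float = 14.0,
) -> FluenceMap:
    """Binary unit-fluence aperture conformal to the PTV in the beam's-eye view.

    Each fluence pixel is switched on when the divergent ray from the source
    through the pixel centre intersects the PTV mask; the resulting projection
    is then morphologically dilated by a disk of radius ``margin_mm``. The map
    is padded by ``pad_mm`` beyond the dilated aperture so that subsequent
    penumbra convolution does not clip kernel mass.
    """
    mask = ptv.values > 0.5
    if not mask.any():
        raise ValueError("empty PTV: cannot build a conformal aperture")
    vox = np.argwhere(mask)
    pts = ptv.world_coords(vox)
    uv = project_to_bev(pts, beam)
    pad = margin_mm + pad_mm
    u_lo = np.floor((uv[:, 0].min() - pad) / pixel_mm) * pixel_mm
    v_lo = np.floor((uv[:, 1].min() - pad) / pixel_mm) * pixel_mm
    nu = int(np.ceil((uv[:, 0].max() + pad - u_lo) / pixel_mm)) + 1
    nv = int(np.ceil((uv[:, 1].max() + pad - v_lo) / pixel_mm)) + 1

    source, e, u_hat, v_hat = beam.basis()
    u = u_lo + np.arange(nu) * pixel_mm
    v = v_lo + np.arange(nv) * pixel_mm
    uu, vv = np.meshgrid(u, v, indexing="ij")
    plane_pts = (
        beam.isocenter_mm
        + uu[..., None] * u_hat
        + vv[..., None] * v_hat
    )
    dirs = plane_pts - source
    dist = np.linalg.norm(dirs, axis=-1)
    dirs = dirs / dist[..., None]
    # sample along each ray over the slab containing the PTV bounding sphere
    radius = np.linalg.norm(pts - beam.isocenter_mm, axis=1).max() + ptv.spacing_mm
    t_near = beam.sad_mm - radius
    t_far = beam.sad_mm + radius
    step = ptv.spacing_mm / 2.0
    n_steps = max(2, int(np.ceil((t_far - t_near) / step)))
    hit = np.zeros(uu.shape, dtype=bool)
    fmask = mask.astype(np.float64)
    for k in range(n_steps):
        t = t_near + (k + 0.5) * (t_far - t_near) / n_steps
        sample = source + dirs * t
        idx = ptv.index_coords(sample.reshape(-1, 3))
        vals = ndimage.map_coordinates(
            fmask, idx.T, order=1, mode="constant", cval=0.0
        )
        hit |= vals.reshape(uu.shape) >= 0.5
    if margin_mm > 0:
        r_px = margin_mm / pixel_mm
        span = int(np.floor(r_px + 1e-9))
        ax = np.arange(-span, span + 1)
        disk = (ax[:, None] ** 2 + ax[None, :] ** 2) <= r_px**2 + 1e-9
        hit = ndimage.binary_dilation(hit, structure=disk)
    return FluenceMap(hit.astype(np.float64), pixel_mm, (u_lo, v_lo))


def _bilinear_weights(gx, gy, shape):
    """Corner indices/weights of bilinear interpolation, zero outside the grid."""
    nu, nv = shape
    i0 = np.floor(gx).astype(np.int64)
    j0 = np.floor(gy).astype(np.int64)
    fx = gx - i0
    fy = gy - j0
    out = []
    for di, wi in ((0, 1.0 - fx), (1, fx)):
        for dj, wj in ((0, 1.0 - fy), (1, fy)):
            i = i0 + di
            j = j0 + dj
            valid = (i >= 0) & (i < nu) & (j >= 0) & (j < nv)
            w = wi * wj * valid
            out.append((np.clip(i, 0, nu - 1), np.clip(j, 0, nv - 1), w))
    return out


class BeamDoseOperator:
    """Linear fluence->dose map for one beam, with its exact adjoint.

    Geometry-dependent factors (projection coordinates, radiological depth,
    PDD, inverse-square) are precomputed for all body voxels; applying the
    operator is then a convolution, a bilinear interpolation and a scaling.
    The adjoint runs the same steps backwards (bilinear splat, symmetric
    kernel correlation).
    """

    def __init__(
        self,
        body: VolumeGrid,
        density: VolumeGrid,
        beam: BeamConfig,
        model: BeamModel,
        fluence_template: FluenceMap,
    ):
        self.body = body
        self.beam = beam
        self.model = model
        self.template = fluence_template
        self.kernel = gaussian_kernel_2d(
            model.kernel_sigma_mm, fluence_template.pixel_mm
        )
        mask = body.values > 0.5
        self.voxel_idx = np.argwhere(mask)
        pts = body.world_coords(self.voxel_idx)
        uv = project_to_bev(pts, beam)
        self.gx = (uv[:, 0] - fluence_template.origin_uv_mm[0]) / fluence_template.pixel_mm
        self.gy = (uv[:, 1] - fluence_template.origin_uv_mm[1]) / fluence_template.pixel_mm
        self._corners = _bilinear_weights(self.gx, self.gy, fluence_template.values.shape)
        source, _, _, _ = beam.basis()
        depth = radiological_depth(density, source, pts)
        w = model.pdd(depth)
        if model.inverse_square:
            r = np.linalg.norm(pts - source, axis=1)
            w = w * (beam.sad_mm / r) ** 2
        self.w = w

    def apply_values(self, fluence_values: np.ndarray) -> np.ndarray:
        """Dose at body voxels (flat array) for fluence values on the template."""
        fc = fftconvolve(fluence_values, self.kernel, mode="same")
        s = np.zeros(len(self.w))
        for i, j, wgt in self._corners:
            s += wgt * fc[i, j]
        return s * self.w

    def adjoint_values(self, dose_values: np.ndarray) -> np.ndarray:
        """Adjoint: dose at body voxels -> gradient on the fluence template."""
        d = dose_values * self.w
        g = np.zeros(self.template.values.shape)
        for i, j, wgt in self._corners:
            np.add.at(g, (i, j), wgt * d)
        return fftconvolve(g, self.kernel, mode="same")

    def dose_volume(self, fluence_values: np.ndarray) -> VolumeGrid:
        out = np.zeros(self.body.shape)
        # FFT convolution leaves O(1e-16) negative noise on a physically
        # non-negative dose; clamp at assembly
        out[tuple(self.voxel_idx.T)] = np.maximum(
            self.apply_values(fluence_values), 0.0
        )
        return self.body.like(out)


class CaseDoseOperator:
    """Linear operator summing per-beam FCBB doses over a case's beams."""

    def __init__(
        self,
        case: CaseBundle,
        fluence_templates: list[FluenceMap],
        density: VolumeGrid | None = None,
    ):
        if len(fluence_templates) != len(case.beams):
            raise ValueError("one fluence template per beam is required")
        if density is None:
            density = case.structures.body
        self.case = case
        self.body = case.structures.body
        self.voxel_idx = np.argwhere(self.body.values > 0.5)
        self.beam_ops = [
            BeamDoseOperator(self.body, density, beam, case.beam_model, tmpl)
            for beam, tmpl in zip(case.beams, fluence_templates)
        ]

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_idx)

    def apply_values(self, fluences: list[np.ndarray]) -> np.ndarray:
        if len(fluences) != len(self.beam_ops):
            raise ValueError("fluence/beam count mismatch")
        out = np.zeros(self.n_voxels)
        for op, f in zip(self.beam_ops, fluences):
            out += op.apply_values(f)
        return out

    def adjoint_values(self, dose_values: np.ndarray) -> list[np.ndarray]:
        return [op.adjoint_values(dose_values) for op in self.beam_ops]

    def dose_volume(self, fluences: list[np.ndarray]) -> VolumeGrid:
        out = np.zeros(self.body.shape)
        out[tuple(self.voxel_idx.T)] = np.maximum(self.apply_values(fluences), 0.0)
        return self.body.like(out)


def fcbb_beam_dose(
    case: CaseBundle,
    beam: BeamConfig,
    fluence: FluenceMap,
    model: BeamModel | None = None,
    density: VolumeGrid | None = None,
) -> VolumeGrid:
    """Single-beam FCBB dose (relative units) for a given fluence map."""
    model = model or case.beam_model
    density = density if density is not None else case.structures.body
    op = BeamDoseOperator(case.structures.body, density, beam, model, fluence)
    return op.dose_volume(fluence.values)


def total_dose(case: CaseBundle, fluences: list[FluenceMap]) -> VolumeGrid:
    """Sum of per-beam FCBB doses; linear in the fluences."""
    op = CaseDoseOperator(case, fluences)
    return op.dose_volume([f.values for f in fluences])
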