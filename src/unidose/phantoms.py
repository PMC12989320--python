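"""Seeded synthetic phantom and cohort generation.

The generator emulates the heterogeneity of a real IMRT planning cohort on a
desk-scale grid (default 64^3 at 2 mm): a convex ellipsoidal body, one or two
nested targets (single prescription or simultaneous integrated boost),
1-3 organs at risk near or overlapping the target, 5-25 coplanar beams at
equispaced or arbitrary gantry angles, and prescriptions spanning 4-79.2 Gy.
Density is binary (1 inside the body, 0 outside), consistent with a no-CT
input design. "Clinical-like" label doses are produced by objective-based
fluence optimization through the same FCBB engine (:func:`make_label_dose`).

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .beams import BeamConfig, default_beam_model
from .fmo import FMOResult, ObjectiveConfig, optimize_planning
from .grid import VolumeGrid
from .io import write_case
from .structures import OAR, CaseBundle, StructureSet, Target


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case (or a cohort template)."""

    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 2.0
    body_semiaxes_range_mm: tuple[tuple[float, float], ...] = (
        (42.0, 56.0),
        (42.0, 56.0),
        (48.0, 60.0),
    )
    target_radius_range_mm: tuple[float, float] = (8.0, 20.0)
    prescription_range_gy: tuple[float, float] = (4.0, 79.2)
    p_sib: float = 0.3
    sib_ratio_range: tuple[float, float] = (0.75, 0.9)
    n_oars_range: tuple[int, int] = (1, 3)
    oar_radius_range_mm: tuple[float, float] = (6.0, 14.0)
    p_oar_overlap: float = 0.2
    n_beams_range: tuple[int, int] = (5, 25)
    angle_mode: str = "random"  # 'equispaced' | 'random'
    sad_mm: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_beams_range[0] < 1:
            raise ValueError("n_beams must be >= 1")
        if self.angle_mode not in ("equispaced", "random"):
            raise ValueError(f"unknown angle_mode {self.angle_mode!r}")
        lo, hi = self.prescription_range_gy
        if not 0 < lo <= hi:
            raise ValueError("invalid prescription range")


def _ellipsoid(grid: VolumeGrid, center_mm, semiaxes_mm) -> np.ndarray:
    pts = grid.voxel_centers()
    rel = (pts - np.asarray(center_mm)) / np.asarray(semiaxes_mm)
    return np.sum(rel**2, axis=-1) <= 1.0


def _cylinder(grid: VolumeGrid, center_mm, radius_mm, half_height_mm) -> np.ndarray:
    pts = grid.voxel_centers()
    rel = pts - np.asarray(center_mm)
    return (rel[..., 0] ** 2 + rel[..., 1] ** 2 <= radius_mm**2) & (
        np.abs(rel[..., 2]) <= half_height_mm
    )


def generate_phantom(spec: PhantomSpec) -> CaseBundle:
    """Generate one case (masks, beams, beam model) without a label dose."""
    rng = np.random.default_rng(spec.seed)
    grid = VolumeGrid(
        np.zeros(spec.grid_shape), spec.spacing_mm, origin_mm=np.zeros(3)
    )
    center = grid.center_mm()
    half_extent = (np.asarray(spec.grid_shape) - 1) / 2.0 * spec.spacing_mm

    semi = np.array([rng.uniform(lo, hi) for lo, hi in spec.body_semiaxes_range_mm])
    semi = np.minimum(semi, half_extent - spec.spacing_mm)
    body = _ellipsoid(grid, center, semi)

    r_t = rng.uniform(*spec.target_radius_range_mm)
    if r_t >= semi.min():
        raise ValueError("target larger than body")
    max_off = np.maximum(0.35 * (semi - r_t), 0.0)
    offset = rng.uniform(-1, 1, 3) * max_off
    t_center = center + offset
    primary = _ellipsoid(grid, t_center, np.full(3, r_t))
    if not primary.any():
        raise ValueError("target mask is empty on this grid")
    if np.any(primary & ~body):
        raise ValueError("target larger than body")

    rx_hi = rng.uniform(*spec.prescription_range_gy)
    targets: list[Target] = []
    if rng.uniform() < spec.p_sib and r_t >= 2.5 * spec.spacing_mm:
        ratio = rng.uniform(*spec.sib_ratio_range)
        boost = _ellipsoid(grid, t_center, np.full(3, 0.5 * r_t))
        targets.append(Target("ptv", grid.like(primary.astype(float)), ratio * rx_hi))
        targets.append(Target("ptv_boost", grid.like(boost.astype(float)), rx_hi))
    else:
        targets.append(Target("ptv", grid.like(primary.astype(float)), rx_hi))

    oars: list[OAR] = []
    n_oars = int(rng.integers(spec.n_oars_range[0], spec.n_oars_range[1] + 1))
    for i in range(n_oars):
        r_o = rng.uniform(*spec.oar_radius_range_mm)
        overlap = rng.uniform() < spec.p_oar_overlap
        placed = None
        for _ in range(50):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            if overlap:
                dist = (r_t + r_o) * rng.uniform(0.5, 0.9)
            else:
                dist = (r_t + r_o) * rng.uniform(1.05, 1.6)
            c_o = t_center + direction * dist
            if rng.uniform() < 0.5:
                m = _ellipsoid(grid, c_o, np.full(3, r_o))
            else:
                m = _cylinder(grid, c_o, 0.8 * r_o, r_o)
            m = m & body
            if not m.any():
                continue
            if not overlap and np.any(m & primary):
                continue
            placed = m
            break
        if placed is None:
            raise ValueError(
                f"OAR {i} placement impossible without overlap for seed {spec.seed}"
            )
        oars.append(OAR(f"oar_{i}", grid.like(placed.astype(float)), 1.0))

    n_beams = int(rng.integers(spec.n_beams_range[0], spec.n_beams_range[1] + 1))
    if spec.angle_mode == "equispaced":
        angles = np.arange(n_beams) * 360.0 / n_beams
    else:
        angles = np.sort(rng.uniform(0.0, 360.0, n_beams))
    iso = grid.world_coords(np.argwhere(primary)).mean(axis=0)
    beams = [
        BeamConfig(gantry_deg=a, isocenter_mm=iso, sad_mm=spec.sad_mm) for a in angles
    ]
    structures = StructureSet(
        body=grid.like(body.astype(float)), targets=targets, oars=oars
    )
    return CaseBundle(
        structures=structures,
        beams=beams,
        beam_model=default_beam_model(),
        case_id=f"phantom_{spec.seed}",
    )


def make_label_dose(
    case: CaseBundle,
    planning_weights: ObjectiveConfig | None = None,
    beamlet_mm: float = 5.0,
) -> tuple[VolumeGrid, FMOResult]:
    """Synthesize a 'clinical-like' label dose by objective-based FMO."""
    obj = planning_weights or ObjectiveConfig(max_iter=200, tol=1e-5)
    res = optimize_planning(case, obj, beamlet_mm=beamlet_mm)
    if np.any(res.dose.values < 0):
        raise RuntimeError("optimizer produced negative dose")
    return res.dose, res


def mask_hash(case: CaseBundle) -> str:
    """Stable content hash of all masks and beam angles (cohort uniqueness)."""
    h = hashlib.sha256()
    h.update(case.structures.body.values.tobytes())
    for t in case.structures.targets:
        h.update(t.mask.values.tobytes())
    for o in case.structures.oars:
        h.update(o.mask.values.tobytes())
    h.update(np.asarray([b.gantry_deg for b in case.beams]).tobytes())
    return h.hexdigest()


def split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Train/val/test counts: floors of the stated fractions, remainder to
    test, with at least one training case."""
    n_train = max(1, int(np.floor(n * fractions[0])))
    n_val = int(np.floor(n * fractions[1]))
    n_val = min(n_val, n - n_train)
    n_test = n - n_train - n_val
    return n_train, n_val, n_test


def generate_cohort(
    n: int,
    spec_template: PhantomSpec,
    seed: int,
    out_dir: str | Path,
    split: tuple[float, float, float] = (0.7, 0.15, 0.15),
    with_labels: bool = True,
    label_obj: ObjectiveConfig | None = None,
) -> dict:
    """Generate ``n`` cases on disk with per-case derived seeds and a manifest.

    The manifest lists case directories and the train/val/test split.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=n)
    case_dirs = []
    for i, s in enumerate(case_seeds):
        spec = replace(spec_template, seed=int(s))
        case = generate_phantom(spec)
        case.case_id = f"case_{i:04d}"
        if with_labels:
            dose, _ = make_label_dose(case, planning_weights=label_obj)
            case.label_dose = dose
        d = write_case(case, out_dir / case.case_id)
        case_dirs.append(d.name)
    n_train, n_val, n_test = split_counts(n, split)
    manifest = {
        "seed": int(seed),
        "n": n,
        "cases": case_dirs,
        "train": case_dirs[:n_train],
        "val": case_dirs[n_train : n_train + n_val],
        "test": case_dirs[n_train + n_val :],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
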