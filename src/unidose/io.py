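"""Volume and plan I/O.

Volumes (masks, channels, doses) are stored as NIfTI (``.nii`` / ``.nii.gz``)
with the isotropic spacing and origin encoded in the affine. Plans are one
JSON document per case::

    {
      "case_id": "case_0001",
      "sad_mm": 1000.0,
      "isocenter_mm": [x, y, z],
      "gantry_deg": [0, 40, ...],
      "prescriptions_gy": {"ptv": 60.0, "ptv_boost": 70.0},
      "oar_weights": {"oar_0": 1.0},
      "beam_model": {...}            # optional; default model if absent
    }

Structure masks live next to the plan as ``body.nii.gz``, ``<target>.nii.gz``
and ``<oar>.nii.gz``; the label dose, when present, is ``label_dose.nii.gz``.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from pathlib import Path

import nibabel as nib
import numpy as np

from .beams import BeamConfig, BeamModel, default_beam_model
from .grid import VolumeGrid, resample_isotropic
from .structures import OAR, CaseBundle, StructureSet, Target

logger = logging.getLogger("unidose")


@contextmanager
def log_stage(case_id: str, stage: str):
    """Structured per-stage log line: case id, stage, wall time."""
    t0 = time.perf_counter()
    try:
        yield
    finally:
        logger.info(
            "case=%s stage=%s wall_s=%.3f", case_id, stage, time.perf_counter() - t0
        )


def write_volume(v: VolumeGrid, path: str | Path) -> None:
    affine = np.diag([v.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = v.origin_mm
    img = nib.Nifti1Image(v.values.astype(np.float64), affine)
    nib.save(img, str(path))


def read_volume(
    path: str | Path, resample_to_mm: float | None = None, mode: str = "linear"
) -> VolumeGrid:
    """Read a 3D raster volume; optionally resample to an isotropic grid.

    Raises on missing files, non-3D data, and anisotropic voxels unless
    ``resample_to_mm`` is given (in which case the volume is resampled axis by
    axis to the requested isotropic spacing).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D data in {path.name}")
    affine = np.asarray(img.affine, dtype=float)
    spacings = np.linalg.norm(affine[:3, :3], axis=0)
    origin = affine[:3, 3]
    if np.ptp(spacings) > 1e-6 * max(spacings.max(), 1.0):
        if resample_to_mm is None:
            raise ValueError(
                f"anisotropic spacing {spacings} in {path.name}; "
                "pass resample_to_mm to resample"
            )
        data = _resample_anisotropic(data, spacings, resample_to_mm, mode)
        return VolumeGrid(data, resample_to_mm, origin)
    v = VolumeGrid(data, float(spacings[0]), origin)
    if resample_to_mm is not None:
        v = resample_isotropic(v, resample_to_mm, mode=mode)
    return v


def _resample_anisotropic(
    data: np.ndarray, spacings: np.ndarray, target_mm: float, mode: str
) -> np.ndarray:
    from scipy import ndimage

    new_shape = tuple(
        max(1, int(np.ceil(n * s / target_mm))) for n, s in zip(data.shape, spacings)
    )
    axes = [
        np.arange(n) * target_mm / s for n, s in zip(new_shape, spacings)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    order = 0 if mode == "nearest" else 1
    return ndimage.map_coordinates(data, np.stack(mesh), order=order, mode="nearest")


# ---------------------------------------------------------------------------
# plans


def write_plan(case: CaseBundle, path: str | Path) -> None:
    doc = {
        "case_id": case.case_id,
        "sad_mm": case.beams[0].sad_mm,
        "isocenter_mm": case.beams[0].isocenter_mm.tolist(),
        "gantry_deg": [b.gantry_deg for b in case.beams],
        "prescriptions_gy": {t.name: t.prescription_gy for t in case.structures.targets},
        "oar_weights": {o.name: o.weight for o in case.structures.oars},
        "beam_model": case.beam_model.to_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_plan(path: str | Path) -> dict:
    """Read and validate a plan document.

    Returns a dict with ``beams`` (list of BeamConfig, angles normalized to
    [0, 360)), ``prescriptions_gy``, ``oar_weights`` and ``beam_model``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    doc = json.loads(path.read_text())
    for key in ("sad_mm", "isocenter_mm", "gantry_deg", "prescriptions_gy"):
        if key not in doc:
            raise ValueError(f"plan file missing required key {key!r}")
    sad = float(doc["sad_mm"])
    if not sad > 0:
        raise ValueError(f"SAD must be positive, got {sad}")
    angles = [float(a) for a in doc["gantry_deg"]]
    if not angles:
        raise ValueError("plan must define at least one beam")
    for a in angles:
        if not np.isfinite(a):
            raise ValueError(f"gantry angle out of numeric range: {a}")
    iso = np.asarray(doc["isocenter_mm"], dtype=float)
    beams = [BeamConfig(gantry_deg=a, isocenter_mm=iso, sad_mm=sad) for a in angles]
    model = (
        BeamModel.from_dict(doc["beam_model"])
        if "beam_model" in doc
        else default_beam_model()
    )
    return {
        "case_id": doc.get("case_id", path.parent.name),
        "beams": beams,
        "prescriptions_gy": {k: float(v) for k, v in doc["prescriptions_gy"].items()},
        "oar_weights": {k: float(v) for k, v in doc.get("oar_weights", {}).items()},
        "beam_model": model,
    }


# ---------------------------------------------------------------------------
# case directories


def write_case(case: CaseBundle, case_dir: str | Path) -> Path:
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    write_volume(case.structures.body, case_dir / "body.nii.gz")
    for t in case.structures.targets:
        write_volume(t.mask, case_dir / f"{t.name}.nii.gz")
    for o in case.structures.oars:
        write_volume(o.mask, case_dir / f"{o.name}.nii.gz")
    if case.label_dose is not None:
        write_volume(case.label_dose, case_dir / "label_dose.nii.gz")
    write_plan(case, case_dir / "plan.json")
    return case_dir


def read_case(case_dir: str | Path) -> CaseBundle:
    """Load a case directory written by :func:`write_case`.

    All volumes are checked against the shared-grid invariant.
    """
    case_dir = Path(case_dir)
    plan = read_plan(case_dir / "plan.json")
    body = read_volume(case_dir / "body.nii.gz")
    targets = [
        Target(name, read_volume(case_dir / f"{name}.nii.gz"), rx)
        for name, rx in plan["prescriptions_gy"].items()
    ]
    oars = [
        OAR(name, read_volume(case_dir / f"{name}.nii.gz"), w)
        for name, w in plan["oar_weights"].items()
    ]
    for v in [t.mask for t in targets] + [o.mask for o in oars]:
        if not v.same_grid(body):
            raise ValueError(f"case {case_dir.name}: volumes not on a shared grid")
    label_path = case_dir / "label_dose.nii.gz"
    label = read_volume(label_path) if label_path.exists() else None
    structures = StructureSet(body=body, targets=targets, oars=oars)
    return CaseBundle(
        structures=structures,
        beams=plan["beams"],
        beam_model=plan["beam_model"],
        label_dose=label,
        case_id=plan["case_id"],
    )
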