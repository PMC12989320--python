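"""The three generalized input channels: prescription, avoidance, beam trace.

* prescription — per-voxel prescribed dose of the highest-dose target covering
  the voxel, normalized to the maximum prescribed dose (dp_max). A single-
  prescription plan yields a binary PTV mask; SIB plans yield discrete levels
  equal to the prescription ratios.
* avoidance — a single weighted mask consolidating all OARs and the body:
  OAR voxels carry their avoidance weight (default 1), body voxels 0.1,
  everything else 0. Target/OAR overlaps are resolved by ``overlap_policy``.
* beam trace — non-modulated cumulative dose: per beam, a conformal aperture
  (5 mm margin) with unit fluence is pushed through the FCBB engine, each
  per-beam dose is normalized to its own maximum, and the sum is divided by
  the number of beams, so overlapping beams peak near 1 at the target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .engine import conformal_aperture, fcbb_beam_dose
from .grid import VolumeGrid
from .structures import CaseBundle, StructureSet

BODY_WEIGHT = 0.1
DEFAULT_APERTURE_MARGIN_MM = 5.0


@dataclass
class ChannelStack:
    """The three aligned input channels plus the dose normalization constant."""

    prescription: VolumeGrid
    avoidance: VolumeGrid
    beam_trace: VolumeGrid
    dp_max_gy: float

    def __post_init__(self) -> None:
        if not (
            self.prescription.same_grid(self.avoidance)
            and self.prescription.same_grid(self.beam_trace)
        ):
            raise ValueError("channels must share the canonical grid")
        if not self.dp_max_gy > 0:
            raise ValueError("dp_max must be positive")

    def as_array(self) -> np.ndarray:
        """Channel-last stack, shape (nx, ny, nz, 3)."""
        return np.stack(
            [self.prescription.values, self.avoidance.values, self.beam_trace.values],
            axis=-1,
        )


def encode_prescription(structures: StructureSet) -> tuple[VolumeGrid, float]:
    """Normalized prescription channel and dp_max (Gy).

    Each voxel takes the prescription of the highest-dose target covering it,
    divided by the maximum prescribed dose; voxels outside all targets are 0.
    """
    dp_max = structures.max_prescription_gy
    out = np.zeros(structures.body.shape)
    for t in sorted(structures.targets, key=lambda t: t.prescription_gy):
        m = t.mask.values > 0.5
        out[m] = t.prescription_gy / dp_max
    return structures.body.like(out), dp_max


def encode_avoidance(
    structures: StructureSet,
    weights: dict[str, float] | None = None,
    body_weight: float = BODY_WEIGHT,
    overlap_policy: str = "target_priority",
    target_value: str = "body",
) -> VolumeGrid:
    """Weighted avoidance mask: OARs -> weight (default 1), body -> 0.1, else 0.

    Overlapping OARs take the maximum weight. Voxels in both a target and an
    OAR are resolved by ``overlap_policy``: ``'target_priority'`` removes them
    from the avoidance set (they fall back to the body value, prioritizing
    coverage), ``'oar_priority'`` keeps the OAR weight — the patient-specific
    adjustment that relabels the overlap as OAR. ``target_value`` selects what
    plain target voxels carry under target_priority: ``'body'`` (0.1, targets
    are inside the body) or ``'zero'``.
    """
    if overlap_policy not in ("target_priority", "oar_priority"):
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    if target_value not in ("body", "zero"):
        raise ValueError(f"unknown target_value {target_value!r}")
    body = structures.body.values > 0.5
    out = np.where(body, body_weight, 0.0)
    target_union = structures.target_union()
    if target_value == "zero":
        out[target_union] = 0.0
    oar_weight = np.zeros(structures.body.shape)
    for o in structures.oars:
        m = o.mask.values > 0.5
        if np.any(m & ~body):
            warnings.warn(
                f"OAR {o.name!r} extends outside the body; clipping", stacklevel=2
            )
            m = m & body
        w = o.weight if weights is None else weights.get(o.name, o.weight)
        oar_weight[m] = np.maximum(oar_weight[m], w)
    in_oar = oar_weight > 0
    if overlap_policy == "target_priority":
        in_oar = in_oar & ~target_union
    out[in_oar] = oar_weight[in_oar]
    return structures.body.like(out)


def encode_beam_trace(
    case: CaseBundle,
    margin_mm: float = DEFAULT_APERTURE_MARGIN_MM,
    pixel_mm: float | None = None,
) -> VolumeGrid:
    """Summed, beam-count-normalized per-beam unit-fluence doses.

    For each beam a conformal aperture around the union of the target masks
    (``margin_mm`` isotropic margin) is filled with unit fluence, convolved
    with the penumbra kernel and pushed through the FCBB engine; the per-beam
    dose is divided by its own maximum before the sum is divided by the number
    of beams, making the map's peak value typically close to 1 and the map
    invariant to duplicating beams.
    """
    structures = case.structures
    union = structures.body.like(structures.target_union().astype(float))
    pixel = pixel_mm if pixel_mm is not None else case.beam_model.fluence_pixel_mm
    acc = np.zeros(structures.body.shape)
    n = len(case.beams)
    # identical beams are computed once and carry their multiplicity, so
    # duplicating every beam leaves the map bit-identical
    groups: dict[tuple, list] = {}
    for beam in case.beams:
        groups.setdefault((beam.gantry_deg, beam.couch_deg), []).append(beam)
    for beams in groups.values():
        beam = beams[0]
        ap = conformal_aperture(union, beam, margin_mm=margin_mm, pixel_mm=pixel)
        d = fcbb_beam_dose(case, beam, ap).values
        peak = d.max()
        if peak > 0:
            acc += d * (len(beams) / n / peak)
    return structures.body.like(acc)


def build_channel_stack(case: CaseBundle, **avoidance_kwargs) -> ChannelStack:
    """All three channels on the shared grid, plus dp_max."""
    prescription, dp_max = encode_prescription(case.structures)
    avoidance = encode_avoidance(case.structures, **avoidance_kwargs)
    beam_trace = encode_beam_trace(case)
    return ChannelStack(prescription, avoidance, beam_trace, dp_max)
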