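"""Structure sets and case bundles.

A :class:`StructureSet` carries the body contour, the prescription targets
(PTVs, possibly nested for simultaneous integrated boost) and the organs at
risk with their avoidance weights. A :class:`CaseBundle` is one complete
plannable case: structures + beam geometry + beam model, optionally with a
reference ("label") dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beams import BeamConfig, BeamModel
from .grid import VolumeGrid


@dataclass
class Target:
    name: str
    mask: VolumeGrid
    prescription_gy: float

    def __post_init__(self) -> None:
        if not self.prescription_gy > 0:
            raise ValueError(
                f"prescription must be positive, got {self.prescription_gy}"
            )


@dataclass
class OAR:
    name: str
    mask: VolumeGrid
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"OAR weight must be in [0, 1], got {self.weight}")


@dataclass
class StructureSet:
    body: VolumeGrid
    targets: list[Target]
    oars: list[OAR] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("structure set must contain at least one target")
        body = self.body.values > 0.5
        if not body.any():
            raise ValueError("body mask is empty")
        for t in self.targets:
            if not t.mask.same_grid(self.body):
                raise ValueError(f"target {t.name!r} is not on the body grid")
            m = t.mask.values > 0.5
            if not m.any():
                raise ValueError(f"target {t.name!r} has an empty mask")
            if np.any(m & ~body):
                raise ValueError(f"target {t.name!r} extends outside the body")
        for o in self.oars:
            if not o.mask.same_grid(self.body):
                raise ValueError(f"OAR {o.name!r} is not on the body grid")

    @property
    def max_prescription_gy(self) -> float:
        """The maximum prescribed dose (normalisation constant dp_max)."""
        return max(t.prescription_gy for t in self.targets)

    def target_union(self) -> np.ndarray:
        """Boolean union of all target masks."""
        out = np.zeros(self.body.shape, dtype=bool)
        for t in self.targets:
            out |= t.mask.values > 0.5
        return out


@dataclass
class CaseBundle:
    structures: StructureSet
    beams: list[BeamConfig]
    beam_model: BeamModel
    label_dose: VolumeGrid | None = None
    case_id: str = "case"

    def __post_init__(self) -> None:
        if not self.beams:
            raise ValueError("case must have at least one beam")
        iso0 = self.beams[0].isocenter_mm
        sad0 = self.beams[0].sad_mm
        for b in self.beams[1:]:
            if not np.allclose(b.isocenter_mm, iso0) or b.sad_mm != sad0:
                raise ValueError("all beams must share isocenter and SAD")
        if self.label_dose is not None and not self.label_dose.same_grid(
            self.structures.body
        ):
            raise ValueError("label dose is not on the case grid")

    @property
    def grid(self) -> VolumeGrid:
        return self.structures.body
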