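"""Fluence-map optimization (FMO).

Two modes share one projected-gradient solver over the linear FCBB dose
operator, with non-negative beamlet intensities:

* planning mode — one-sided quadratic objectives (target under/overdose, OAR
  and body overdose above configurable limits) synthesize a "clinical-like"
  label dose for a case;
* reference-guided mode — a feasibility probe: one-sided penalties pull the
  achievable dose toward a reference (e.g., a network prediction), penalizing
  underdose below the reference on its support and overdose above it
  everywhere, so the optimum reproduces any reference that the engine itself
  can generate.

The solver is deterministic (zero-fluence init, Barzilai–Borwein step with
monotone backtracking) and exposes the objective trace for convergence
checks. Beamlets live on per-beam conformal apertures at a configurable
resolution (default 5 mm, coarser than the 2 mm dose grid to bound problem
size); intensities outside the aperture are fixed at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .beams import FluenceMap
from .engine import CaseDoseOperator, conformal_aperture
from .grid import VolumeGrid
from .structures import CaseBundle

DEFAULT_BEAMLET_MM = 5.0


@dataclass
class ObjectiveConfig:
    """Weights and limits of the one-sided quadratic FMO objective.

    All penalties are per-voxel means of squared one-sided residuals, with
    residuals normalized by the maximum prescription (planning) or the
    reference maximum (reference mode), making the objective dimensionless
    and positively homogeneous: scaling prescriptions/reference by c scales
    the optimal dose by c.
    """

    target_under_w: float = 100.0
    target_over_w: float = 25.0
    oar_over_w: float = 5.0
    body_over_w: float = 2.0
    oar_limit_frac: float = 0.1
    body_limit_frac: float = 0.6
    ref_under_w: float = 1.0
    ref_over_w: float = 1.0
    ref_support_frac: float = 0.05
    reference: VolumeGrid | None = None
    max_iter: int = 500
    tol: float = 1e-6

    def __post_init__(self) -> None:
        for name in (
            "target_under_w",
            "target_over_w",
            "oar_over_w",
            "body_over_w",
            "ref_under_w",
            "ref_over_w",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")


@dataclass
class FMOResult:
    fluences: list[FluenceMap]
    dose: VolumeGrid
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    status: str = ""


@dataclass
class _Term:
    """One one-sided quadratic penalty: (side * (d - limit))_+ over a region."""

    idx: np.ndarray  # indices into the body-voxel flat dose array
    weight: float  # already divided by the region voxel count
    limit: np.ndarray | float  # Gy
    side: float  # +1 penalizes overdose, -1 underdose
    scale: float  # Gy normalization of the residual


def _build_terms(
    case: CaseBundle, obj: ObjectiveConfig, voxel_idx: np.ndarray
) -> list[_Term]:
    st = case.structures
    flat = tuple(voxel_idx.T)
    rx_max = st.max_prescription_gy
    target_union = st.target_union()[flat]
    terms: list[_Term] = []

    if obj.reference is not None:
        ref = obj.reference.values[flat]
        ref_max = float(ref.max())
        scale = ref_max if ref_max > 0 else rx_max
        support = target_union | (ref >= obj.ref_support_frac * max(ref_max, 1e-12))
        under_idx = np.flatnonzero(support)
        all_idx = np.arange(len(ref))
        if len(under_idx) and obj.ref_under_w > 0:
            terms.append(
                _Term(under_idx, obj.ref_under_w / len(under_idx), ref[under_idx], -1.0, scale)
            )
        if obj.ref_over_w > 0:
            terms.append(_Term(all_idx, obj.ref_over_w / len(all_idx), ref, +1.0, scale))
        return terms

    # planning mode: exclusive target regions (boost overrides primary)
    masks = [t.mask.values[flat] > 0.5 for t in st.targets]
    rx = [t.prescription_gy for t in st.targets]
    order = np.argsort(rx)  # ascending; higher prescriptions claim overlaps
    claimed = np.zeros(len(masks[0]), dtype=bool)
    for i in order[::-1]:
        region = masks[i] & ~claimed
        claimed |= region
        idx = np.flatnonzero(region)
        if not len(idx):
            continue
        terms.append(_Term(idx, obj.target_under_w / len(idx), rx[i], -1.0, rx_max))
        terms.append(_Term(idx, obj.target_over_w / len(idx), rx[i], +1.0, rx_max))

    oar_any = np.zeros(len(claimed), dtype=bool)
    for o in st.oars:
        region = (o.mask.values[flat] > 0.5) & ~target_union
        oar_any |= region
        idx = np.flatnonzero(region)
        if len(idx) and obj.oar_over_w * o.weight > 0:
            terms.append(
                _Term(
                    idx,
                    obj.oar_over_w * o.weight / len(idx),
                    obj.oar_limit_frac * rx_max,
                    +1.0,
                    rx_max,
                )
            )
    body_region = ~target_union & ~oar_any
    idx = np.flatnonzero(body_region)
    if len(idx) and obj.body_over_w > 0:
        terms.append(
            _Term(idx, obj.body_over_w / len(idx), obj.body_limit_frac * rx_max, +1.0, rx_max)
        )
    return terms


def _objective_and_grad(d: np.ndarray, terms: list[_Term]):
    phi = 0.0
    g = np.zeros_like(d)
    for t in terms:
        viol = np.maximum(t.side * (d[t.idx] - t.limit), 0.0) / t.scale
        phi += t.weight * float(viol @ viol)
        g[t.idx] += t.side * 2.0 * t.weight * viol / t.scale
    return phi, g


def _curvature_bound(dd: np.ndarray, terms: list[_Term]) -> float:
    """Upper bound on the objective curvature along dose direction dd."""
    c = 0.0
    for t in terms:
        v = dd[t.idx] / t.scale
        c += 2.0 * t.weight * float(v @ v)
    return c


def objective_value(dose: VolumeGrid, case: CaseBundle, obj: ObjectiveConfig) -> float:
    """Pure objective evaluation on a dose volume; >= 0, and 0 iff all
    one-sided constraints are satisfied."""
    if not dose.same_grid(case.structures.body):
        raise ValueError("dose is not on the case grid")
    voxel_idx = np.argwhere(case.structures.body.values > 0.5)
    terms = _build_terms(case, obj, voxel_idx)
    phi, _ = _objective_and_grad(dose.values[tuple(voxel_idx.T)], terms)
    return phi


def _make_templates(
    case: CaseBundle, beamlet_mm: float, margin_mm: float
) -> list[FluenceMap]:
    union = case.structures.body.like(
        case.structures.target_union().astype(float)
    )
    out = []
    for i, beam in enumerate(case.beams):
        ap = conformal_aperture(union, beam, margin_mm=margin_mm, pixel_mm=beamlet_mm)
        ap.beam_index = i
        out.append(ap)
    return out


def _solve(
    case: CaseBundle,
    obj: ObjectiveConfig,
    beamlet_mm: float,
    margin_mm: float,
) -> FMOResult:
    templates = _make_templates(case, beamlet_mm, margin_mm)
    supports = [t.values > 0.5 for t in templates]
    op = CaseDoseOperator(case, templates)
    terms = _build_terms(case, obj, op.voxel_idx)

    def apply_x(x: np.ndarray) -> np.ndarray:
        vals, pos = [], 0
        for s in supports:
            f = np.zeros(s.shape)
            n = int(s.sum())
            f[s] = x[pos : pos + n]
            pos += n
            vals.append(f)
        return op.apply_values(vals)

    def adjoint_d(gd: np.ndarray) -> np.ndarray:
        grads = op.adjoint_values(gd)
        return np.concatenate([g[s] for g, s in zip(grads, supports)])

    n_var = int(sum(s.sum() for s in supports))
    x = np.zeros(n_var)
    d = apply_x(x)
    phi, gd = _objective_and_grad(d, terms)
    trace = [phi]
    g = adjoint_d(gd)
    converged = False
    status = "max_iter"
    x_prev = g_prev = None
    step = None
    for it in range(obj.max_iter):
        if not np.isfinite(phi):
            raise FloatingPointError(f"non-finite objective at iteration {it}")
        if phi <= 1e-18:
            converged, status = True, "objective zero"
            break
        if x_prev is not None:
            s = x - x_prev
            y = g - g_prev
            sy = float(s @ y)
            step = float(s @ s) / sy if sy > 1e-30 else step
        if step is None or not np.isfinite(step) or step <= 0:
            dd = apply_x(-g)
            curv = _curvature_bound(dd, terms)
            step = float(g @ g) / curv if curv > 0 else 1.0
        accepted = False
        t = step
        for _ in range(40):
            x_new = np.maximum(x - t * g, 0.0)
            if np.array_equal(x_new, x):
                break
            d_new = apply_x(x_new)
            phi_new, gd_new = _objective_and_grad(d_new, terms)
            if phi_new < phi:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            converged, status = True, "no descent step"
            break
        x_prev, g_prev = x, g
        x, d, gd = x_new, d_new, gd_new
        rel = (phi - phi_new) / max(phi, 1e-30)
        phi = phi_new
        g = adjoint_d(gd)
        trace.append(phi)
        step = t
        if rel < obj.tol:
            converged, status = True, "objective change below tol"
            break

    fl_values, pos = [], 0
    for s in supports:
        f = np.zeros(s.shape)
        n = int(s.sum())
        f[s] = x[pos : pos + n]
        pos += n
        fl_values.append(f)
    fluences = [t.like(v) for t, v in zip(templates, fl_values)]
    dose = op.dose_volume(fl_values)
    return FMOResult(
        fluences=fluences,
        dose=dose,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace) - 1,
        status=status,
    )


def optimize_planning(
    case: CaseBundle,
    obj: ObjectiveConfig | None = None,
    beamlet_mm: float = DEFAULT_BEAMLET_MM,
    margin_mm: float = 5.0,
) -> FMOResult:
    """Objective-based planning: synthesize a deliverable dose from scratch."""
    obj = obj or ObjectiveConfig()
    if obj.reference is not None:
        raise ValueError("planning mode takes no reference; use optimize_reference")
    return _solve(case, obj, beamlet_mm, margin_mm)


def optimize_reference(
    case: CaseBundle,
    reference_dose: VolumeGrid,
    obj: ObjectiveConfig | None = None,
    beamlet_mm: float = DEFAULT_BEAMLET_MM,
    margin_mm: float = 5.0,
) -> FMOResult:
    """Reference-guided FMO: the physical-feasibility probe.

    Finds non-negative fluences whose engine dose approximates the reference;
    if the reference was produced by the engine from non-negative fluences,
    the optimum recovers it (objective zero iff dose matches the reference on
    its support and nowhere exceeds it).
    """
    if not reference_dose.same_grid(case.structures.body):
        raise ValueError("reference dose is not on the case grid")
    if np.any(reference_dose.values < -1e-9):
        raise ValueError("reference dose must be non-negative")
    obj = replace(obj, reference=reference_dose) if obj else ObjectiveConfig(
        reference=reference_dose
    )
    return _solve(case, obj, beamlet_mm, margin_mm)
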