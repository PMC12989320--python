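"""Evaluation metrics: gamma passing rate, DVH / Dx%, MAPE, cohort reports.

The gamma index compares an evaluated dose against a reference dose with a
dose-difference criterion (percent of the global reference maximum) and a
distance-to-agreement (DTA) criterion; voxels below a low-dose threshold of
the reference maximum are excluded. Per voxel,

    gamma = min over search points r of
            sqrt( (D_eval(r) - D_ref(x))^2 / (dd% * D_ref_max)^2
                + |r - x|^2 / dta^2 )

with the evaluated dose trilinearly interpolated on a sub-voxel search
lattice (step dta/10, radius 3*dta by default). GPR is the percentage of
included voxels with gamma <= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import VolumeGrid
from .structures import CaseBundle

DEFAULT_DX_LEVELS = (2.0, 5.0, 50.0, 95.0)


@dataclass
class GammaCriteria:
    dose_diff_pct: float = 3.0
    dta_mm: float = 2.0
    low_dose_threshold_pct: float = 10.0

    def __post_init__(self) -> None:
        if not (
            self.dose_diff_pct > 0
            and self.dta_mm > 0
            and self.low_dose_threshold_pct > 0
        ):
            raise ValueError("gamma criteria must all be positive")


@dataclass
class GammaResult:
    gamma_map: np.ndarray  # NaN where excluded by the low-dose threshold
    gpr: float  # percent of included voxels with gamma <= 1
    n_evaluated: int


def _trilinear(values: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at fractional index coords (N, 3), in-bounds."""
    i0 = np.floor(coords).astype(np.int64)
    i0 = np.minimum(i0, np.asarray(values.shape) - 2)
    i0 = np.maximum(i0, 0)
    f = coords - i0
    out = np.zeros(len(coords))
    for dx in (0, 1):
        wx = f[:, 0] if dx else 1.0 - f[:, 0]
        for dy in (0, 1):
            wy = f[:, 1] if dy else 1.0 - f[:, 1]
            for dz in (0, 1):
                wz = f[:, 2] if dz else 1.0 - f[:, 2]
                out += wx * wy * wz * values[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out


def gamma_passing_rate(
    reference: VolumeGrid,
    evaluated: VolumeGrid,
    crit: GammaCriteria | None = None,
    search_factor: float = 3.0,
    step_frac: float = 0.1,
) -> GammaResult:
    """Gamma map and passing rate of ``evaluated`` against ``reference``.

    Normalization is global (percent of the reference maximum) and the
    low-dose threshold applies to the reference. The search visits lattice
    offsets in order of increasing distance and drops a voxel as soon as its
    current gamma can no longer improve (the distance penalty alone exceeds
    it), which leaves the result identical to exhaustive search within the
    radius.
    """
    crit = crit or GammaCriteria()
    if not reference.same_grid(evaluated):
        raise ValueError("reference and evaluated dose must share a grid")
    refv = reference.values
    evv = evaluated.values
    ref_max = float(refv.max())
    if ref_max <= 0:
        raise ValueError("all-zero reference dose")
    dd_gy = crit.dose_diff_pct / 100.0 * ref_max
    include = refv >= crit.low_dose_threshold_pct / 100.0 * ref_max
    pos = np.argwhere(include).astype(float)
    ref_at = refv[include]

    step = crit.dta_mm * step_frac
    n_steps = int(np.floor(search_factor * crit.dta_mm / step + 1e-9))
    ax = np.arange(-n_steps, n_steps + 1)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    r2 = np.sum(offs**2, axis=1) * (step / crit.dta_mm) ** 2
    keep = r2 <= search_factor**2 + 1e-9
    offs, r2 = offs[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    offs, r2 = offs[order], r2[order]
    offs_idx = offs * (step / reference.spacing_mm)  # offsets in index units

    shape = np.asarray(refv.shape, dtype=float)
    best = np.full(len(pos), np.inf)
    active = np.arange(len(pos))
    for off, pen in zip(offs_idx, r2):
        if not len(active):
            break
        alive = best[active] > pen
        active = active[alive]
        if not len(active):
            break
        coords = pos[active] + off
        valid = np.all((coords >= 0) & (coords <= shape - 1), axis=1)
        if not valid.any():
            continue
        sel = active[valid]
        vals = _trilinear(evv, coords[valid])
        g2 = ((vals - ref_at[sel]) / dd_gy) ** 2 + pen
        best[sel] = np.minimum(best[sel], g2)

    gamma = np.sqrt(best)
    gmap = np.full(refv.shape, np.nan)
    gmap[include] = gamma
    n_eval = int(include.sum())
    gpr = 100.0 * float(np.count_nonzero(gamma <= 1.0 + 1e-12)) / n_eval
    return GammaResult(gamma_map=gmap, gpr=gpr, n_evaluated=n_eval)


def dose_at_volume(dose: VolumeGrid, mask: VolumeGrid, x_pct: float) -> float:
    """Dx%: the largest dose received by at least x% of the ROI volume.

    Computed by descending sort: the value at rank ceil(x/100 * n), without
    interpolation.
    """
    if not 0 < x_pct <= 100:
        raise ValueError("x_pct must be in (0, 100]")
    m = mask.values > 0.5
    if not m.any():
        raise ValueError("empty ROI mask")
    vals = np.sort(dose.values[m])[::-1]
    rank = int(np.ceil(x_pct / 100.0 * len(vals)))
    return float(vals[rank - 1])


@dataclass
class DVHCurve:
    roi: str
    dose_gy: np.ndarray
    volume_fraction: np.ndarray  # cumulative, monotone non-increasing


def dvh_curve(dose: VolumeGrid, mask: VolumeGrid, bin_gy: float = 0.1, roi: str = "roi") -> DVHCurve:
    """Cumulative dose-volume histogram of a ROI."""
    m = mask.values > 0.5
    if not m.any():
        raise ValueError("empty ROI mask")
    vals = dose.values[m]
    edges = np.arange(0.0, vals.max() + 2 * bin_gy, bin_gy)
    frac = np.array([np.mean(vals >= e) for e in edges])
    return DVHCurve(roi=roi, dose_gy=edges, volume_fraction=frac)


def mape(
    metric_pairs: list[tuple[float, float]], dp_gy: float | np.ndarray
) -> float:
    """Mean absolute percentage error of a DVH metric over cases.

    100/n * sum_i |Dx%_i(pred) - Dx%_i(ref)| / Dp_i, with Dp the prescribed
    dose of case i (a scalar Dp applies to all cases).
    """
    if not metric_pairs:
        raise ValueError("need at least one metric pair")
    pairs = np.asarray(metric_pairs, dtype=float)
    dp = np.broadcast_to(np.asarray(dp_gy, dtype=float), (len(pairs),))
    if np.any(dp <= 0):
        raise ValueError("prescribed dose must be positive")
    return float(100.0 * np.mean(np.abs(pairs[:, 0] - pairs[:, 1]) / dp))


def _dx_table(case: CaseBundle, dose: VolumeGrid, levels=DEFAULT_DX_LEVELS) -> dict:
    out = {}
    st = case.structures
    for t in st.targets:
        for x in levels:
            out[f"{t.name}_D{x:g}%"] = dose_at_volume(dose, t.mask, x)
    for o in st.oars:
        for x in levels:
            out[f"{o.name}_D{x:g}%"] = dose_at_volume(dose, o.mask, x)
    return out


def report_cohort(
    cases: list[CaseBundle],
    doses: list[dict],
    crit: GammaCriteria | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-case and summary metric report.

    ``doses[i]`` maps names among {'pred', 'opt', 'label'} to dose volumes for
    ``cases[i]``. For each available pair the gamma passing rate is computed
    with the second-named dose as reference (pred vs opt -> opt is reference;
    pred/opt vs label -> label is reference), plus Dx% tables per dose. Cases
    with missing doses are skipped per-comparison with a warning. Returns
    (per-case rows, mean +/- SD summary).
    """
    crit = crit or GammaCriteria()
    comparisons = [("pred", "opt"), ("pred", "label"), ("opt", "label")]
    rows = []
    for case, dd in zip(cases, doses):
        row: dict = {"case_id": case.case_id}
        for a, b in comparisons:
            if a not in dd or b not in dd or dd[a] is None or dd[b] is None:
                warnings.warn(
                    f"{case.case_id}: missing dose for {a} vs {b}; skipped",
                    stacklevel=2,
                )
                continue
            row[f"gpr_{a}_vs_{b}"] = gamma_passing_rate(dd[b], dd[a], crit).gpr
        for name, dose in dd.items():
            if dose is None:
                continue
            for k, v in _dx_table(case, dose).items():
                row[f"{name}_{k}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    numeric = df.select_dtypes("number")
    summary = pd.DataFrame({"mean": numeric.mean(), "sd": numeric.std(ddof=1)})
    return df, summary
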