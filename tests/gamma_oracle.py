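"""Exhaustive brute-force gamma oracle, independent of the package's
implementation: the evaluated dose is presampled onto a fine lattice once and
every search offset within the radius is visited for every voxel (no early
termination, no retirement)."""

import numpy as np
from scipy import ndimage


def brute_gamma(ref, ev, crit, search_factor=3.0, step_frac=0.1, chunk=512):
    refv, evv = ref.values, ev.values
    ref_max = refv.max()
    dd = crit.dose_diff_pct / 100 * ref_max
    include = refv >= crit.low_dose_threshold_pct / 100 * ref_max
    step = crit.dta_mm * step_frac
    up = int(round(ref.spacing_mm / step))
    assert abs(up * step - ref.spacing_mm) < 1e-9, "spacing must be a step multiple"
    fine_ax = [np.arange((ni - 1) * up + 1) / up for ni in refv.shape]
    mesh = np.meshgrid(*fine_ax, indexing="ij")
    fine = ndimage.map_coordinates(evv, np.stack(mesh), order=1)

    n_steps = int(np.floor(search_factor * crit.dta_mm / step + 1e-9))
    ax = np.arange(-n_steps, n_steps + 1)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([o.ravel() for o in (ox, oy, oz)], 1)
    r2 = (offs**2).sum(1) * (step / crit.dta_mm) ** 2
    keep = r2 <= search_factor**2 + 1e-9
    offs, r2 = offs[keep], r2[keep]

    pos = np.argwhere(include) * up
    refs = refv[include]
    best = np.full(len(pos), np.inf)
    fshape = np.array(fine.shape)
    flat = fine.ravel()
    strides = np.array(
        [fine.shape[1] * fine.shape[2], fine.shape[2], 1], dtype=np.int64
    )
    for i in range(0, len(offs), chunk):
        ob, rb = offs[i : i + chunk], r2[i : i + chunk]
        q = pos[None, :, :] + ob[:, None, :]  # (chunk, nvox, 3)
        valid = np.all((q >= 0) & (q < fshape), axis=2)
        qi = np.clip(q, 0, fshape - 1) @ strides
        vals = flat[qi]
        g2 = ((vals - refs[None, :]) / dd) ** 2 + rb[:, None]
        g2 = np.where(valid, g2, np.inf)
        best = np.minimum(best, g2.min(axis=0))
    gamma = np.sqrt(best)
    gpr = 100.0 * np.mean(gamma <= 1 + 1e-12)
    return gpr, gamma
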