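"""Deeper interfaces: shift-based estimation and two-pass refinement.

The corneal interfaces below the air–epithelium boundary (epithelium–stroma,
endothelium–aqueous) run roughly parallel to it, so a first estimate comes
from rigidly shifting the refined anterior profile down and keeping the shift
that maximises the summed absolute gradient,

    mu* = argmax_{mu in S}  sum_x |g(x, f(x) + mu)| ,

with ``S`` the thickness-derived search band.  The cornea is thinner at the
centre than at the periphery, so the rigid shift is then relaxed by the same
centre-out refinement as the anterior, run twice: first with a decay constant
growing linearly from the centre (peripheral columns explore more), then with
a constant low ``p`` for smoothing, followed by a median filter (deeper
boundaries have no predefined polynomial model).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.ndimage import median_filter

from .core import (
    BScanImage,
    BoundaryCurve,
    GradientField,
    InvalidInputError,
    SegConfig,
    StageError,
)
from .preprocess import ArtifactReport, preprocess_pipeline
from .anterior import coarse_anterior, fit_parabola
from .refine import axial_gradient, refine_boundary_2d, smooth_sg

__all__ = [
    "estimate_layer_by_shift",
    "linear_growth_p_profile",
    "refine_layer",
    "enforce_depth_order",
    "segment_bscan",
]


def estimate_layer_by_shift(
    g: GradientField,
    anterior: BoundaryCurve,
    shift_range: tuple[int, int],
    report: ArtifactReport | None = None,
) -> tuple[BoundaryCurve, int]:
    """Locate a deeper interface by shifting the anterior profile downward.

    Columns whose shifted position leaves the image are dropped from the sum
    for that shift.  A gradient field with no signal at any admissible shift
    (all sums zero, or no column ever in range) raises rather than returning
    an arbitrary shift.
    """
    absg = np.abs(g.values)
    y_dim, x_dim = absg.shape
    if anterior.width != x_dim:
        raise InvalidInputError("curve width does not match gradient width")
    lo, hi = int(shift_range[0]), int(shift_range[1])
    if lo < 1 or hi < lo:
        raise InvalidInputError("shift range must satisfy 1 <= lo <= hi")
    valid = anterior.valid.copy()
    if report is not None:
        valid[list(report.central_columns)] = False
    cols = np.flatnonzero(valid)
    if cols.size == 0:
        raise InvalidInputError("no valid columns to estimate a layer from")
    base = np.rint(anterior.positions[cols]).astype(int)

    shifts = np.arange(lo, hi + 1)
    sums = np.full(shifts.size, -np.inf)
    for i, mu in enumerate(shifts):
        rows = base + mu
        ok = (rows >= 0) & (rows < y_dim)
        if ok.any():
            sums[i] = absg[rows[ok], cols[ok]].sum()
    if not np.isfinite(sums).any() or np.nanmax(sums) <= 0:
        raise InvalidInputError(
            "no gradient signal in the shift search band (empty or zero sums)"
        )
    best = int(shifts[int(np.argmax(sums))])

    pos = np.where(valid, anterior.positions + best, np.nan)
    in_bounds = valid & (np.nan_to_num(pos, nan=-1.0) >= 0) & (
        np.nan_to_num(pos, nan=float(y_dim)) <= y_dim - 1
    )
    pos = np.where(in_bounds, pos, np.nan)
    return BoundaryCurve(pos, in_bounds, "other"), best


def linear_growth_p_profile(
    width: int, center: int, p_min: float, p_max: float
) -> np.ndarray:
    """Decay constant per column, growing linearly from centre to periphery.

    ``p(center) = p_min`` and ``p = p_max`` at the farthest edge, linear in
    ``|x - center|`` — peripheral columns trust their committed neighbourhood
    more narrowly and explore the gradient more freely.
    """
    if not (0.0 < p_min <= p_max < 1.0):
        raise InvalidInputError("need 0 < p_min <= p_max < 1")
    if not (0 <= center < width):
        raise InvalidInputError("center must be a column index")
    x = np.arange(width)
    dist = np.abs(x - center).astype(float)
    max_dist = dist.max()
    if max_dist == 0:
        return np.full(width, p_min)
    return p_min + (p_max - p_min) * dist / max_dist


def _median_valid_runs(curve: BoundaryCurve, window: int) -> BoundaryCurve:
    pos = curve.positions.copy()
    x = 0
    while x < curve.width:
        if not curve.valid[x]:
            x += 1
            continue
        start = x
        while x < curve.width and curve.valid[x]:
            x += 1
        run = x - start
        size = min(window, run if run % 2 == 1 else run - 1)
        if size >= 3:
            pos[start:x] = median_filter(pos[start:x], size=size, mode="nearest")
    return BoundaryCurve(pos, curve.valid.copy(), curve.interface_name)


def refine_layer(
    g: GradientField, initial: BoundaryCurve, cfg: SegConfig
) -> BoundaryCurve:
    """Two-pass refinement of a shift-estimated deeper interface.

    Pass 1 uses the linear-growth decay profile (exploration, strongest at
    the periphery); pass 2 re-anchors on the pass-1 result with a constant
    low decay (``layer_p_min``) for smoothing; a median filter finishes the
    curve.  The output is clamped within ``search_radius_px`` of the pass-1
    result, so no stage can run away in flat-gradient regions.
    """
    if initial.n_valid == 0:
        raise InvalidInputError("layer refinement needs at least one valid column")
    cols = np.flatnonzero(initial.valid)
    centre = int(cols[np.argmin(np.abs(cols - (initial.width - 1) / 2.0))])
    profile = linear_growth_p_profile(
        initial.width, centre, cfg.layer_p_min, cfg.layer_p_max
    )
    pass1 = refine_boundary_2d(g, initial, cfg, p_profile=profile)
    smooth_cfg = replace(cfg, decay_p=cfg.layer_p_min)
    pass2 = refine_boundary_2d(g, pass1, smooth_cfg)
    out = _median_valid_runs(pass2, cfg.median_window)
    lo = pass1.positions - cfg.search_radius_px
    hi = pass1.positions + cfg.search_radius_px
    pos = np.where(out.valid, np.clip(out.positions, lo, hi), np.nan)
    return BoundaryCurve(pos, out.valid, initial.interface_name)


def enforce_depth_order(curves: list[BoundaryCurve]) -> list[int]:
    """Clip crossings so interfaces stay strictly depth-ordered.

    Physical corneal layers cannot cross; wherever a deeper curve rises to or
    above a shallower one it is clipped to one pixel below it.  Returns the
    columns that needed clipping (for logging).
    """
    touched: set[int] = set()
    for upper, lower in zip(curves, curves[1:]):
        both = upper.valid & lower.valid
        cross = both & (lower.positions <= upper.positions)
        idx = np.flatnonzero(cross)
        if idx.size:
            lower.positions[idx] = upper.positions[idx] + 1
            touched.update(int(i) for i in idx)
    return sorted(touched)


def segment_bscan(image: BScanImage, cfg: SegConfig | None = None) -> list[BoundaryCurve]:
    """Full 2D pipeline on one raw B-scan.

    preprocess -> coarse anterior -> parabola fit -> gradient refinement ->
    Savitzky–Golay smoothing -> per configured deeper interface: shift
    estimation + two-pass refinement.  Returns curves in depth order
    (anterior first) in ORIGINAL image coordinates, positions rounded to
    pixel rows; columns cropped away or excluded by the central artifact are
    invalid (optionally interpolated when ``cfg.interpolate_gaps``).
    """
    cfg = cfg or SegConfig()

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage label
            raise StageError(name, exc) from exc

    pre = _stage("preprocess", preprocess_pipeline, image, cfg)
    roi, report = pre.image, pre.report
    coarse = _stage("coarse_anterior", coarse_anterior, roi, report, cfg)
    fitted, _ = _stage("fit_parabola", fit_parabola, coarse)
    excluded = np.array(report.central_columns, dtype=int)
    mask = np.ones(roi.width, dtype=bool)
    if excluded.size:
        mask[excluded] = False
    fitted = BoundaryCurve(
        np.where(mask, fitted.positions, np.nan), mask, "anterior"
    )
    g = _stage("axial_gradient", axial_gradient, roi)
    refined = _stage("refine_anterior", refine_boundary_2d, g, fitted, cfg)
    ant = _stage("smooth_anterior", smooth_sg, refined, cfg)

    curves = [ant]
    for layer in cfg.layers:
        rng = layer.shift_range_px(roi.axial_res_um)
        est, _ = _stage(f"estimate_{layer.name}", estimate_layer_by_shift, g, ant, rng, report)
        est = BoundaryCurve(est.positions, est.valid, layer.name)
        cur = _stage(f"refine_{layer.name}", refine_layer, g, est, cfg)
        curves.append(cur)

    # back to original coordinates, pixel-rounded
    row_off, col_off = roi.crop_offset
    out: list[BoundaryCurve] = []
    for c in curves:
        pos = np.where(c.valid, np.rint(c.positions), np.nan)
        full = BoundaryCurve(pos, c.valid, c.interface_name).embedded(
            image.width, col_off - image.crop_offset[1], row_off - image.crop_offset[0]
        )
        out.append(full)
    enforce_depth_order(out)
    if cfg.interpolate_gaps:
        out = [c.interpolate_gaps() for c in out]
    return out
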