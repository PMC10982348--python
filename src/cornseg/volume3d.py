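"""Direct 3D segmentation of layer surfaces in an OCT volume.

The 2D machinery generalises frame-wise for preprocessing and candidate
generation, while estimation and refinement act on surfaces: per-frame
boundary-function picks are pooled into one weighted quadratic surface fit,
the surface is refined greedily in order of city-block geodesic distance from
the central position (the corneal centre has the highest SNR), deeper
surfaces are located by rigidly shifting the refined anterior surface
(argmax over the summed absolute gradient), and height maps are median
smoothed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .core import (
    BoundaryCurve,
    BoundarySurface,
    InvalidInputError,
    SegConfig,
    StageError,
    Volume,
)
from .anterior import coarse_anterior
from .preprocess import (
    ArtifactReport,
    denoise,
    detect_apex_row,
    detect_central_artifact,
    remove_horizontal_artifact,
)
from .refine import axial_gradient, decay_horizon

__all__ = [
    "QuadraticSurface",
    "fit_quadratic_surface",
    "geodesic_order",
    "refine_surface_3d",
    "estimate_layer_3d",
    "segment_volume",
]

#: lateral city-block radius inside which committed neighbours contribute
#: to a candidate's propagation score
_NEIGHBOR_RADIUS = 8


@dataclass(frozen=True)
class QuadraticSurface:
    """z = a0 + a1 u + a2 v + a3 u^2 + a4 u v + a5 v^2 over (column, frame)."""

    coefficients: tuple[float, float, float, float, float, float]

    def evaluate(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        a0, a1, a2, a3, a4, a5 = self.coefficients
        return a0 + a1 * u + a2 * v + a3 * u * u + a4 * u * v + a5 * v * v


def fit_quadratic_surface(
    points: np.ndarray, weights: np.ndarray | None = None
) -> QuadraticSurface:
    """Weighted least-squares quadratic surface with outlier rejection.

    ``points`` is ``(n, 3)`` rows of ``(u, v, z)``.  As in the 2D parabola
    fit, a second pass drops points whose absolute residual exceeds three
    times the median absolute residual.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 6:
        raise InvalidInputError("need at least 6 (u, v, z) points")
    w = np.ones(pts.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (pts.shape[0],):
        raise InvalidInputError("weights must match the number of points")

    def _design(u, v):
        return np.column_stack([np.ones_like(u), u, v, u * u, u * v, v * v])

    def _solve(p, wts):
        a = _design(p[:, 0], p[:, 1]) * wts[:, None]
        b = p[:, 2] * wts
        coef, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
        if rank < 6:
            raise InvalidInputError("rank-deficient design (degenerate points)")
        return coef

    coef = _solve(pts, np.sqrt(w))
    resid = np.abs(_design(pts[:, 0], pts[:, 1]) @ coef - pts[:, 2])
    med = np.median(resid)
    keep = resid <= max(3.0 * med, 1e-9)
    if keep.sum() >= 6 and keep.sum() < keep.size:
        coef = _solve(pts[keep], np.sqrt(w[keep]))
    return QuadraticSurface(tuple(float(c) for c in coef))


def geodesic_order(
    valid_mask: np.ndarray, seed: tuple[int, int]
) -> tuple[list[tuple[int, int]], np.ndarray, list[tuple[int, int]]]:
    """City-block geodesic distances within a mask, sorted for propagation.

    Breadth-first traversal over the 4-connected grid restricted to valid
    positions.  Returns the reachable positions sorted by increasing
    distance (ties broken by (row, column)), the distance grid (-1 where
    unreachable/invalid), and any valid-but-unreachable positions.
    """
    mask = np.asarray(valid_mask, dtype=bool)
    sv, su = seed
    if not (0 <= sv < mask.shape[0] and 0 <= su < mask.shape[1]) or not mask[sv, su]:
        raise InvalidInputError("seed must be a valid position")
    dist = np.full(mask.shape, -1, dtype=int)
    dist[sv, su] = 0
    q: deque[tuple[int, int]] = deque([(sv, su)])
    while q:
        v, u = q.popleft()
        for dv, du in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nv, nu = v + dv, u + du
            if (
                0 <= nv < mask.shape[0]
                and 0 <= nu < mask.shape[1]
                and mask[nv, nu]
                and dist[nv, nu] < 0
            ):
                dist[nv, nu] = dist[v, u] + 1
                q.append((nv, nu))
    reachable = [
        (int(v), int(u))
        for v, u in zip(*np.nonzero(dist >= 0))
    ]
    reachable.sort(key=lambda p: (dist[p], p[0], p[1]))
    unreachable = [
        (int(v), int(u)) for v, u in zip(*np.nonzero(mask & (dist < 0)))
    ]
    return reachable, dist, unreachable


def _central_seed(valid: np.ndarray) -> tuple[int, int]:
    """Valid position nearest the lateral centroid of the valid mask."""
    vs, us = np.nonzero(valid)
    if vs.size == 0:
        raise InvalidInputError("no valid positions")
    cv, cu = vs.mean(), us.mean()
    cost = np.abs(vs - cv) + np.abs(us - cu)
    order = np.lexsort((us, vs, cost))
    return int(vs[order[0]]), int(us[order[0]])


def refine_surface_3d(
    gvol: np.ndarray, coarse: BoundarySurface, cfg: SegConfig
) -> BoundarySurface:
    """Geodesically ordered greedy refinement of a coarse surface.

    ``gvol`` is the stacked axial gradient, shape (frames, depth, width).
    The scoring rule is the 3D analogue of the 2D refinement: candidate
    offsets are scored by their own |gradient| plus the decay-weighted
    |gradient| of already-refined positions within city-block lateral radius
    8, rigidly shifted by the candidate offset; the decay distance is the
    geodesic-distance difference.  The refined height map is median smoothed
    (``median3d_window`` square) and clamped within ``search_radius_px`` of
    the coarse surface.
    """
    absg = np.abs(np.asarray(gvol, dtype=float))
    n_frames, y_dim, x_dim = absg.shape
    if coarse.shape != (n_frames, x_dim):
        raise InvalidInputError("coarse surface shape must be (frames, width)")
    r = cfg.search_radius_px
    if r == 0:
        return BoundarySurface(
            coarse.heights.copy(), coarse.valid.copy(), coarse.interface_name
        )
    if not coarse.valid.any():
        raise InvalidInputError("refinement needs at least one valid position")

    base = np.where(coarse.valid, coarse.heights, 0.0)
    base = np.clip(np.rint(base).astype(int), 0, y_dim - 1)
    seed = _central_seed(coarse.valid)
    order, dist, _unreached = geodesic_order(coarse.valid, seed)

    deltas = np.arange(-r, r + 1)
    horizon = decay_horizon(cfg.decay_p)
    heights = np.full((n_frames, x_dim), np.nan)
    offsets = np.zeros((n_frames, x_dim), dtype=int)
    done = np.zeros((n_frames, x_dim), dtype=bool)

    sv, su = seed
    rows = np.clip(base[sv, su] + deltas, 0, y_dim - 1)
    k = int(np.argmax(absg[sv, rows, su]))
    offsets[sv, su] = deltas[k]
    heights[sv, su] = rows[k]
    done[sv, su] = True

    p = cfg.decay_p
    for v, u in order[1:]:
        v0, v1 = max(0, v - _NEIGHBOR_RADIUS), min(n_frames, v + _NEIGHBOR_RADIUS + 1)
        u0, u1 = max(0, u - _NEIGHBOR_RADIUS), min(x_dim, u + _NEIGHBOR_RADIUS + 1)
        patch = done[v0:v1, u0:u1]
        nv, nu = np.nonzero(patch)
        nv = nv + v0
        nu = nu + u0
        city = np.abs(nv - v) + np.abs(nu - u)
        sel = city <= _NEIGHBOR_RADIUS
        nv, nu = nv[sel], nu[sel]
        cand = absg[v, np.clip(base[v, u] + deltas, 0, y_dim - 1), u]
        if nv.size:
            d = np.clip(dist[v, u] - dist[nv, nu], 0, None)
            keep = d <= horizon
            nv, nu, d = nv[keep], nu[keep], d[keep]
        if nv.size:
            w = p * (1.0 - p) ** d
            ref = heights[nv, nu].astype(int)
            offs = offsets[nv, nu]
            shifted = np.clip(
                ref[:, None] + deltas[None, :] - offs[:, None], 0, y_dim - 1
            )
            prop = (w[:, None] * absg[nv[:, None], shifted, nu[:, None]]).sum(axis=0)
            score = cand + prop
        else:
            score = cand
        k = int(np.argmax(score))
        offsets[v, u] = deltas[k]
        heights[v, u] = np.clip(base[v, u] + deltas[k], 0, y_dim - 1)
        done[v, u] = True

    # smooth the height map; fill gaps with the coarse base so the filter has
    # support, then restore the validity mask
    filled = np.where(done, heights, base.astype(float))
    smoothed = median_filter(filled, size=cfg.median3d_window, mode="nearest")
    lo = base - r
    hi = base + r
    smoothed = np.clip(smoothed, np.clip(lo, 0, y_dim - 1), np.clip(hi, 0, y_dim - 1))
    out = np.where(done, smoothed, np.nan)
    return BoundarySurface(out, done, coarse.interface_name)


def estimate_layer_3d(
    gvol: np.ndarray,
    anterior_surface: BoundarySurface,
    shift_range: tuple[int, int],
) -> tuple[BoundarySurface, int]:
    """3D analogue of the 2D shift estimator (Eq.-style argmax over shifts)."""
    absg = np.abs(np.asarray(gvol, dtype=float))
    n_frames, y_dim, x_dim = absg.shape
    if anterior_surface.shape != (n_frames, x_dim):
        raise InvalidInputError("surface shape must be (frames, width)")
    lo, hi = int(shift_range[0]), int(shift_range[1])
    if lo < 1 or hi < lo:
        raise InvalidInputError("shift range must satisfy 1 <= lo <= hi")
    vs, us = np.nonzero(anterior_surface.valid)
    if vs.size == 0:
        raise InvalidInputError("no valid surface positions")
    base = np.rint(anterior_surface.heights[vs, us]).astype(int)
    shifts = np.arange(lo, hi + 1)
    sums = np.full(shifts.size, -np.inf)
    for i, mu in enumerate(shifts):
        rows = base + mu
        ok = (rows >= 0) & (rows < y_dim)
        if ok.any():
            sums[i] = absg[vs[ok], rows[ok], us[ok]].sum()
    if not np.isfinite(sums).any() or np.nanmax(sums) <= 0:
        raise InvalidInputError("no gradient signal in the 3D shift search band")
    best = int(shifts[int(np.argmax(sums))])
    h = np.where(anterior_surface.valid, anterior_surface.heights + best, np.nan)
    ok = anterior_surface.valid & (np.nan_to_num(h, nan=-1.0) >= 0) & (
        np.nan_to_num(h, nan=float(y_dim)) <= y_dim - 1
    )
    h = np.where(ok, h, np.nan)
    return BoundarySurface(h, ok, "other"), best


def _enforce_surface_order(surfaces: list[BoundarySurface]) -> None:
    for upper, lower in zip(surfaces, surfaces[1:]):
        both = upper.valid & lower.valid
        cross = both & (lower.heights <= upper.heights)
        lower.heights[cross] = upper.heights[cross] + 1


def segment_volume(volume: Volume, cfg: SegConfig | None = None) -> list[BoundarySurface]:
    """Full 3D pipeline: per-frame preprocessing, pooled estimation, ordered
    greedy refinement, shift-based deeper surfaces.

    Frames are preprocessed with one shared crop window (min apex top / max
    bottom across frames) so the volume stays rectangular.  A frame whose
    preprocessing fails is masked invalid rather than aborting the run.
    Returns surfaces depth-ordered, in ORIGINAL coordinates, heights rounded
    to pixel rows.
    """
    cfg = cfg or SegConfig()
    if volume.n_frames < 3:
        raise InvalidInputError(
            "direct 3D segmentation needs at least 3 frames; use the 2D "
            "pipeline (segment_bscan) for single B-scans"
        )
    first = volume.frames[0]
    axial_res = first.axial_res_um

    # ---- unified crop window --------------------------------------------
    apexes = [detect_apex_row(f) for f in volume.frames]
    depth = cfg.resolved_depth_extent(axial_res)
    side = cfg.resolved_side_crop(first.width)
    r0 = max(0, min(apexes) - cfg.apex_margin_px)
    r1 = min(first.height, max(apexes) + depth)
    c0, c1 = side, first.width - side
    if (r1 - r0) < 3 or (c1 - c0) < 3:
        raise InvalidInputError("cropped 3D ROI is smaller than 3x3")

    n_frames = volume.n_frames
    width = c1 - c0
    gvol = np.zeros((n_frames, r1 - r0, width))
    frame_ok = np.zeros(n_frames, dtype=bool)
    col_valid = np.ones((n_frames, width), dtype=bool)
    points: list[tuple[float, float, float]] = []
    failures: list[tuple[int, str]] = []

    for f, frame in enumerate(volume.frames):
        try:
            roi = frame.with_pixels(frame.pixels[r0:r1, c0:c1].copy())
            roi = remove_horizontal_artifact(roi)
            report = detect_central_artifact(roi, cfg)
            roi = denoise(roi, cfg)
            coarse = coarse_anterior(roi, report, cfg)
        except Exception as exc:  # noqa: BLE001 - frame-level fault isolation
            failures.append((f, str(exc)))
            col_valid[f] = False
            continue
        frame_ok[f] = True
        if report.central_columns:
            col_valid[f, list(report.central_columns)] = False
        gvol[f] = axial_gradient(roi).values
        for x in np.flatnonzero(coarse.valid & col_valid[f]):
            points.append((float(x), float(f), float(coarse.positions[x])))

    if not frame_ok.any() or len(points) < 6:
        raise StageError("coarse_surface", InvalidInputError(
            f"too few candidate points pooled across frames ({len(points)}); "
            f"frame failures: {failures}"
        ))

    pts = np.asarray(points)
    quad = fit_quadratic_surface(pts)
    uu, vv = np.meshgrid(np.arange(width, dtype=float), np.arange(n_frames, dtype=float))
    coarse_heights = np.clip(quad.evaluate(uu, vv), 0, (r1 - r0) - 1)
    valid = col_valid & frame_ok[:, None]
    coarse_surface = BoundarySurface(
        np.where(valid, coarse_heights, np.nan), valid, "anterior"
    )

    anterior = refine_surface_3d(gvol, coarse_surface, cfg)
    surfaces = [anterior]
    for layer in cfg.layers:
        rng = layer.shift_range_px(axial_res)
        est, _ = estimate_layer_3d(gvol, anterior, rng)
        est = BoundarySurface(est.heights, est.valid, layer.name)
        refined = refine_surface_3d(gvol, est, cfg)
        surfaces.append(refined)

    out: list[BoundarySurface] = []
    for s in surfaces:
        h = np.full((n_frames, first.width), np.nan)
        v = np.zeros((n_frames, first.width), dtype=bool)
        h[:, c0:c1] = np.where(s.valid, np.rint(s.heights) + r0, np.nan)
        v[:, c0:c1] = s.valid
        out.append(BoundarySurface(h, v, s.interface_name))
    _enforce_surface_order(out)
    return out
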