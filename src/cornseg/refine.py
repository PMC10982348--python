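"""Gradient-based, centre-out boundary refinement with geometric decay.

The true interface is where the axial intensity change is largest, so the
coarse boundary is adjusted to the strongest absolute forward-difference
gradient inside a small search window.  Robustness in low-SNR columns comes
from propagation: starting at the central column (where corneal OCT is
brightest) and walking outward, each candidate offset is scored by its own
gradient *plus* the gradient the already-committed neighbours would see if
the refined profile were rigidly shifted by the same offset, down-weighted
geometrically with distance,

    w(d) = p (1 - p)^d ,   d = column distance - 1,

so the nearest committed pixel carries weight ``p`` and distant pixels fade
exponentially.  Larger ``p`` trusts only the immediate neighbourhood; smaller
``p`` averages over a wider stretch of committed boundary.

The search window stays anchored on the coarse boundary, so the refined curve
can never drift more than ``search_radius_px`` from its initialisation — the
hard contract that keeps refinement from running away in zero-SNR regions.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import savgol_filter

from .core import (
    BScanImage,
    BoundaryCurve,
    GradientField,
    InvalidInputError,
    SegConfig,
)

__all__ = [
    "axial_gradient",
    "geometric_weights",
    "decay_horizon",
    "refine_boundary_2d",
    "smooth_sg",
]


def axial_gradient(image: BScanImage) -> GradientField:
    """Forward-difference axial gradient ``g(x, y) = (I(x, y+1) - I(x, y))/2``.

    The last row has no forward neighbour and duplicates the previous row's
    value, keeping the field the same shape as the image.
    """
    px = image.pixels
    g = np.empty_like(px)
    g[:-1] = (px[1:] - px[:-1]) / 2.0
    g[-1] = g[-2]
    return GradientField(g)


def geometric_weights(p: float, n: int) -> np.ndarray:
    """Geometric decay weights ``w(d) = p (1-p)^d`` for ``d = 0 .. n-1``."""
    if not (0.0 < p < 1.0):
        raise InvalidInputError("decay constant p must lie in (0, 1)")
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    d = np.arange(n)
    return p * (1.0 - p) ** d


def decay_horizon(p: float, rel_tol: float = 1e-6) -> int:
    """Distance beyond which ``w(d) < rel_tol * w(0)`` (truncation horizon)."""
    if not (0.0 < p < 1.0):
        raise InvalidInputError("decay constant p must lie in (0, 1)")
    return max(1, math.ceil(math.log(rel_tol) / math.log(1.0 - p)))


def refine_boundary_2d(
    g: GradientField,
    coarse: BoundaryCurve,
    cfg: SegConfig,
    p_profile: np.ndarray | None = None,
) -> BoundaryCurve:
    """Centre-out greedy refinement of a coarse boundary curve.

    Parameters
    ----------
    g
        Axial gradient field of the (preprocessed) B-scan.
    coarse
        Initial boundary; its valid mask controls which columns take part.
        Invalid columns are skipped and bridged (distance keeps counting).
    cfg
        Uses ``search_radius_px`` and ``decay_p``.
    p_profile
        Optional per-column decay constant overriding ``cfg.decay_p`` —
        deeper-layer refinement feeds the centre-to-periphery growth profile
        through here.

    Notes
    -----
    The seed is the central valid column, refined to the in-window argmax of
    ``|g|`` alone; both halves of the image then propagate independently from
    it.  For a candidate offset ``delta`` at column ``x`` the score is::

        |g(x, base(x) + delta)|
          + sum_j w(d_j) |g(x_j, refined(x_j) + delta - delta_j)|

    over previously refined columns ``x_j`` on the same side, with
    ``d_j = |x - x_j| - 1`` and ``delta_j`` the committed offset of ``x_j``
    (so the committed profile is rigidly shifted by ``delta``).  Rows are
    clamped to the image; the weighted sum is truncated once weights fall
    below ``1e-6 w(0)``.  Ties take the first (shallowest) offset.
    """
    absg = np.abs(g.values)
    y_dim, x_dim = absg.shape
    if coarse.width != x_dim:
        raise InvalidInputError("curve width does not match gradient width")
    if coarse.n_valid == 0:
        raise InvalidInputError("refinement needs at least one valid column")
    r = cfg.search_radius_px
    if r == 0:
        # empty search region: the coarse curve is already the answer
        return BoundaryCurve(
            coarse.positions.copy(), coarse.valid.copy(), coarse.interface_name
        )
    if p_profile is not None:
        p_profile = np.asarray(p_profile, dtype=float)
        if p_profile.shape != (x_dim,):
            raise InvalidInputError("p_profile must have one value per column")

    base = np.where(coarse.valid, coarse.positions, 0.0)
    base = np.clip(np.rint(base).astype(int), 0, y_dim - 1)
    deltas = np.arange(-r, r + 1)
    cols = np.flatnonzero(coarse.valid)
    centre = cols[np.argmin(np.abs(cols - (x_dim - 1) / 2.0))]

    refined = np.full(x_dim, np.nan)
    offsets = np.zeros(x_dim, dtype=int)

    rows_c = np.clip(base[centre] + deltas, 0, y_dim - 1)
    k = int(np.argmax(absg[rows_c, centre]))
    offsets[centre] = deltas[k]
    refined[centre] = rows_c[k]

    def _p_at(x: int) -> float:
        return float(p_profile[x]) if p_profile is not None else cfg.decay_p

    for side in (cols[cols > centre], cols[cols < centre][::-1]):
        hist_x: list[int] = [centre]
        hist_row: list[int] = [int(refined[centre])]
        hist_off: list[int] = [int(offsets[centre])]
        for x in side:
            p = _p_at(x)
            horizon = decay_horizon(p)
            # most recent commits are the nearest columns on this side
            xs = np.array(hist_x[::-1])
            d = np.abs(x - xs) - 1
            keep = d <= horizon
            xs = xs[keep]
            d = d[keep]
            rows_j = np.array(hist_row[::-1])[keep]
            offs_j = np.array(hist_off[::-1])[keep]
            cand = absg[np.clip(base[x] + deltas, 0, y_dim - 1), x]
            if xs.size:
                w = p * (1.0 - p) ** d
                shifted = np.clip(
                    rows_j[:, None] + deltas[None, :] - offs_j[:, None], 0, y_dim - 1
                )
                prop = (w[:, None] * absg[shifted, xs[:, None]]).sum(axis=0)
                score = cand + prop
            else:
                score = cand
            k = int(np.argmax(score))
            offsets[x] = deltas[k]
            refined[x] = np.clip(base[x] + deltas[k], 0, y_dim - 1)
            hist_x.append(x)
            hist_row.append(int(refined[x]))
            hist_off.append(int(offsets[x]))

    return BoundaryCurve(refined, coarse.valid.copy(), coarse.interface_name)


def smooth_sg(curve: BoundaryCurve, cfg: SegConfig) -> BoundaryCurve:
    """Savitzky–Golay smoothing of the valid runs of a boundary curve.

    Order-``sg_order`` local polynomial least squares over ``sg_window``
    columns; endpoints are handled by evaluating the polynomial fitted to the
    terminal window.  Runs shorter than the window shrink it to the largest
    odd length that still fits (runs too short for the order pass through
    unchanged).  An order-1 filter reproduces affine curves exactly.
    """
    pos = curve.positions.copy()
    valid = curve.valid
    x = 0
    while x < curve.width:
        if not valid[x]:
            x += 1
            continue
        run_start = x
        while x < curve.width and valid[x]:
            x += 1
        run = slice(run_start, x)
        n = x - run_start
        window = min(cfg.sg_window, n if n % 2 == 1 else n - 1)
        if window <= cfg.sg_order:
            continue
        pos[run] = savgol_filter(
            pos[run], window_length=window, polyorder=cfg.sg_order, mode="interp"
        )
    np.clip(pos, 0.0, None, out=pos)
    return BoundaryCurve(pos, valid.copy(), curve.interface_name)
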