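"""Coarse estimation of the air–epithelium interface.

Layer boundaries in corneal OCT show up as over-exposed bright bands, so each
A-scan is reduced to its strict local maxima and pairs of candidate peaks are
scored with the boundary function

    G = |I(y1) - I(y2)|  -  min_{mu in [y1, y2]} I(mu),

i.e. the intensity contrast between the two boundary pixels minus the darkest
intensity of the valley between them.  Only peaks reaching a configurable
fraction of their A-scan maximum participate (the brightest OCT response sits
near the corneal boundary, not in background noise), and pair separations are
limited to a thickness-derived window.  The winning pair's shallower member
marks the anterior band; a second-order polynomial fit with outlier rejection
then turns the per-column picks into a smooth coarse boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import (
    BScanImage,
    BoundaryCurve,
    InvalidInputError,
    SegConfig,
)
from .preprocess import ArtifactReport

__all__ = [
    "CandidatePair",
    "find_axial_local_maxima",
    "boundary_function_score",
    "coarse_anterior",
    "fit_parabola",
]


@dataclass(frozen=True)
class CandidatePair:
    """A scored pair of candidate boundary pixels in one A-scan."""

    y1: int
    y2: int
    score: float

    def __post_init__(self) -> None:
        if self.y1 >= self.y2:
            raise InvalidInputError("candidate pair requires y1 < y2")

    @property
    def top(self) -> int:
        return min(self.y1, self.y2)


def find_axial_local_maxima(ascan: np.ndarray) -> np.ndarray:
    """Strict interior local maxima of one A-scan, ascending.

    A plateau bordered by strictly smaller neighbours contributes its first
    index as the single candidate (deterministic tie handling).
    """
    a = np.asarray(ascan, dtype=float)
    if a.ndim != 1 or a.size < 3:
        raise InvalidInputError("A-scan must be 1D with length >= 3")
    _, props = find_peaks(a, plateau_size=1)
    return props["left_edges"].astype(int)


def boundary_function_score(ascan: np.ndarray, y1: int, y2: int) -> float:
    """Evaluate the boundary function G for one candidate pair."""
    a = np.asarray(ascan, dtype=float)
    if y1 >= y2:
        raise InvalidInputError("boundary function requires y1 < y2")
    t_plus = abs(a[y1] - a[y2])
    t_minus = a[y1 : y2 + 1].min()
    return float(t_plus - t_minus)


def _best_pair(
    ascan: np.ndarray,
    peaks: np.ndarray,
    sep_lo: int,
    sep_hi: int,
) -> CandidatePair | None:
    """Maximise G over admissible peak pairs; ties prefer the shallower top."""
    best: CandidatePair | None = None
    n = peaks.size
    for i in range(n):
        y1 = int(peaks[i])
        for j in range(i + 1, n):
            y2 = int(peaks[j])
            sep = y2 - y1
            if sep < sep_lo:
                continue
            if sep > sep_hi:
                break
            score = boundary_function_score(ascan, y1, y2)
            if (
                best is None
                or score > best.score
                or (score == best.score and y1 < best.top)
            ):
                best = CandidatePair(y1, y2, score)
    return best


def coarse_anterior(
    image: BScanImage, report: ArtifactReport, cfg: SegConfig
) -> BoundaryCurve:
    """Coarse per-column anterior boundary from the boundary function.

    For every non-excluded column the admissible candidate pairs are scored
    and the winner's top pixel marks the anterior band; the reported position
    is the row just above it (the transition row indexed by the
    forward-difference gradient, the convention used package-wide).  Columns
    inside the flagged central artifact, or with fewer than two candidates,
    are marked invalid rather than guessed.
    """
    px = image.pixels
    y_dim, x_dim = px.shape
    sep_lo = cfg.min_pair_sep_px
    sep_hi = min(cfg.max_pair_sep_px(image.axial_res_um), y_dim - 1)
    excluded = set(report.central_columns)
    positions = np.full(x_dim, np.nan)
    valid = np.zeros(x_dim, dtype=bool)
    for x in range(x_dim):
        if x in excluded:
            continue
        col = px[:, x]
        peaks = find_axial_local_maxima(col)
        lo, hi = col.min(), col.max()
        floor = lo + cfg.min_peak_fraction * (hi - lo)
        if peaks.size:
            peaks = peaks[col[peaks] >= floor]
        if peaks.size < 2:
            continue
        pair = _best_pair(col, peaks, sep_lo, sep_hi)
        if pair is None:
            continue
        # "the top pixel in the axial direction": walk to the top of the
        # over-exposed run the winning candidate belongs to, so a peak in
        # the band interior still yields the band's first bright pixel
        top = pair.top
        while top > 0 and col[top - 1] >= floor:
            top -= 1
        positions[x] = max(0, top - 1)
        valid[x] = True
    return BoundaryCurve(positions, valid, "anterior")


def fit_parabola(
    curve: BoundaryCurve,
) -> tuple[BoundaryCurve, tuple[float, float, float]]:
    """Least-squares second-order polynomial fit with outlier rejection.

    Two passes: fit all valid columns, drop points whose absolute residual
    exceeds three times the median absolute residual, refit.  The returned
    curve evaluates the polynomial at *every* column (so artifact gaps are
    bridged geometrically) while keeping the input validity mask.
    """
    if curve.n_valid < 3:
        raise InvalidInputError("parabola fit needs at least 3 valid columns")
    x = np.flatnonzero(curve.valid).astype(float)
    y = curve.positions[curve.valid]

    def _fit(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        # highest power first, as numpy returns it
        return np.polyfit(xs, ys, 2)

    coeffs = _fit(x, y)
    resid = np.abs(np.polyval(coeffs, x) - y)
    med = np.median(resid)
    keep = resid <= max(3.0 * med, 1e-9)
    if keep.sum() >= 3 and keep.sum() < keep.size:
        coeffs = _fit(x[keep], y[keep])
    cols = np.arange(curve.width, dtype=float)
    fitted = np.clip(np.polyval(coeffs, cols), 0.0, None)
    # the fit bridges every column; callers re-apply artifact exclusions
    out = BoundaryCurve(fitted, np.ones(curve.width, dtype=bool), curve.interface_name)
    a2, a1, a0 = (float(c) for c in coeffs)
    return out, (a0, a1, a2)
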