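"""Pre-processing: region-of-interest cropping and artifact/noise suppression.

Corneal OCT B-scans carry three nuisances on top of speckle: structures above
and below the cornea (air gap, iris), bright horizontal stripes spanning the
full width (a system artifact), and a vertical saturation stripe near the apex
caused by specular reflection.  The pipeline here crops to the cornea using
the apex found in the row-sum profile, mean-centres every row to cancel the
horizontal stripes, flags saturated central A-scans against the peripheral
mean, and finishes with an adaptive (Wiener) denoiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .core import (
    BScanImage,
    InvalidConfigError,
    InvalidInputError,
    SegConfig,
)

__all__ = [
    "ArtifactReport",
    "detect_apex_row",
    "crop_roi",
    "remove_horizontal_artifact",
    "detect_central_artifact",
    "denoise",
    "preprocess_pipeline",
    "PreprocessResult",
]


@dataclass
class ArtifactReport:
    """What the artifact detectors decided for one B-scan.

    ``central_columns`` are image-local column indices of excluded saturated
    A-scans (always inside the middle third), ``peripheral_mean`` the mean
    A-scan intensity of the two outer thirds used as reference.
    """

    central_columns: tuple[int, ...] = ()
    horizontal_corrected: bool = False
    peripheral_mean: float = float("nan")
    threshold_used: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "central_columns": list(self.central_columns),
            "horizontal_corrected": self.horizontal_corrected,
            "peripheral_mean": self.peripheral_mean,
            "threshold_used": self.threshold_used,
        }


def detect_apex_row(image: BScanImage) -> int:
    """Locate the corneal apex via the row-wise intensity summation profile.

    Returns the first row whose summation ``S(y)`` is a strict interior local
    maximum *and* exceeds the mean of ``S`` (the threshold that skips dim
    noise ripples above the cornea).  A plateau bordered by strictly smaller
    neighbours counts as one maximum at its first row — the same convention
    used for A-scan candidate peaks.  When no interior maximum qualifies the
    global argmax of ``S`` is returned.
    """
    if image.height < 3:
        raise InvalidInputError("apex detection needs at least 3 rows")
    s = image.pixels.sum(axis=1)
    thr = s.mean()
    from scipy.signal import find_peaks

    _, props = find_peaks(s, plateau_size=1)
    candidates = props["left_edges"][s[props["left_edges"]] > thr]
    if candidates.size:
        return int(candidates[0])
    return int(np.argmax(s))


def crop_roi(image: BScanImage, apex_row: int, cfg: SegConfig) -> BScanImage:
    """Crop to the corneal region of interest around the apex.

    Keeps rows ``[apex - apex_margin, apex + depth_extent)`` (clamped to the
    frame) and trims ``side_crop`` low-SNR columns from each edge;
    ``crop_offset`` is updated so original coordinates stay recoverable.
    """
    if not (0 <= apex_row < image.height):
        raise InvalidInputError(f"apex_row {apex_row} outside image")
    depth = cfg.resolved_depth_extent(image.axial_res_um)
    side = cfg.resolved_side_crop(image.width)
    r0 = max(0, apex_row - cfg.apex_margin_px)
    r1 = min(image.height, apex_row + depth)
    c0, c1 = side, image.width - side
    if (r1 - r0) < 3 or (c1 - c0) < 3:
        raise InvalidConfigError(
            f"cropped ROI {r1 - r0}x{c1 - c0} is smaller than 3x3"
        )
    off_r, off_c = image.crop_offset
    return BScanImage(
        image.pixels[r0:r1, c0:c1].copy(),
        image.axial_res_um,
        image.lateral_res_um,
        crop_offset=(off_r + r0, off_c + c0),
    )


def remove_horizontal_artifact(image: BScanImage) -> BScanImage:
    """Cancel full-width bright stripes by mean-centring every row.

    Each row has its own mean subtracted, then a single global offset (the
    magnitude of the most negative value) restores non-negativity, so every
    output row ends with the same mean and relative contrasts are untouched.
    Applying the operation twice equals applying it once.
    """
    z = image.pixels - image.pixels.mean(axis=1, keepdims=True)
    out = z - z.min()
    # numerically exact non-negativity; clipping is a no-op except for -0.0
    np.clip(out, 0.0, None, out=out)
    return image.with_pixels(out)


def detect_central_artifact(image: BScanImage, cfg: SegConfig) -> ArtifactReport:
    """Flag saturated A-scans in the central third of the image.

    The frame is split into three equal lateral regions; the mean A-scan
    intensity ``mu`` of the two peripheral regions is the reference, and a
    central column is flagged when its mean exceeds
    ``central_artifact_factor * mu``.  Peripheral columns are never flagged.
    """
    if image.width < 9:
        raise InvalidInputError("central-artifact detection needs width >= 9")
    third = image.width // 3
    col_means = image.pixels.mean(axis=0)
    peripheral = np.concatenate([col_means[:third], col_means[image.width - third :]])
    mu = float(peripheral.mean())
    thr = cfg.central_artifact_factor * mu
    mid = np.arange(third, image.width - third)
    flagged = mid[col_means[mid] > thr]
    return ArtifactReport(
        central_columns=tuple(int(c) for c in flagged),
        peripheral_mean=mu,
        threshold_used=float(thr),
    )


def _local_stats(x: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    m = uniform_filter(x, size=size, mode="reflect")
    m2 = uniform_filter(x * x, size=size, mode="reflect")
    v = np.clip(m2 - m * m, 0.0, None)
    return m, v


def denoise(image: BScanImage, cfg: SegConfig) -> BScanImage:
    """Adaptive (Wiener) denoising with a square window.

    Classic pixel-wise Wiener filter: ``out = m + max(v - n, 0)/v * (x - m)``
    with local window mean ``m`` and variance ``v``.  The global noise power
    ``n`` is estimated as the median of the local variances, which leaves
    genuinely noise-free images untouched and preserves strong edges (their
    local variance dwarfs ``n``).
    """
    if cfg.wiener_window < 3 or cfg.wiener_window % 2 == 0:
        raise InvalidConfigError("wiener_window must be odd and >= 3")
    x = image.pixels
    m, v = _local_stats(x, cfg.wiener_window)
    noise = float(np.median(v))
    gain = np.zeros_like(v)
    np.divide(np.clip(v - noise, 0.0, None), v, out=gain, where=v > 0)
    out = m + gain * (x - m)
    np.clip(out, 0.0, None, out=out)
    return image.with_pixels(out)


@dataclass
class PreprocessResult:
    """Cropped/cleaned image plus everything decided along the way."""

    image: BScanImage
    report: ArtifactReport
    apex_row: int  # in the coordinates of the *input* image


def preprocess_pipeline(image: BScanImage, cfg: SegConfig) -> PreprocessResult:
    """Run apex detection, cropping, artifact removal and denoising in order."""
    apex = detect_apex_row(image)
    roi = crop_roi(image, apex, cfg)
    roi = remove_horizontal_artifact(roi)
    report = detect_central_artifact(roi, cfg)
    report.horizontal_corrected = True
    roi = denoise(roi, cfg)
    return PreprocessResult(image=roi, report=report, apex_row=apex)
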