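"""Shared domain types, coordinate conventions and configuration.

Coordinate convention (used by every module): arrays are indexed
``[row, column]`` with row ``y`` increasing with depth (0 at the top of the
frame) and column ``x`` increasing laterally, both 0-based.  An interface
position is the last row *above* the axial intensity transition, i.e. the row
at which the forward-difference axial gradient of the transition lives.
Indices are converted to 1-based only when written to disk (see
:mod:`cornseg.io`).

Intensities are normalised to ``[0, 1]`` floats on load regardless of the
source bit depth, so every threshold in :class:`SegConfig` lives on that one
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "InvalidInputError",
    "InvalidConfigError",
    "InvalidSpecError",
    "StageError",
    "BScanImage",
    "Volume",
    "BoundaryCurve",
    "BoundarySurface",
    "GradientField",
    "SegConfig",
    "LayerSpec",
]


class InvalidInputError(ValueError):
    """Raised when an operation receives data violating its preconditions."""


class InvalidConfigError(ValueError):
    """Raised when a :class:`SegConfig` (or a derived value) is unusable."""


class InvalidSpecError(ValueError):
    """Raised for an inconsistent phantom specification."""


class StageError(RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")


def _as_float_array(a, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != ndim:
        raise InvalidInputError(f"{name} must be {ndim}-dimensional, got {arr.ndim}")
    return arr


@dataclass
class BScanImage:
    """A 2D OCT cross-section: intensity grid plus pixel-resolution metadata.

    Parameters
    ----------
    pixels
        Non-negative intensity grid, shape ``(Y, X)`` = (depth, width).
    axial_res_um, lateral_res_um
        Physical size of one pixel in micrometres along depth / width.
    crop_offset
        ``(row, col)`` position of this image inside its source frame, so
        cropped results can be mapped back to original coordinates.
    """

    pixels: np.ndarray
    axial_res_um: float
    lateral_res_um: float
    crop_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.pixels = _as_float_array(self.pixels, "pixels", 2)
        if self.height < 3 or self.width < 3:
            raise InvalidInputError(
                f"image must be at least 3x3, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError("image intensities must be finite")
        if self.pixels.min() < 0:
            raise InvalidInputError("image intensities must be non-negative")
        if self.axial_res_um <= 0 or self.lateral_res_um <= 0:
            raise InvalidInputError("pixel resolutions must be positive")
        r, c = self.crop_offset
        if r < 0 or c < 0:
            raise InvalidInputError("crop_offset components must be >= 0")
        self.crop_offset = (int(r), int(c))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_raw(
        cls,
        raw: np.ndarray,
        axial_res_um: float,
        lateral_res_um: float,
    ) -> "BScanImage":
        """Build from a raw (possibly integer) grayscale array.

        Integer inputs are scaled by the full range of their dtype so 8- and
        16-bit sources share one code path; float inputs are clipped to be
        non-negative and rescaled by their max if it exceeds 1.
        """
        raw = np.asarray(raw)
        if np.issubdtype(raw.dtype, np.integer):
            info = np.iinfo(raw.dtype)
            pixels = raw.astype(float) / float(info.max)
        else:
            pixels = np.clip(raw.astype(float), 0.0, None)
            top = pixels.max()
            if top > 1.0:
                pixels = pixels / top
        return cls(pixels, axial_res_um, lateral_res_um)

    def with_pixels(self, pixels: np.ndarray) -> "BScanImage":
        return replace(self, pixels=pixels)


@dataclass
class Volume:
    """An ordered stack of B-scans sharing shape and resolution."""

    frames: list[BScanImage]
    slice_gap_um: float

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise InvalidInputError("a volume needs at least one frame")
        first = self.frames[0]
        for f in self.frames[1:]:
            if f.pixels.shape != first.pixels.shape:
                raise InvalidInputError("all frames must share the same shape")
            if (f.axial_res_um, f.lateral_res_um) != (
                first.axial_res_um,
                first.lateral_res_um,
            ):
                raise InvalidInputError("all frames must share pixel resolutions")
        if self.slice_gap_um <= 0:
            raise InvalidInputError("slice_gap_um must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_frames, self.frames[0].height, self.frames[0].width)

    def as_array(self) -> np.ndarray:
        """Stack frame pixels into a ``(frames, depth, width)`` array."""
        return np.stack([f.pixels for f in self.frames], axis=0)


#: Sentinel stored at invalid columns of a curve / surface.
INVALID_POSITION = np.nan


@dataclass
class BoundaryCurve:
    """Per-column axial positions of one interface in one B-scan.

    Invalid columns (e.g. inside an excluded central artifact) carry NaN in
    ``positions`` and ``False`` in ``valid``; they are never interpreted as
    coordinates downstream.
    """

    positions: np.ndarray
    valid: np.ndarray
    interface_name: str = "other"

    def __post_init__(self) -> None:
        self.positions = _as_float_array(self.positions, "positions", 1)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.positions.shape:
            raise InvalidInputError("positions and valid must have equal length")
        # normalise the sentinel: invalid columns always hold NaN
        self.positions = np.where(self.valid, self.positions, INVALID_POSITION)
        ok = self.positions[self.valid]
        if ok.size and (not np.all(np.isfinite(ok)) or ok.min() < 0):
            raise InvalidInputError("valid positions must be finite and >= 0")

    @property
    def width(self) -> int:
        return self.positions.size

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def shifted(self, rows: float) -> "BoundaryCurve":
        """Return a copy moved ``rows`` deeper (negative = shallower)."""
        pos = np.where(self.valid, self.positions + rows, INVALID_POSITION)
        return BoundaryCurve(pos, self.valid.copy(), self.interface_name)

    def embedded(self, width: int, col_offset: int, row_offset: float) -> "BoundaryCurve":
        """Map a curve on a cropped image back into original coordinates."""
        if col_offset < 0 or col_offset + self.width > width:
            raise InvalidInputError("curve does not fit in the requested width")
        pos = np.full(width, INVALID_POSITION)
        val = np.zeros(width, dtype=bool)
        sl = slice(col_offset, col_offset + self.width)
        pos[sl] = np.where(self.valid, self.positions + row_offset, INVALID_POSITION)
        val[sl] = self.valid
        return BoundaryCurve(pos, val, self.interface_name)

    def interpolate_gaps(self) -> "BoundaryCurve":
        """Optionally fill invalid columns by linear interpolation.

        Exterior invalid columns (before the first / after the last valid
        column) stay invalid; only interior gaps are bridged.
        """
        if self.n_valid < 2:
            return BoundaryCurve(self.positions.copy(), self.valid.copy(), self.interface_name)
        cols = np.flatnonzero(self.valid)
        pos = self.positions.copy()
        val = self.valid.copy()
        lo, hi = cols[0], cols[-1]
        gap = np.arange(lo, hi + 1)
        inner = gap[~self.valid[lo : hi + 1]]
        if inner.size:
            pos[inner] = np.interp(inner, cols, self.positions[cols])
            val[inner] = True
        return BoundaryCurve(pos, val, self.interface_name)


@dataclass
class BoundarySurface:
    """Per-(frame, column) axial heights of one interface in a volume."""

    heights: np.ndarray
    valid: np.ndarray
    interface_name: str = "other"

    def __post_init__(self) -> None:
        self.heights = _as_float_array(self.heights, "heights", 2)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.heights.shape:
            raise InvalidInputError("heights and valid must share a shape")
        self.heights = np.where(self.valid, self.heights, INVALID_POSITION)
        ok = self.heights[self.valid]
        if ok.size and (not np.all(np.isfinite(ok)) or ok.min() < 0):
            raise InvalidInputError("valid heights must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def frame_curve(self, frame: int) -> BoundaryCurve:
        return BoundaryCurve(
            self.heights[frame].copy(), self.valid[frame].copy(), self.interface_name
        )


@dataclass
class GradientField:
    """Axial forward-difference gradient of a B-scan (same shape)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "values", 2)
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("gradient values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class LayerSpec:
    """One deeper interface to extract: name + axial search band below the
    anterior surface, in micrometres (converted to pixels per image)."""

    name: str
    min_depth_um: float
    max_depth_um: float

    def shift_range_px(self, axial_res_um: float) -> tuple[int, int]:
        lo = max(1, math.ceil(self.min_depth_um / axial_res_um))
        hi = math.ceil(self.max_depth_um / axial_res_um)
        if hi < lo:
            raise InvalidConfigError(
                f"layer '{self.name}': empty shift range at {axial_res_um} um/px"
            )
        return lo, hi


DEFAULT_LAYERS: tuple[LayerSpec, ...] = (
    LayerSpec("epithelium_stroma", 30.0, 120.0),
    LayerSpec("posterior", 300.0, 1200.0),
)


@dataclass
class SegConfig:
    """All tunable parameters of the segmentation pipeline.

    Lengths are pixels unless suffixed ``_um``; ``None`` means "derive from
    the image" (documented per field).

    Attributes
    ----------
    apex_margin_px
        Rows kept above the detected apex before cropping (default 15).
    depth_extent_px
        Rows kept below the apex.  ``None`` derives ``ceil(1.5 mm / axial
        resolution)`` — comfortably more than corneal thickness plus sag.
    side_crop_px
        Columns removed from each lateral edge. ``None`` derives ``X // 16``.
    central_artifact_factor
        A middle-third column is flagged as saturated when its mean exceeds
        this multiple of the peripheral-thirds mean (default 4/3).
    wiener_window
        Square window of the adaptive Wiener denoiser (odd, default 5).
    decay_p
        Geometric-decay constant ``w(d) = p (1-p)^d`` used while refining
        (default 0.5).
    search_radius_px
        Half-width of the axial search window during refinement (default 5).
    sg_order, sg_window
        Savitzky–Golay smoothing of the refined anterior curve (1, 21).
    layer_p_min, layer_p_max
        End points of the centre-to-periphery linear growth of ``p`` used for
        deeper-layer refinement.
    min_pair_sep_px / max_pair_sep_um
        Allowed axial separation of a candidate pair in the coarse boundary
        function (thickness-derived window).
    min_peak_fraction
        A local maximum only becomes a boundary-pixel candidate when it
        reaches this fraction of its A-scan maximum — the prior that the
        brightest response sits near the corneal boundary.
    layers
        Deeper interfaces to extract below the anterior surface.
    median_window / median3d_window
        Median smoothing widths for non-parametric curves / surface height
        maps.
    interpolate_gaps
        Fill artifact-excluded columns by linear interpolation in the final
        output (off by default: excluded stays excluded).
    rng_seed
        Recorded for provenance; the segmentation itself is deterministic.
    """

    apex_margin_px: int = 15
    depth_extent_px: int | None = None
    side_crop_px: int | None = None
    central_artifact_factor: float = 4.0 / 3.0
    wiener_window: int = 5
    decay_p: float = 0.5
    search_radius_px: int = 5
    sg_order: int = 1
    sg_window: int = 21
    layer_p_min: float = 0.3
    layer_p_max: float = 0.9
    min_pair_sep_px: int = 2
    max_pair_sep_um: float = 1200.0
    min_peak_fraction: float = 0.5
    layers: tuple[LayerSpec, ...] = DEFAULT_LAYERS
    median_window: int = 5
    median3d_window: int = 3
    interpolate_gaps: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.apex_margin_px < 0:
            raise InvalidConfigError("apex_margin_px must be >= 0")
        if self.depth_extent_px is not None and self.depth_extent_px <= 0:
            raise InvalidConfigError("depth_extent_px must be positive")
        if self.side_crop_px is not None and self.side_crop_px < 0:
            raise InvalidConfigError("side_crop_px must be >= 0")
        if self.central_artifact_factor <= 1:
            raise InvalidConfigError("central_artifact_factor must exceed 1")
        if self.wiener_window < 3 or self.wiener_window % 2 == 0:
            raise InvalidConfigError("wiener_window must be odd and >= 3")
        if not (0 < self.decay_p < 1):
            raise InvalidConfigError("decay_p must lie in (0, 1)")
        if self.search_radius_px < 0:
            raise InvalidConfigError("search_radius_px must be >= 0")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise InvalidConfigError("sg_window must be odd and exceed sg_order")
        if not (0 < self.layer_p_min <= self.layer_p_max < 1):
            raise InvalidConfigError("need 0 < layer_p_min <= layer_p_max < 1")
        if self.min_pair_sep_px < 1:
            raise InvalidConfigError("min_pair_sep_px must be >= 1")
        if not (0 <= self.min_peak_fraction < 1):
            raise InvalidConfigError("min_peak_fraction must lie in [0, 1)")
        if self.median_window % 2 == 0 or self.median3d_window % 2 == 0:
            raise InvalidConfigError("median windows must be odd")
        self.layers = tuple(
            l if isinstance(l, LayerSpec) else LayerSpec(*l) for l in self.layers
        )

    # ---- derived, image-dependent values -------------------------------
    def resolved_depth_extent(self, axial_res_um: float) -> int:
        if self.depth_extent_px is not None:
            return self.depth_extent_px
        return math.ceil(1500.0 / axial_res_um)

    def resolved_side_crop(self, width: int) -> int:
        if self.side_crop_px is not None:
            return self.side_crop_px
        return width // 16

    def max_pair_sep_px(self, axial_res_um: float) -> int:
        return math.ceil(self.max_pair_sep_um / axial_res_um)

    # ---- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "layers"
        }
        d["layers"] = [
            {"name": l.name, "min_depth_um": l.min_depth_um, "max_depth_um": l.max_depth_um}
            for l in self.layers
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SegConfig":
        d = dict(d)
        if "layers" in d and d["layers"] is not None:
            d["layers"] = tuple(
                LayerSpec(**l) if isinstance(l, dict) else LayerSpec(*l)
                for l in d["layers"]
            )
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)
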