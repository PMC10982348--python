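"""File I/O: grayscale images, boundary/surface CSVs, JSON sidecars.

Disk formats are 1-based (matching common annotation tools); in-memory
structures are 0-based.  The conversion happens only here.  Floats are
written with ``repr`` so a round-trip through CSV is bit-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from .core import (
    BScanImage,
    BoundaryCurve,
    BoundarySurface,
    InvalidInputError,
    SegConfig,
    Volume,
)

__all__ = [
    "read_bscan",
    "read_volume",
    "write_bscan_tiff",
    "write_volume_tiff",
    "write_boundary_csv",
    "read_boundary_csv",
    "write_surface_csv",
    "read_surface_csv",
    "write_sidecar",
]

_CONVENTION = (
    "# coordinates: 1-based; row/axial index increases with depth (top = 1); "
    "column index increases laterally (left = 1); invalid positions are empty"
)


def read_bscan(path: str | Path, axial_res_um: float, lateral_res_um: float) -> BScanImage:
    """Read a grayscale PNG/TIFF into a normalised B-scan."""
    raw = iio.imread(Path(path))
    if raw.ndim == 3:  # collapse an (accidentally) colour image
        raw = raw.mean(axis=-1).astype(raw.dtype)
    return BScanImage.from_raw(raw, axial_res_um, lateral_res_um)


def read_volume(
    path: str | Path,
    axial_res_um: float,
    lateral_res_um: float,
    slice_gap_um: float,
) -> Volume:
    """Read a multi-page TIFF, or a directory of ordered grayscale images."""
    p = Path(path)
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise InvalidInputError(f"no image files found in {p}")
        frames = [read_bscan(f, axial_res_um, lateral_res_um) for f in files]
    else:
        stack = tifffile.imread(p)
        if stack.ndim == 2:
            stack = stack[None]
        frames = [
            BScanImage.from_raw(stack[i], axial_res_um, lateral_res_um)
            for i in range(stack.shape[0])
        ]
    return Volume(frames, slice_gap_um)


def write_bscan_tiff(image: BScanImage, path: str | Path) -> None:
    """Write normalised intensities as 16-bit grayscale TIFF."""
    arr = np.clip(image.pixels, 0.0, 1.0)
    tifffile.imwrite(Path(path), (arr * 65535).astype(np.uint16))


def write_volume_tiff(volume: Volume, path: str | Path) -> None:
    arr = np.clip(volume.as_array(), 0.0, 1.0)
    tifffile.imwrite(Path(path), (arr * 65535).astype(np.uint16))


# ---------------------------------------------------------------------------
# boundary curves
# ---------------------------------------------------------------------------

def write_boundary_csv(curves: list[BoundaryCurve], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_CONVENTION + "\n")
        writer = csv.writer(fh)
        writer.writerow(["column_index", "interface_name", "axial_position", "valid"])
        for curve in curves:
            for x in range(curve.width):
                ok = bool(curve.valid[x])
                writer.writerow(
                    [
                        x + 1,
                        curve.interface_name,
                        repr(float(curve.positions[x] + 1)) if ok else "",
                        int(ok),
                    ]
                )


def read_boundary_csv(path: str | Path) -> list[BoundaryCurve]:
    groups: dict[str, dict[int, tuple[float, bool]]] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    header, body = rows[0], rows[1:]
    if header[:4] != ["column_index", "interface_name", "axial_position", "valid"]:
        raise InvalidInputError(f"unrecognised boundary CSV header in {path}")
    for col, name, pos, ok in body:
        groups.setdefault(name, {})[int(col) - 1] = (
            float(pos) - 1 if pos else np.nan,
            bool(int(ok)),
        )
    curves = []
    for name, cols in groups.items():
        width = max(cols) + 1
        positions = np.full(width, np.nan)
        valid = np.zeros(width, dtype=bool)
        for c, (p, ok) in cols.items():
            positions[c] = p
            valid[c] = ok
        curves.append(BoundaryCurve(positions, valid, name))
    return curves


# ---------------------------------------------------------------------------
# surfaces (long format)
# ---------------------------------------------------------------------------

def write_surface_csv(surfaces: list[BoundarySurface], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_CONVENTION + "\n")
        writer = csv.writer(fh)
        writer.writerow(
            ["frame_index", "column_index", "interface_name", "height", "valid"]
        )
        for s in surfaces:
            n_frames, width = s.shape
            for f in range(n_frames):
                for x in range(width):
                    ok = bool(s.valid[f, x])
                    writer.writerow(
                        [
                            f + 1,
                            x + 1,
                            s.interface_name,
                            repr(float(s.heights[f, x] + 1)) if ok else "",
                            int(ok),
                        ]
                    )


def read_surface_csv(path: str | Path) -> list[BoundarySurface]:
    entries: dict[str, dict[tuple[int, int], tuple[float, bool]]] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    header, body = rows[0], rows[1:]
    expected = ["frame_index", "column_index", "interface_name", "height", "valid"]
    if header[:5] != expected:
        raise InvalidInputError(f"unrecognised surface CSV header in {path}")
    for f, c, name, h, ok in body:
        entries.setdefault(name, {})[(int(f) - 1, int(c) - 1)] = (
            float(h) - 1 if h else np.nan,
            bool(int(ok)),
        )
    surfaces = []
    for name, cells in entries.items():
        n_frames = max(k[0] for k in cells) + 1
        width = max(k[1] for k in cells) + 1
        heights = np.full((n_frames, width), np.nan)
        valid = np.zeros((n_frames, width), dtype=bool)
        for (f, c), (h, ok) in cells.items():
            heights[f, c] = h
            valid[f, c] = ok
        surfaces.append(BoundarySurface(heights, valid, name))
    return surfaces


def write_sidecar(
    path: str | Path,
    cfg: SegConfig,
    crop_offset: tuple[int, int] | None = None,
    artifact_report: dict | None = None,
) -> None:
    """JSON sidecar carrying the configuration and crop provenance."""
    payload: dict = {"seg_config": cfg.to_dict()}
    if crop_offset is not None:
        payload["crop_offset"] = list(crop_offset)
    if artifact_report is not None:
        payload["artifact_report"] = artifact_report
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
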