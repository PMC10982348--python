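"""Mean unsigned surface positioning error (MSPE) against ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoundaryCurve, BoundarySurface, InvalidInputError

__all__ = ["MSPEResult", "mspe", "mspe_surface"]


@dataclass
class MSPEResult:
    """Per-interface positioning error summary.

    Errors are computed in pixels over positions valid in both inputs; the
    micrometre value is derived via the axial resolution.  ``std_px`` is the
    spread across the evaluated positions (an image-level spread across scans
    is obtained by aggregating several results).
    """

    mean_px: float
    std_px: float
    mean_um: float
    n_columns: int
    per_column_errors: np.ndarray

    def to_dict(self) -> dict:
        return {
            "mean_px": self.mean_px,
            "std_px": self.std_px,
            "mean_um": self.mean_um,
            "n_columns": self.n_columns,
        }


def _errors(seg_pos, seg_valid, truth_pos, truth_valid) -> np.ndarray:
    if seg_pos.shape != truth_pos.shape:
        raise InvalidInputError(
            f"shape mismatch: {seg_pos.shape} vs {truth_pos.shape}"
        )
    both = seg_valid & truth_valid
    if not both.any():
        raise InvalidInputError("no positions valid in both inputs")
    return np.abs(seg_pos[both] - truth_pos[both])


def _result(err: np.ndarray, axial_res_um: float) -> MSPEResult:
    mean = float(err.mean())
    return MSPEResult(
        mean_px=mean,
        std_px=float(err.std()),
        mean_um=mean * axial_res_um,
        n_columns=int(err.size),
        per_column_errors=err,
    )


def mspe(
    seg: BoundaryCurve, truth: BoundaryCurve, axial_res_um: float = 1.0
) -> MSPEResult:
    """MSPE between a segmented curve and a reference curve."""
    err = _errors(seg.positions, seg.valid, truth.positions, truth.valid)
    return _result(err, axial_res_um)


def mspe_surface(
    seg: BoundarySurface, truth: BoundarySurface, axial_res_um: float = 1.0
) -> MSPEResult:
    """MSPE between a segmented surface and a reference surface."""
    err = _errors(seg.heights, seg.valid, truth.heights, truth.valid)
    return _result(err, axial_res_um)
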