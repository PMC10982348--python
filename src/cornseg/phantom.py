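"""Synthetic corneal OCT phantoms with analytically known ground truth.

The generator renders the intensity structure the segmentation relies on —
over-exposed bright bands at each interface, dimmer tissue fill between them,
dark background above the cornea and in the aqueous below — from closed-form
interface geometry (quadratic sag plus an optional sinusoidal perturbation so
the boundary is *not* a polynomial and refinement is genuinely exercised).
OCT-like degradations are parameterised: multiplicative log-normal speckle,
additive Gaussian noise, lateral contrast falloff (quadratic toward the
edges, emulating peripheral SNR loss), and the two artifact types seen in
clinical scans (a full-width horizontal stripe and a vertical central
saturation region).

Ground truth is computed from the analytic geometry directly and shares no
code path with the segmentation modules.  Reported truth rows follow the
package-wide convention: an interface position is the last row above the
intensity transition; the bright band occupies the rows immediately below it.
Because images are rendered on the pixel grid, the reported truth is the
pixel-quantised boundary actually present in the image (the analytic
sub-pixel curve is available via :meth:`PhantomSpec.analytic_depths`).

Artifacts are injected *after* noise, so two specs differing only in their
artifact fields produce pixel-identical images elsewhere — the basis of the
paired artifact-robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    BScanImage,
    BoundaryCurve,
    BoundarySurface,
    InvalidSpecError,
    Volume,
)

__all__ = [
    "InterfaceModel",
    "PhantomSpec",
    "make_phantom_2d",
    "make_phantom_3d",
    "clean_phantom_spec",
    "noisy_phantom_spec",
    "volume_phantom_spec",
]


@dataclass(frozen=True)
class InterfaceModel:
    """Analytic geometry and brightness of one rendered interface.

    Depth of the interface at normalised lateral position ``u`` in [-1, 1]
    (and normalised frame position ``v`` for volumes)::

        t(u, v) = base_depth_px + curvature_px * u**2
                  + frame_curvature_px * v**2
                  + perturb_amp_px * sin(2 pi x / perturb_period_px + phase)

    ``curvature_px`` is the sag at the lateral edge, in pixels.
    """

    name: str
    base_depth_px: float
    curvature_px: float = 0.0
    frame_curvature_px: float = 0.0
    perturb_amp_px: float = 0.0
    perturb_period_px: float = 200.0
    perturb_phase: float = 0.0
    band_brightness: float = 0.9
    band_taper: float | None = None  # None -> PhantomSpec.band_taper
    band_flat_px: int = 0  # rows at full brightness before the taper begins


_DEFAULT_INTERFACES: tuple[InterfaceModel, ...] = (
    InterfaceModel("anterior", 80.0, 8.0, band_brightness=0.95),
    InterfaceModel("epithelium_stroma", 92.0, 10.0, band_brightness=0.65),
    InterfaceModel("posterior", 210.0, 14.0, band_brightness=0.45),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for synthetic B-scans / volumes.

    Defaults mirror a desk-scale anterior-segment scan: 256 A-scans, 400
    depth pixels at 5 um axial / 60 um lateral resolution, epithelium about
    60 um (12 px) thick and the posterior surface about 650 um (130 px) below
    the anterior, slightly thicker toward the periphery.
    """

    width: int = 256
    height: int = 400
    n_frames: int = 1
    interfaces: tuple[InterfaceModel, ...] = _DEFAULT_INTERFACES
    band_width_px: int = 4
    band_taper: float = 0.5
    tissue_intensity: float = 0.22
    background_intensity: float = 0.05
    speckle_sigma: float = 0.0
    gaussian_sigma: float = 0.0
    peripheral_snr_decay: float = 0.0
    horizontal_stripe: tuple[int, float] | None = None
    central_artifact: tuple[tuple[int, ...], float] | None = None
    replicate_frames: bool = False
    axial_res_um: float = 5.0
    lateral_res_um: float = 60.0
    slice_gap_um: float = 20.0
    rng_seed: int = 0

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        if self.width < 9 or self.height < 9:
            raise InvalidSpecError("phantom must be at least 9x9")
        if not self.interfaces:
            raise InvalidSpecError("at least one interface is required")
        if self.band_width_px < 1:
            raise InvalidSpecError("band_width_px must be >= 1")
        if not (0.0 <= self.band_taper < 1.0):
            raise InvalidSpecError("band_taper must lie in [0, 1)")
        if self.speckle_sigma < 0 or self.gaussian_sigma < 0:
            raise InvalidSpecError("noise levels must be >= 0")
        if self.peripheral_snr_decay < 0:
            raise InvalidSpecError("peripheral_snr_decay must be >= 0")
        if self.central_artifact is not None:
            cols, _amp = self.central_artifact
            third = self.width // 3
            for c in cols:
                if not (third <= c < self.width - third):
                    raise InvalidSpecError(
                        f"central_artifact column {c} outside the middle third"
                    )

    def analytic_depths(self, frame: int = 0) -> np.ndarray:
        """Sub-pixel interface depths, shape ``(n_interfaces, width)``."""
        x = np.arange(self.width)
        u = (x - (self.width - 1) / 2.0) / ((self.width - 1) / 2.0)
        if self.n_frames > 1:
            v = (frame - (self.n_frames - 1) / 2.0) / ((self.n_frames - 1) / 2.0)
        else:
            v = 0.0
        rows = []
        for m in self.interfaces:
            t = (
                m.base_depth_px
                + m.curvature_px * u**2
                + m.frame_curvature_px * v**2
                + m.perturb_amp_px
                * np.sin(2.0 * np.pi * x / m.perturb_period_px + m.perturb_phase)
            )
            rows.append(t)
        return np.asarray(rows)

    def truth_edges(self, frame: int = 0) -> np.ndarray:
        """Pixel-grid truth: the rendered transition row of each interface."""
        return np.rint(self.analytic_depths(frame))


def _render_clean_frame(spec: PhantomSpec, edges: np.ndarray) -> np.ndarray:
    """Noise-free intensity frame from integer interface edge rows."""
    y_dim, x_dim = spec.height, spec.width
    n_if, bw = edges.shape[0], spec.band_width_px
    if edges.min() < 1 or edges.max() + bw > y_dim - 1:
        raise InvalidSpecError(
            "interfaces (incl. band_width_px) must stay inside the frame; "
            "adjust base_depth_px / height"
        )
    seps = np.diff(edges, axis=0)
    if n_if > 1 and seps.min() < 2:
        raise InvalidSpecError("interfaces must stay depth-ordered with >= 2 px gaps")

    img = np.full((y_dim, x_dim), spec.background_intensity)
    rows = np.arange(y_dim)[:, None]
    # tissue fill between consecutive interfaces (band regions overwritten next)
    for i in range(n_if - 1):
        in_tissue = (rows > edges[i]) & (rows <= edges[i + 1])
        img[in_tissue] = spec.tissue_intensity
    # bright bands: brightest at the top row, tapering downward so the upper
    # transition always carries the strongest gradient
    cols = np.arange(x_dim)
    for i in range(n_if):
        m = spec.interfaces[i]
        b = m.band_brightness
        taper = m.band_taper if m.band_taper is not None else spec.band_taper
        flat = min(m.band_flat_px, bw)
        for k in range(bw):
            if k < flat:
                level = b
            elif flat > 0:
                level = b * (1.0 - taper * (k - flat + 1) / (bw - flat))
            else:
                level = b * (1.0 - taper * k / max(bw - 1, 1))
            img[edges[i] + 1 + k, cols] = level
    return img


def _apply_degradations(
    img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    x_dim = spec.width
    u = (np.arange(x_dim) - (x_dim - 1) / 2.0) / ((x_dim - 1) / 2.0)
    if spec.peripheral_snr_decay > 0:
        contrast = 1.0 - spec.peripheral_snr_decay * u**2
        img = spec.background_intensity + (img - spec.background_intensity) * contrast
    if spec.speckle_sigma > 0:
        s = spec.speckle_sigma
        img = img * np.exp(rng.standard_normal(img.shape) * s - s * s / 2.0)
    if spec.gaussian_sigma > 0:
        img = img + rng.standard_normal(img.shape) * spec.gaussian_sigma
    return np.clip(img, 0.0, 1.0)


def _inject_artifacts(img: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.horizontal_stripe is not None:
        row, amp = spec.horizontal_stripe
        img = img.copy()
        img[int(row), :] += amp
    if spec.central_artifact is not None:
        cols, amp = spec.central_artifact
        img = img.copy()
        img[:, list(cols)] = amp
    return np.clip(img, 0.0, 1.0)


def make_phantom_2d(spec: PhantomSpec) -> tuple[BScanImage, list[BoundaryCurve]]:
    """Render one synthetic B-scan and its ground-truth boundary curves."""
    spec._validate()
    rng = np.random.default_rng(spec.rng_seed)
    edges = spec.truth_edges(frame=0)
    img = _render_clean_frame(spec, edges.astype(int))
    img = _apply_degradations(img, spec, rng)
    img = _inject_artifacts(img, spec)
    image = BScanImage(img, spec.axial_res_um, spec.lateral_res_um)
    truth = [
        BoundaryCurve(
            edges[i].astype(float),
            np.ones(spec.width, dtype=bool),
            spec.interfaces[i].name,
        )
        for i in range(len(spec.interfaces))
    ]
    return image, truth


def make_phantom_3d(spec: PhantomSpec) -> tuple[Volume, list[BoundarySurface]]:
    """Render a volume of B-scans with smoothly varying surface geometry.

    With ``replicate_frames`` the first frame (including its noise) is tiled,
    which yields a translation-invariant volume for 2D/3D consistency checks.
    """
    spec._validate()
    if spec.n_frames < 1:
        raise InvalidSpecError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.rng_seed)
    frames: list[BScanImage] = []
    heights = np.empty((spec.n_frames, len(spec.interfaces), spec.width))

    if spec.replicate_frames:
        edges = spec.truth_edges(frame=0)
        img = _render_clean_frame(spec, edges.astype(int))
        img = _apply_degradations(img, spec, rng)
        img = _inject_artifacts(img, spec)
        for f in range(spec.n_frames):
            frames.append(BScanImage(img.copy(), spec.axial_res_um, spec.lateral_res_um))
            heights[f] = edges
    else:
        for f in range(spec.n_frames):
            edges = spec.truth_edges(frame=f)
            img = _render_clean_frame(spec, edges.astype(int))
            img = _apply_degradations(img, spec, rng)
            img = _inject_artifacts(img, spec)
            frames.append(BScanImage(img, spec.axial_res_um, spec.lateral_res_um))
            heights[f] = edges

    volume = Volume(frames, spec.slice_gap_um)
    surfaces = [
        BoundarySurface(
            heights[:, i, :].copy(),
            np.ones((spec.n_frames, spec.width), dtype=bool),
            spec.interfaces[i].name,
        )
        for i in range(len(spec.interfaces))
    ]
    return volume, surfaces


# ----------------------------------------------------------------------
# Canonical study specifications used by the test-bench and the
# reproduction script.  The perturbation wavelength/phase of the clean
# phantom are chosen so the pixel-quantised boundary is a fixed point of
# the pipeline's final smoothing (see the methods note); the noisy spec
# uses the speckle level and peripheral falloff of the synthetic study
# conditions.
# ----------------------------------------------------------------------

def _study_interfaces(perturb_amp: float = 1.5) -> tuple[InterfaceModel, ...]:
    common = dict(perturb_period_px=180.0, perturb_phase=0.4, perturb_amp_px=perturb_amp)
    return (
        InterfaceModel("anterior", 80.0, 8.0, band_brightness=0.95, **common),
        InterfaceModel("epithelium_stroma", 92.0, 10.0, band_brightness=0.65, **common),
        InterfaceModel("posterior", 210.0, 14.0, band_brightness=0.45, **common),
    )


def clean_phantom_spec(seed: int = 1) -> PhantomSpec:
    """Noiseless three-interface B-scan with a non-polynomial boundary."""
    return PhantomSpec(interfaces=_study_interfaces(), rng_seed=seed)


def noisy_phantom_spec(
    seed: int,
    speckle_sigma: float = 0.15,
    peripheral_snr_decay: float = 0.5,
) -> PhantomSpec:
    """Speckled, peripherally dimmed three-interface B-scan."""
    return PhantomSpec(
        interfaces=_study_interfaces(),
        speckle_sigma=speckle_sigma,
        gaussian_sigma=0.01,
        peripheral_snr_decay=peripheral_snr_decay,
        rng_seed=seed,
    )


def volume_phantom_spec(
    seed: int = 0,
    n_frames: int = 20,
    width: int = 64,
    height: int = 300,
    speckle_sigma: float = 0.1,
    replicate_frames: bool = False,
) -> PhantomSpec:
    """Desk-scale volume: paraboloid surfaces over frames and columns."""
    common = dict(perturb_period_px=64.0, perturb_phase=0.9, perturb_amp_px=1.5)
    interfaces = (
        InterfaceModel("anterior", 50.0, 6.0, 8.0, band_brightness=0.95, **common),
        InterfaceModel("epithelium_stroma", 62.0, 7.0, 8.0, band_brightness=0.65, **common),
        InterfaceModel("posterior", 180.0, 9.0, 8.0, band_brightness=0.45, **common),
    )
    return PhantomSpec(
        width=width,
        height=height,
        n_frames=n_frames,
        interfaces=interfaces,
        speckle_sigma=speckle_sigma,
        gaussian_sigma=0.01 if speckle_sigma > 0 else 0.0,
        replicate_frames=replicate_frames,
        rng_seed=seed,
    )
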