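# cornseg

Automatic segmentation of corneal layer interfaces in anterior-segment OCT
images — 2D B-scans and 3D volumes.

Corneal OCT shows each layer interface (air–epithelium, epithelium–stroma,
endothelium–aqueous) as an over-exposed bright band, but clinical scans also
carry speckle, low signal at the lateral periphery, bright horizontal stripe
artifacts and a vertical saturation stripe at the apex. `cornseg` extracts
the interfaces with a two-stage, gradient-based approach that needs no
training data and runs in well under a second per B-scan:

1. **Coarse estimation.** Each A-scan is reduced to its local-maximum
   candidate pixels and pairs (y₁, y₂) are scored with the boundary function

   *G = |I(x, y₁) − I(x, y₂)| − min\_{μ∈[y₁,y₂]} I(x, μ)*,

   the intensity contrast between two candidate boundary pixels minus the
   darkest valley between them. The winning pair's top pixel marks the
   anterior surface; a second-order polynomial fit with outlier rejection
   smooths the per-column picks.
2. **Refinement.** The boundary is snapped to the strongest absolute axial
   forward-difference gradient, |∂I/∂y| with ∂I/∂y = (I(x,y+1) − I(x,y))/2,
   inside a ±5-pixel window. Starting from the image centre (highest SNR)
   and walking outward, each candidate offset is scored by its own gradient
   plus the gradient of the rigidly shifted, already-committed boundary,
   weighted by a geometric decay *w(d) = p(1−p)^d* — distant columns count
   exponentially less. A Savitzky–Golay filter (order 1, 21 columns)
   smooths the final anterior curve.
3. **Deeper interfaces** are estimated by shifting the refined anterior
   profile downward to the shift μ* = argmax\_{μ∈S} Σₓ |g(x, f(x)+μ)| in a
   thickness-derived band S, then refined twice: once with a decay constant
   growing linearly from centre to periphery (the periphery explores more),
   once with a constant low decay for smoothing, followed by a median
   filter.
4. **3D volumes** are segmented directly: per-frame boundary-function
   candidates are pooled into a quadratic surface fit, refined greedily in
   order of city-block geodesic distance from the corneal centre, and
   deeper surfaces are found with the 3D analogue of the shift estimator.

Accuracy is quantified as the mean unsigned surface positioning error
(MSPE): the mean absolute axial distance, in pixels (and µm via the axial
resolution), between a segmented and a reference boundary over mutually
valid columns.

A synthetic phantom generator with analytically known ground truth stands in
for clinical data, so the entire pipeline is exercisable and testable
offline.

## Worked example

```python
from cornseg import noisy_phantom_spec, make_phantom_2d, segment_bscan, mspe

spec = noisy_phantom_spec(seed=7)          # speckle + peripheral SNR falloff
image, truth = make_phantom_2d(spec)       # 256 x 400 B-scan, 3 interfaces
curves = segment_bscan(image)              # anterior first, depth-ordered
for c, t in zip(curves, truth):
    r = mspe(c, t, spec.axial_res_um)
    print(f"{c.interface_name:18s} MSPE {r.mean_px:.3f} px "
          f"({r.mean_um:.2f} um) over {r.n_columns} columns")
```

prints

```
anterior           MSPE 0.045 px (0.22 um) over 224 columns
epithelium_stroma  MSPE 0.022 px (0.11 um) over 224 columns
posterior          MSPE 0.183 px (0.92 um) over 224 columns
```

i.e. on a speckled phantom every interface is recovered to a small fraction
of a pixel; the 224 evaluated columns are those surviving the lateral
low-SNR crop. Columns inside a detected central saturation artifact are
excluded, not guessed.

The same functionality is available from the shell:

```bash
cornseg phantom --out-dir data --seed 7          # synthetic B-scan + truth CSV
cornseg segment2d data/phantom.tiff --out-dir out
cornseg evaluate out/phantom_boundaries.csv data/truth_boundaries.csv \
        --out report.json
cornseg segment3d volume.tiff --out-dir out3d    # multi-page TIFF volumes
```

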