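# thzmargin

Terahertz refractive-index mapping and contour-constrained morphological
dilation for tumour margin delineation.

The package implements a full desk-scale pipeline:

1. **optics** — forward electromagnetic model: normal-incidence Fresnel
   transmission/reflection coefficients, substrate propagation, and the
   candidate transfer function of the substrate–tissue echo referenced to an
   ideal metal-plate reflection.
2. **inversion** — per-pixel extraction of the complex refractive index
   `n − jκ` by exhaustive grid search (`n ∈ [1.5, 3]` step 0.01,
   `κ ∈ [0, 1]` step 0.001) minimizing the squared log-magnitude discrepancy
   between measured and candidate transfer functions at the 550-GHz operating
   frequency.  A `magnitude` mode reproduces the magnitude-only objective
   (with deterministic tie-breaking, since it is degenerate at a single
   frequency); the default `complex` mode adds a wrapped phase term that
   makes the problem well posed.  Substrate pre-characterization from a
   bare-substrate trace uses the same minimization.
3. **segmentation** — binary thresholding (strictly "index higher than
   threshold"), a nested family of origin-symmetric structuring elements
   Λ⁰–Λ³ (1/5/13/21 offsets, JSON-configurable), and exactly one
   Minkowski dilation clipped to the tissue-support contour.
4. **registration** — isoline contouring (marching squares), bicubic
   resizing of the pathology side to the terahertz grid, and a rotation
   search maximizing Pearson correlation between the contour matrices.  The
   terahertz image is never resampled.
5. **evaluation** — confusion counts over the evaluable ("applicable")
   region, TPR/FPR, threshold-swept ROC curves per structuring element,
   trapezoidal AUC, and best/second-best threshold selection by TPR − FPR.
6. **phantom** — synthetic-data generator: adipose/fibrous/tumour tissue
   maps (tumour index highest), an optional sparse tumour fill and Gaussian
   blur emulating diffraction-limited class overlap, forward-simulated field
   cubes with controlled complex noise, and a higher-resolution rotated
   "pathology" truth mask.

## CLI

```sh
thzmargin simulate --out-dir run --seed 0 --snr-db 30 --blur-fwhm 2 \
    --pathology-scale 4 --pathology-angle 12
thzmargin extract  --cube run/cube.h5 --out run/map.tiff --support run/support.png
thzmargin classify --map run/map.tiff --out-dir run/masks \
    --thresholds "2.1 2.4" --ranks "0 1 2 3"
thzmargin register --thz run/map.tiff --pathology run/pathology_support.png \
    --payload run/pathology_mask.png --out run/registered.png
thzmargin evaluate --map run/map.tiff \
    --pathology-mask run/pathology_mask.png \
    --pathology-support run/pathology_support.png --out-dir run/eval
```

Exit codes: 0 success, 1 validation failure, 2 runtime failure.  Every
command writes a provenance JSON (config, config hash, package version).
Field cubes are HDF5; index maps are 32-bit float TIFF with a JSON sidecar;
masks are 8-bit PNG (0 = benign/outside, 255 = malignant); ROC tables are
CSV; summaries are JSON.

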