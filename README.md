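# bpq

Quantitative analysis toolkit for 3D-bioprinted Y-shaped mammary epithelial
cultures. It covers the full readout pipeline on synthetic data with known
ground truth:

- **geometry** — parametric Y design (stem + two mirror-symmetric branches),
  rasterization to metric masks, tip/trunk sub-region partitioning by
  nearest skeleton point, rigid mask registration, outline-length
  measurement, and G-code toolpath export/parsing (RepRap dialect).
- **synth** — seeded synthetic culture scenes (region-dependent growth,
  outline-seeded invasive protrusions, DAPI/Ki67/PI nuclei channels) and
  Hertz spherical-indentation curves, all with exact ground-truth sidecars.
- **quantify** — growth expansion between culture days, invasion extraction
  by morphological opening with outline-length normalization, Ki67/DAPI
  proliferation ratio, nucleus-level viability, confluence normalization.
- **afm** — Hertz contact model, deterministic separable least-squares
  fitting of modulus + contact offset, the 3×(5×5)×3 = 225-curve sampling
  plan, and Gaussian modulus summaries gated by Shapiro–Wilk.
- **stats** — normality-gated two-group comparison (paired/unpaired t,
  Wilcoxon signed-rank, Mann–Whitney) with significance star labels.
- **pipeline / cli** — reproducible end-to-end runs producing tidy CSVs,
  a comparison table, and a manifest.

## CLI

```bash
bpq design build --out design.yaml
bpq design rasterize --design-file design.yaml --pixel-size 4 --out mask.tif
bpq design gcode --out well.gcode                  # 4 structures, F60 feed
bpq partition --mask mask.tif --design-file design.yaml --out labels.tif
bpq simulate scene --mode dcis --seed 1 --out-dir scene/
bpq simulate afm --modulus 103.4 --seed 1 --out curves.csv
bpq afm fit --curves curves.csv --out fits.csv
bpq afm summarize --fits fits.csv --out summary.json
bpq quantify ki67 --dapi scene/dapi.tif --ki67 scene/ki67.tif \
    --labels scene/labels.tif --out ki67.csv
bpq run --mode dcis --n-structures 20 --seed 1 --out-dir run/
```

Masks and label maps travel as TIFF with a JSON sidecar (pixel size,
origin); curves as CSV (`delta_m, force_N`); reports as tidy CSV.

## Conventions

Row-major 0-based grids with the origin at the center of pixel (0, 0);
x along columns, y decreasing with rows; areas are pixel count × pixel
size². Default analysis pixel size is 4 µm/px (tests and the demo pipeline
use 8 µm/px for speed). AFM quantities are SI (m, N, Pa).
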