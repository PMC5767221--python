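# ratioimg

Ratiometric luminescence (BRET/FRET-style) time-lapse analysis as a
scriptable library and CLI. The pipeline cleans donor (D) and acceptor (A)
image stacks, aligns them over time, masks the donor with global or local
adaptive thresholds — including a composite method built from Gaussian-blur
subtraction, Li thresholding and an OR with Otsu — divides A by D pixel by
pixel, renders the ratio on a bounded 16-color pseudocolor scale, and
quantifies ratio mean/SD in regions of interest over time.

## Layout

| Module | Purpose |
| --- | --- |
| `ratioimg.core_io` | image stacks (multi-page TIFF), regions (JSON sidecar, optional ImageJ `.roi`), measurement CSV, shared domain types |
| `ratioimg.preprocess` | 3×3 median filter, per-frame background-median subtraction, optional background image, translation-only subpixel registration, crop |
| `ratioimg.thresholding` | constant / median-ROI / Otsu / Li / Phansalkar / composite donor masks; all "keep" decisions are strictly-greater-than |
| `ratioimg.ratio` | masked A/D division (0 = background sentinel), nearest-rank permille display range, pseudocolor and donor-weighted rendering, stack histogram |
| `ratioimg.quantify` | per-ROI, per-frame mean / sample SD / pixel count of nonzero ratio; pooling across sources |
| `ratioimg.synthetic` | deterministic neuron-like two-channel phantoms (soma, neurites, spines, decay, drift, noise) with ground truth |
| `ratioimg.pipeline` / `ratioimg.cli` | orchestration, manifest/provenance, threshold comparison reports, `click` CLI |

## CLI

Each pipeline stage is a subcommand; stages run individually on the
intermediates match the integrated `run`.

```bash
ratioimg simulate --preset neuron --seed 1 --out-dir phantom/
ratioimg clean --donor phantom/D.tif --acceptor phantom/A.tif \
    --background-region phantom/regions.json --align --out-dir clean/
ratioimg threshold --donor clean/D_clean.tif --method chastagnier \
    --sigma-low 2 --sigma-high 5 --out mask.tif --masked-donor D_masked.tif
ratioimg divide --acceptor clean/A_clean.tif --donor D_masked.tif \
    --out ratio.tif --png-dir renders/
ratioimg measure --ratio ratio.tif --rois phantom/regions.json --out measures.csv
ratioimg compare-thresholds --donor clean/D_clean.tif \
    --truth-mask phantom/truth_mask.tif --out report.csv
```

The integrated run takes a JSON config whose keys mirror
`ratioimg.pipeline.PipelineConfig`:

```bash
ratioimg run --config config.json
```

Every run writes its intermediates (cleaned stacks, mask, masked donor,
32-bit float ratio TIFF, PNG renders, CSV) plus `manifest.json`, which is
sufficient to re-run the analysis bit-identically.

## Conventions

- Coordinates are 0-based `(x, y)`, origin top-left; rectangles are
  half-open `[x0, x1) × [y0, y1)`; polygons rasterize by an even-odd
  pixel-center test.
- Masks are `{0, 1}` in memory, `0/255` in 8-bit TIFFs on disk.
- A ratio of exactly 0 marks masked background and renders black.
- Display bounds default to the 5th/995th permille (nearest-rank) of the
  nonzero ratio pixels pooled over the stack.
- ROI statistics exclude zero pixels; mean is missing when no pixel
  survives, sample SD (n−1) is missing below 2 pixels.

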