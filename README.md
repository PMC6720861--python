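# cytotile

Processing for multi-cycle, multi-channel, tiled 3-D fluorescence
microscopy — the kind of data produced by cyclical multiplexed
immunofluorescence protocols (CODEX-style dye-exchange imaging, DNA exchange
imaging, and similar), where a specimen is imaged repeatedly over many
cycles of ~4 channels each, as a grid of 3-D tiles per region, and where a
nuclear reference stain is present in every cycle.

It is aimed at bioinformaticians who need unattended, configuration-driven,
batch processing of such experiments on a CPU: from raw 2-D grayscale files
on disk to per-cell cytometry tables, with every choice recorded in a single
experiment configuration.

## What the pipeline does

The seven experiment dimensions are (region, tile row, tile column, cycle,
channel, z, y/x). Per tile, the stages run in a fixed order:

1. **Assembly** — raw 8/16-bit 2-D files, with indices encoded in their
   names by a configurable template, are assembled into a 5-D volume
   ordered (cycle, z, channel, y, x), streamed through a bounded prefetch
   queue so I/O overlaps compute.
2. **Cycle registration** — sample drift between cycles is a translation
   (Δy, Δx).  It is estimated between the cycle-0 and cycle-c reference
   channels by frequency-domain cross-correlation with subpixel refinement
   via a locally upsampled DFT: resolution 1/u pixel at upsample factor u.
   The inferred translation is applied to every plane of the cycle.
3. **Deconvolution** — a Gibson–Lanni point spread function is generated
   from the configured optics (NA, emission wavelength λ, refractive
   indices n_i/n_s, voxel sizes).  The scalar-diffraction field is the
   pupil integral

       I(r, z) = ∫₀¹ J₀(k·NA·r·ρ) · exp(i·k·W(ρ; z)) · ρ dρ,   k = 2π/λ,

   evaluated by a fast scaled-Bessel basis approximation, and the PSF is
   |I|².  Richardson–Lucy restoration then iterates
   x ← x · (Kᵀ ⊛ (d / (K ⊛ x))) with FFT convolutions on a
   reflection-padded grid.
4. **Focus selection** — each z-plane of the reference channel is scored by
   a pluggable sharpness metric; the best-scoring plane is used for 2-D
   segmentation and quantification of all channels of the tile.
5. **Segmentation** — a 3-class probability map (background / nucleus
   interior / nucleus boundary) drives nucleus detection: interior-argmax
   pixels, size filter, then a one-pixel label-preserving dilation.  Cells
   grow from nuclei by fixed-radius expansion, masked seeded watershed on a
   membrane channel, or propagation segmentation (seeded lowest-cost region
   growing with step cost (ΔI)² + λ per unit step).
6. **Quantification** — one record per cell: centroids (tile-local and
   region-global), size A, equivalent diameter 2√(A/π), circularity
   4πA/P², per-channel mean intensity over cell and nucleus, and
   adjacency-graph features (neighbor ids, neighbor count, contact
   boundary in 4-adjacent pixel pairs).
7. **Export** — CSV and FCS 3.1 cell tables, ImageJ-compatible TIFF
   hyperstacks mixing raw channels with object images
   (`cyto_cell_boundaries`, …), and stitched region montages.

A synthetic-data generator (`cytotile.fixtures`) renders full raw
experiments with known ground truth (cell positions and radii, expression
levels, per-cycle drift, focal plane), so every stage is testable without
external data.

## Worked example

Write a configuration (`exp.yaml`) for a 2×2 grid, 2 cycles × (DAPI +
marker), 3 z-planes of 128×128 tiles:

```yaml
dimensions:
  regions: 1
  grid_rows: 2
  grid_cols: 2
  cycles: 2
  z_planes: 3
  channels_per_cycle: 2
  tile_height: 128
  tile_width: 128
microscope:
  objective_na: 0.75
  magnification: 20
  immersion_ri: 1.0
  sample_ri: 1.33
  lateral_pixel_size_um: 0.325
  axial_step_um: 0.5
channels:
  - {name: DAPI,  role: reference,  emission_wavelength_nm: 461}
  - {name: CD3,   role: expression, emission_wavelength_nm: 525}
  - {name: DAPI2, role: reference,  emission_wavelength_nm: 461}
  - {name: CD4,   role: expression, emission_wavelength_nm: 595}
operations:
  segmentation: {min_nucleus_size: 20, radius: 6}
```

Then generate a synthetic experiment and run the pipeline:

```console
$ cytotile config validate --path exp.yaml
OK: 1 region(s), 2x2 grid, 2 cycle(s) x 2 channel(s), 3 z-plane(s), tiles 128x128

$ cytotile fixtures generate --config exp.yaml --out data --seed 4 \
      --cells-per-tile 6 --drift-max 3
wrote 24 cells over 4 tile(s) to data

$ cytotile processor run --config exp.yaml --data-dir data --output-dir out \
      --set operations.segmentation.radius=5
processed 4 tile(s), 24 cell(s)

$ cytotile analysis montage --config exp.yaml --output-dir out \
      --channel DAPI --out montage.tif
wrote montage.tif with shape (256, 256)
```

All 24 rendered cells are recovered.  `out/` now holds, per tile, the
processed hyperstack (`volume.tif`), nucleus/cell label images and a cell
table, plus aggregated `cells.csv` / `cells.fcs`, a `shifts.csv` drift log
(the injected per-cycle drift appears there with opposite sign, as the
correction), `best_z.csv`, and a copy of the effective configuration.
Intensity columns follow the convention `ci:<channel>` (mean over the whole
cell) and `ni:<channel>` (mean over the nucleus alone).

`--set path=value` applies configuration *deltas* — the same mechanism as
`cytotile.config.apply_delta` — so variants of an experiment share one
template file.

## Scope

No GPU execution, no learned segmentation weights (the probability-map
contract accepts any external model's output), no rotation/deformable
registration, no interactive viewer, no automatic gating — exports are
meant to feed downstream cytometry tools.
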