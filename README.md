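# spheromigrate

Quantification of 3D spheroid-outgrowth (microtissue migration) assays.

When a multicellular spheroid embedded in a hydrogel is stimulated with a
growth factor, cells move outward in two distinct modes: **collective
migration** — multicellular sprouts that stay physically connected to the
spheroid body — and **single-cell (mesenchymal-type) migration** —
individual cells that detach and appear as isolated objects. In an
f-actin (phalloidin) stained image every cell-occupied voxel is bright, so
the two modes can be separated purely by connectivity:

1. threshold the intensity stack into a stained-voxel mask `M`;
2. locate the spheroid center `c` as the argmax of the Euclidean distance
   transform (EDT) of `M` — the deepest interior point of the largest
   blob — with core radius `ρ = max EDT`;
3. label the connected component of `M` containing `c` (minus the core
   ball) as *collective*, and every remaining foreground voxel as
   *single*;
4. for every outgrowth voxel `v`, record the migration distance
   `d(v) = ‖(v − c) · s‖₂` (voxel offset scaled by the physical spacing
   `s`), and histogram the per-class voxel counts over uniform distance
   bins.

The package also implements threshold-based positive-pixel
histomorphometry for stained sections (fraction of pixels strictly above
a user-chosen intensity cut-off, normalized to a control group), and a
seeded synthetic-image generator that produces spheroid + sprouts +
scattered single cells with exact per-voxel ground-truth labels, so every
stage is testable without acquired data.

Intended users: groups running sprouting/invasion or microtissue
migration assays who want a reproducible, scriptable readout instead of a
one-off analysis script.

## Worked example

```python
from spheromigrate import SpheroidParams, generate_spheroid_stack, quantify_stack

# synthetic 128x128x16 stack: one spheroid (radius 6 vx), 5 sprouts,
# 10 isolated single cells, fg/bg = 200/20 grey levels, noise sd 10
params = SpheroidParams(noise_sd=10.0, seed=1)
stack, truth = generate_spheroid_stack(params)

# fixed threshold halfway between the two intensity levels
result = quantify_stack(stack, threshold=110.0, min_single_size=5)
s = result.summary
print(f"core voxels:        {s.n_core}")
print(f"collective voxels:  {s.n_collective}")
print(f"single voxels:      {s.n_single}")
print(f"collective fraction: {s.collective_fraction:.3f}")
print(result.histogram.as_frame().to_string(index=False))
```

prints

```
core voxels:        925
collective voxels:  740
single voxels:      334
collective fraction: 0.689
 bin_lo  bin_hi  collective_pixels  single_pixels
    0.0    10.0                114              0
   10.0    20.0                323              0
   20.0    30.0                291              0
   30.0    40.0                 12             46
   40.0    50.0                  0            286
   50.0    60.0                  0              2
```

Reading: 925 voxels form the spheroid core; 740 outgrowth voxels are
connected to it (sprouts, reaching out to the 30–40 px bin) and 334
belong to detached cells sitting 30–60 px from the center. The
classification here matches the generator's ground truth voxel for voxel
(`truth.true_counts` shows the same numbers). With unit voxel spacing,
distances are in pixels; pass a physical `spacing` to get micrometres.

The same pipeline is scriptable from a shell:

```bash
spheromigrate simulate --config params.yaml --out sim/
spheromigrate quantify sim/spheroid_image.tif --threshold fixed:110 --out results/
spheromigrate batch manifest.csv --threshold otsu --out combined.csv
spheromigrate histomorph section.tif --threshold 60 --out score.json
```

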