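# econet

Ecological-network construction and optimization on raster landscapes,
implemented as a tested, seeded pipeline:

1. **synthetic_landscape** — seeded generator for a grassland-dominated
   nine-class land-use raster (contiguous east, fragmented west), a smooth
   DEM, a vegetation-cover field correlated with grassland, and sparse
   connected road networks; plus Horn-method aspect classification.
2. **mspa** — morphological segmentation of a binary habitat map into the
   seven structural classes (core, islet, perforation, edge, loop, bridge,
   branch) on the 8-neighborhood, with per-class area statistics.
3. **connectivity** — core-patch graph (edge-to-edge distances, 5000 m
   link threshold, probability 0.5 at the threshold), IIC / PC indices,
   per-patch dIIC / dPC importance, and top-dPC source selection.
4. **resistance** — six-factor reclassification to 1–5 scores (elevation,
   aspect, land use, vegetation cover, distance to main/branch roads),
   weights either fixed (shipped defaults) or derived by PCA of sampled
   factor scores, combined by weighted sum into a [1, 5] surface.
5. **corridors** — exact Dijkstra cost distances on the 8-connected cell
   graph, one least-cost corridor per source pair, gravity-model scoring
   `G = L_max² ln(S_i) ln(S_j) / (L² P_i P_j)` and importance ranking.
6. **network_opt** — betweenness-centrality stepping-stone selection,
   all-pairs planned network over sources + stones, and α / β / γ network
   form indices.
7. **io_cli** — pipeline orchestration, YAML configuration, manifest with
   per-file SHA-256 hashes, and the `econet` command-line interface.

Rasters are exchanged as ESRI ASCII grids (`.asc`), tables as CSV,
corridor geometry as GeoJSON, configuration as YAML — all plain text.

## CLI

```bash
# full pipeline with defaults (200x200 synthetic landscape, 30 m cells)
econet run --seed 1 --out runs/demo

# individual stages
econet simulate --config cfg.yaml --out runs/sim
econet mspa --landuse runs/sim/landuse.asc --foreground grassland --edge-width 1 --out runs/m
econet connectivity --stack runs/sim --threshold 5000 --p 0.5 --top 10 --out runs/c
econet resistance --stack runs/sim --out runs/r            # add --pca-weights for PCA-derived weights
econet corridors --stack runs/sim --top-k 15 --out runs/k
econet optimize --stack runs/sim --stones 10 --top-k-important 8 --out runs/o
```

A full default run emits, among other artifacts, `corridors.geojson`
(45 potential corridors among the 10 sources), `planned_corridors.geojson`
(190 corridors over sources + 10 stepping stones) and
`network_quality.csv` (α/β/γ before and after planning, with the node and
link counts used).

## Conventions

- Row 0 is the northern raster edge; cell centers at
  `(origin_x + (col+0.5)·cell, origin_y − (row+0.5)·cell)`; distances in
  meters between cell centers; areas in km² (gravity masses in hectares).
- MSPA class codes: 0 background, 1 core, 2 islet, 3 perforation, 4 edge,
  5 loop, 6 bridge, 7 branch.
- Step cost between adjacent cells: `cell_size · m · (R_u + R_v)/2`, with
  `m = √2` for diagonal moves.
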