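# woodchange

Reusable pipeline for analyzing long-term change in tropical dry woodland
cover and its relation to large-mammal distributions:

1. **Harmonize** multi-source woodland maps (categorical, binary, or
   fractional; different native resolutions) onto a common fractional-cover
   grid (`woodchange.grids`).
2. **Screen** candidates with a two-observer reference sample: observers'
   10%-interval estimates are fused (midpoint average, rounded to the
   nearest 5%), both reference and map are binarized over a 15–22% threshold
   sweep, and sources failing the accuracy floors (overall accuracy < 0.70
   or woodland user's accuracy < 0.90 at their best threshold) are dropped
   (`woodchange.validation`).
3. **Fuse** the retained sources into an accuracy-weighted consensus map —
   both the literal sum(UA·WL)/n formula (`as_printed`) and the
   weight-normalized convex combination are provided
   (`woodchange.ensemble`).
4. **Reconstruct** a multi-epoch cover series (default epochs 1880–2020),
   mask persistent non-woodland (≤ 5% cover in every epoch), and compute
   pixel-wise percentage-point change maps, period area accounting, and
   per-ecoregion mean ± SD trajectories (`woodchange.change`).
5. **Cluster** coarse-cell cover trajectories into change archetypes with an
   online self-organizing map on a 1-D node chain, plus cluster-count
   diagnostics (quantization error, silhouette, empty nodes)
   (`woodchange.archetypes`).
6. **Overlay** species ranges: richness maps by threat group,
   richness–cover Pearson correlations, per-range cover trajectories,
   archetype composition of ranges, and median richness per archetype
   (`woodchange.megafauna`).

Everything is exercisable end to end on synthetic data with known truth:
`woodchange.synth` generates spatially autocorrelated cover surfaces whose
per-cell trajectories follow archetype templates arranged in contiguous
patches, derived source maps with known omission/commission error, noisy
two-observer validation samples, ecoregion partitions, and species ranges
that are either cover-seeking ("threatened") or placed uniformly. All
generators are bit-reproducible under a fixed seed.

## CLI

Every stage is independently scriptable against a run directory:

```bash
woodchange simulate  --config cfg.yaml --out run/world
woodchange validate  --world run/world --out run/accuracy.csv
woodchange ensemble  --world run/world --accuracy run/accuracy.csv --out run/ensemble.tif
woodchange change    --world run/world --out run/change
woodchange archetypes --world run/world --out run/arch
woodchange megafauna --world run/world --labels run/arch/archetype_assignments.tif --out run/mega
```

or end to end:

```bash
woodchange run-all --seed 1 --out run/
```

`run-all` writes every intermediate artifact (GeoTIFFs and tidy CSVs), a
`manifest.json` tying outputs to the configuration and derived stage seeds,
and a `summary.json` with the headline numbers. Re-running with the same
config and seed is bit-identical. Configuration is a single YAML file whose
defaults reproduce the reference settings (sweep 15–22%, floors 0.70/0.90,
10×10 coarse aggregation, k = 6, 5% non-woodland cutoff); CLI flags override
the config.

## File formats

Rasters are single-band GeoTIFFs (via `tifffile`, with standard
ModelPixelScale/ModelTiepoint georeferencing tags and a JSON sidecar tag for
CRS id, epoch year, class legend, and nodata). Tables are plain CSV with
explicit unit columns. Reprojection between coordinate systems is
deliberately out of scope: all grids must share one CRS and be nested
(integer cell-size factors, common origin).
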