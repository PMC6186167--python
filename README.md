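# mycotree

Design, simulation and analysis pipeline for tree diversity × mycorrhizal-type
experiments: trait-matched species-pool selection, constrained experimental
design generation, a resource-niche growth simulator, additive partitioning of
mixture productivity into net biodiversity / complementarity / selection
effects, and treatment-level inference with mixed models.

## What's inside

| Module | Purpose |
| --- | --- |
| `mycotree.traits` | Mixed-type Gower dissimilarity, Rao's quadratic entropy, and selection of two maximally trait-similar species pools (one per mycorrhizal type: AMF / EMF) |
| `mycotree.design` | Treatments (richness 1/2/4 × AMF/EMF/Both), composition enumeration, balanced subsetting (equal species occurrence), block-grid randomisation under 8-neighbourhood constraints, and regular 140-tree planting layouts with a 64-tree core |
| `mycotree.simulate` | Species niche disks in a 2-D resource box; grid-quadrature resource capture with overlap sharing; noisy diameter-growth inventories under complementarity / selection / neutral scenarios |
| `mycotree.partition` | Basal-area increment productivity and the additive partition NE = CE + SE (population covariance, exact identity) |
| `mycotree.stats` | Bootstrap group summaries with percentile CIs, REML random-intercept mixed models (statsmodels), marginal/conditional R² |
| `mycotree.cli` / `mycotree.config` | Click CLI, YAML/JSON run configs, deterministic per-stage seed fan-out, JSON run manifests |
| `mycotree.datasets` | Bundled example species labels and a synthetic demo trait table |

Default design parameters reproduce the standard 80-plot layout: 20
monocultures (10 species × 2), 30 two-species and 30 four-species mixture
plots in two blocks of 5×8 grid cells, 140 trees per plot (11,200 total),
with same-treatment plots never adjacent and no treatment occurring more
than twice around any focal plot.

## CLI

```bash
# whole pipeline with defaults (demo trait table, complementarity scenario)
mycotree run-all --out-dir out/

# or stage by stage
mycotree select-pools --traits my_traits.csv --out-dir out/
mycotree design --pools out/pools.json --config config.yaml --out-dir out/
mycotree simulate --design out/design.csv --layout out/layout.csv --out-dir out/
mycotree partition --inventory out/inventory.csv --design out/design.csv --out-dir out/
mycotree analyze --partition out/partition.csv --out-dir out/

# re-check all design invariants on exported CSVs (nonzero exit on violation)
mycotree validate-design --design out/design.csv --layout out/layout.csv
```

Configuration is YAML or JSON, e.g.

```yaml
seed: 7
design: {pool_size: 5, blocks: 2, grid_rows: 5, grid_cols: 8}
simulation: {scenario: selection, years: 2, noise_sd: 0.05, resolution: 200}
analysis: {n_boot: 2000, richness_scale: log2}
```

A single global `seed` is split deterministically into per-stage child seeds,
so every run is bit-reproducible and each stage independently replayable;
every stage writes a `manifest_<stage>.json` with the config, seed and input
hashes.

## File formats

All tabular I/O is plain CSV (UTF-8, comma-delimited, header row): design
(`plot_id, block, row, col, richness, myco_level, species` —
semicolon-delimited species), planting layout (`plot_id, row, col,
species_id, is_core`), inventory (`plot_id, row, col, species_id, year,
diameter_cm, alive`), partition (`plot_id, richness, myco_level,
composition, NE, CE, SE` in m² basal-area increment per year). Niche
configurations and model results serialise to JSON.
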