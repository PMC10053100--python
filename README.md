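# soilrisk

A tested, reusable pipeline for soil heavy-metal studies: pollution summary
statistics and enrichment factors, a from-scratch uncertainty-weighted
positive matrix factorization (PMF) receptor model, deterministic and Monte
Carlo human health risk assessment, and inverse-distance-weighted (IDW)
concentration surfaces. Synthetic-data generators with known ground truth
make every stage testable without field data.

## Modules

| Module | Purpose |
| --- | --- |
| `soilrisk.io_model` | Domain types, CSV/YAML readers, validated configuration (background/guide values, MDLs, RfD/SF, exposure distributions) |
| `soilrisk.synthetic_data` | Factor-structured samples `X = G·F + E` with ground truth; lognormal samples moment-matched to a published summary table |
| `soilrisk.indices` | Summary statistics (CV%, exceedance rates), enrichment factors with Sutherland-style classes, Pearson correlations |
| `soilrisk.pmf` | Weighted nonnegative factorization minimizing `Q = Σ((x−GF)/u)²`, MDL-based uncertainties, multi-start runs, factor-number scan, robust downweighting, source reports |
| `soilrisk.hra` | Three-route average daily dose, hazard quotient/index, cancer risk |
| `soilrisk.mc_hra` | Monte Carlo propagation of concentration and exposure distributions; percentile/exceedance summaries and contribution shares |
| `soilrisk.spatial` | IDW interpolation onto regular grids, ASCII-grid output |
| `soilrisk.cli` | `soilrisk` command wiring everything into one reproducible pipeline |

## CLI

```sh
# one-command demo: synthesize a 40-site survey and run every stage
soilrisk demo --out results/demo --seed 1

# full pipeline on your own table (CSV: site_id,x,y,Cd,Cr,Cu,Zn,Ni,Pb,Mn)
soilrisk run --samples samples.csv --config config.yaml --out results/ --seed 1

# pieces
soilrisk synth matched --n 40 --seed 1 --out samples.csv
soilrisk synth factors --k 4 --n 40 --noise-cv 0.1 --out samples.csv
soilrisk idw --in samples.csv --metal Cd --cell 100 --out cd.asc
```

The shipped default configuration (`src/soilrisk/data/default_config.yaml`)
carries regional background/guide values plus conventional US-EPA exposure
and toxicity stand-ins; edit it for site-specific work. `soilrisk run`
writes CSV tables, one ASCII grid per metal, and a `manifest.json` whose
seeds make reruns bit-identical.

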