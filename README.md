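# polarflow

Quantitative analysis of flow-driven endothelial polarity and vessel
regression in planar vascular networks — built for the developing mouse
retina, where remodeling prunes the primitive capillary plexus largely
*without* endothelial cell death: cells polarize their Golgi against the
blood flow direction and migrate out of low-shear segments, leaving empty
collagen-IV sleeves ("regression profiles") behind.

The package is aimed at vascular-biology labs quantifying flat-mount
retina (or similar planar plexus) data, and provides:

* **Network extraction** — lumen masks → spatial graph with per-segment
  centerlines and radii (skeleton + distance transform).
* **Haemodynamics** — steady Poiseuille network flow: per-segment flow
  Q = π r⁴ ΔP / (8 μ L), velocity, wall shear stress τ = 4 μ |Q| / (π r³),
  and oriented flow directions.
* **Axial polarity** — per-cell nucleus→Golgi vectors **p**, the angle to
  local flow θ ∈ [0°, 180°], the signed scalar product s = |p|·cos θ,
  against-flow fractions in the 180° ± 45° window, and sign-stratified
  regressions of s on τ.
* **Radial profiling** — cell density, branchpoint density and
  length-weighted mean shear versus distance from the optic nerve.
* **Regression detection** — matrix-positive / lumen-deficient segments,
  staged along the four-step regression sequence (selection → stenosis →
  retraction → resolution), apoptosis colocalization percentages, and
  low-flow association statistics.
* **A synthetic-retina generator** with complete ground truth (planted
  polarity concentration, regression stages, apoptosis colocalization
  rate), so the whole pipeline is testable by planted-parameter recovery.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
import polarflow as pf
from polarflow.polarity import (cells_from_table, assign_to_segments,
                                angle_and_scalar, region_stats)
from polarflow.regression import (detect_profiles, colocalize_apoptosis,
                                  resident_cell_counts)

# one whole synthetic P6 retina: plexus, flow, planted regression, cells
world = pf.simulate_world(pf.GenConfig(seed=1))

cells = assign_to_segments(cells_from_table(world.cells), world.net)
cells = angle_and_scalar(cells, world.net, world.flow)
stats = region_stats(cells)
for region in ("artery", "capillary", "vein"):
    rec = stats[region]
    print(f"{region:12s} n={rec['n']:5d}  "
          f"against-flow={100 * rec['against_flow_fraction']:.1f}%")

counts = resident_cell_counts(cells, world.net)
profiles = detect_profiles(world.net, counts)
res = colocalize_apoptosis(profiles, world.truth.apoptosis, world.net)
print(f"cells={len(world.cells)}  apoptosis events="
      f"{len(world.truth.apoptosis)}")
print(f"regression profiles={res['n_profiles']}  "
      f"colocalized={res['coloc_percent']:.2f}%")
```

prints

```
artery       n=  592  against-flow=85.0%
capillary    n=14120  against-flow=82.1%
vein         n=  583  against-flow=82.3%
cells=16000  apoptosis events=84
regression profiles=151  colocalized=4.64%
```

Reading: with the default polarity concentration (von Mises κ = 4 against
flow), ~82–85% of endothelial cells in every perfused vascular bed point
their Golgi within 45° of the upstream direction; the retina carries
16,000 endothelial cells and 84 apoptotic events, and only 4.6% of the
151 detected regression profiles have an apoptotic event within one
cell-body radius (10 μm) — regression overwhelmingly without cell death.

## Command line

```sh
polarflow run --config cfg.yaml --seed 1 --outdir out/   # full pipeline
polarflow simulate --config cfg.yaml --outdir out/        # synthetic data
polarflow extract --image masks.tif --out net.json        # mask → graph
polarflow flow --net net.json --out flow.csv              # Poiseuille solve
```

`run` writes every stage artifact (network JSON, flow CSV, augmented cell
table, radial profile, regression summary) plus a machine-readable
`report.json` with headline metrics; identical config + seed reproduces
the run exactly.

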