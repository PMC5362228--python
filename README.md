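# octfovea

Foveal intra-retinal layer morphometry for SD-OCT B-scans.

Pediatric studies of anisometropic amblyopia ask whether the retina itself
— not just the cortex — differs between amblyopic, fellow and visually
normal eyes. Answering that requires measuring eight intra-retinal layers
(NFL, GCL+IPL, INL, OPL, HFL+ONL, MEZ, OS, IZ+RPE) at the foveal center
and 0.5 mm away in four quadrants, to a precision of a few μm, and then
comparing three small groups while adjusting for age, sex and ocular
magnification. `octfovea` implements that entire chain as a tested,
reusable pipeline:

* **`octfovea.phantom`** — synthetic B-scan phantoms (layered retina,
  Gaussian foveal pit where the inner layers vanish, PSF blur,
  multiplicative gamma speckle) with sub-pixel ground truth, and synthetic
  three-group cohorts drawn from built-in published reference
  distributions (18 eyes/group).
* **`octfovea.segmentation`** — the nine boundaries B1 (ILM) … B9 (BrM) by
  minimum-cost path search on polarity-split gradient maps: node weight
  `w = 1 − g + w_min`, edges limited to ±`max_jump` rows per column, edge
  cost `w(a)+w(b)`, virtual zero-cost end columns, solved by dynamic
  programming with a sequential search-region protocol.
* **`octfovea.metrics`** — layer thicknesses `(B(k+1) − Bk)·axial_scale`,
  Bennett magnification correction `q = 0.01306·(AL − 1.82)` applied to
  the lateral scale in ratio form, foveal-center detection (inner layers
  absent + total-thickness minimum) and 0.5-mm quadrant sampling.
* **`octfovea.stats`** — per-outcome ANCOVA `thickness ~ group + age + sex`
  (statsmodels OLS) with Bonferroni-corrected pairwise contrasts of
  adjusted means (m = 3, display ">0.999" above 0.9995), Welch t-tests for
  baseline biometry, Pearson correlations. `ThicknessAncova(...).fit()`
  returns an `AncovaResults` with `summary()`.
* **`octfovea.pipeline` / CLI `octfovea`** — one-command orchestration
  (`simulate`, `segment`, `measure`, `compare`, `run`) with schema-tagged,
  byte-reproducible CSV outputs.

## Worked example

Segment a speckled phantom pair with known truth and sample the fovea:

```python
from octfovea import (PhantomSpec, generate_bscan, segment_layers,
                      boundary_error, profile_from_scan, sample_fovea,
                      find_foveal_center)

profiles = {}
for meridian, seed in (("horizontal", 7), ("vertical", 8)):
    spec = PhantomSpec(meridian=meridian, noise_level=0.1, seed=seed)
    scan, truth = generate_bscan(spec)
    boundaries = segment_layers(scan)
    err = boundary_error(truth, boundaries, spec.axial_scale)
    profiles[meridian] = profile_from_scan(scan, boundaries)

print("worst boundary MAE = %.2f um" % err["mae_um"].max())
print("foveal center column:", find_foveal_center(profiles["horizontal"]))
sample = sample_fovea(profiles["horizontal"], profiles["vertical"])
print("central total: %.1f um" % sample.central["total"])
print("nasal total @0.5mm: %.1f um" % sample.peripheral["nasal"]["total"])
```

prints

```
worst boundary MAE = 2.01 um
foveal center column: 255
central total: 135.4 um
nasal total @0.5mm: 204.2 um
```

i.e. every boundary is recovered to about half an axial pixel on average
(3.87 μm/px), the pit center is found within one column of the configured
256, and the central total (~133 μm configured) and tail-of-pit nasal
sample come back at their ground-truth values.

The statistics stage works the same way from a synthetic cohort:

```python
from octfovea import CohortSpec, generate_cohort, cohort_to_long, ThicknessAncova
long = cohort_to_long(generate_cohort(CohortSpec(seed=7)))
print(ThicknessAncova.from_long(long, "nasal", "NFL").fit().summary())
```

A full end-to-end run (`octfovea run --out out --seed 5`) writes
`cohort.csv`, `thickness.csv`, a Table-style `report.csv` (adjusted means ±
SD and three Bonferroni p columns per outcome), `baselines.csv`,
`correlations.csv` and a `run_report.json` manifest, all byte-identical
under a fixed seed.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic amblyopic cohort at large n with the
given seed, measures the sample mean of total central foveal thickness,
and writes it as JSON. See `docs/methods.md` for the models, operator
choices and known limitations.
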