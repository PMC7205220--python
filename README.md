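# nodalmorph

Morphometry of cardiac nodal regions from serial stained sections:
how deep the sinoatrial (SAN) and atrioventricular (AVN) nodes lie
beneath the epi/endocardial surface, what tissue covers them, and how
both change with age.

## The problem

The cardiac conduction system cannot be seen during surgery or catheter
procedures; it is localized indirectly from anatomical landmarks, and
accidental damage to the SAN or AVN remains a real procedural risk.
Serial histology — Masson's-trichrome-stained sections cut at a fixed
interval through the nodal regions — can quantify where a node sits
relative to the tissue surface, but turning stacks of segmented section
images into depth profiles, coverage percentages and age trends takes a
careful, reproducible measurement chain. `nodalmorph` is that chain, for
researchers who have per-section images plus node/surface segmentations
(or who want to validate the methodology on synthetic data first).

## What it computes

Per section, given an RGB image, a binary node mask and a one-pixel
surface trace with known pixel size:

* **surface geometry** — the trace is ordered into a polyline, fitted
  with a cubic smoothing spline, and resampled at uniform arc length;
* **depth** — the exact Euclidean distance transform of the node mask is
  sampled (bilinear) along the fitted surface; the *minimal depth* is
  the minimum over the **nodal projection** (the stretch of surface
  nearest to the node);
* **coverage** — trichrome-red (myocardium) and trichrome-white
  (adipose) percentages in circular ROIs centered on the surface
  (radius/spacing 150/75 µm for SAN, 500/250 µm for AVN), counting only
  tissue superficial to the node, partitioned into cephalic / nodal /
  caudal surface regions.

Across sections and hearts:

* aligned minimal-depth topology (AVN series aligned at the
  transition-to-His origin);
* age regressions `y(age) = a + b·age` and `y(age) = a + b·log(age)`,
  tested against a constant model via `F = ((SST−SSE)/1)/(SSE/(n−2))`
  with `P` from `F(1, n−2)`, reported with `R²`;
* one-way ANOVA with Tukey–Kramer post hoc comparisons between surface
  regions, and the reporting conventions `P>0.05` / `P<0.001`.

Because real nodal histology of this kind is rarely shareable, the
package ships a first-class synthetic generator (`nodalmorph.phantom`)
that builds sections, serial stacks and multi-heart cohorts with
analytic ground truth, used by the test suite, the examples and the demo
pipeline.

## Worked example

```python
import numpy as np
from nodalmorph import CohortSpec, fit_model, format_p, make_cohort

ages = tuple(np.geomspace(4.4, 58.3, 8))
cohort = make_cohort(CohortSpec(ages_months=ages, model_kind="log",
                                a=-102.607, b=135.018, noise_sd_um=50.0, seed=2))
res = fit_model(cohort.age_months, cohort.min_depth_um, "log")
print(f"depth = {res.a:.1f} + {res.b:.1f} * ln(age)")
print(f"R^2 = {res.r_squared:.3f}, {format_p(res.p_value)}")
```

prints

```
depth = -163.9 + 157.6 * ln(age)
R^2 = 0.844, P = 0.001
```

an 8-heart cohort whose AVN minimal depth was generated from
`depth = −102.607 + 135.018·ln(age)` µm plus 50 µm noise: the fit
recovers the offset and rate within sampling error, and the F-test
correctly rejects the constant model. See `examples/` for the full tour
(single-section depth, serial V-profile, ROI coverage, end-to-end
pipeline); each script prints what it computes and what the numbers
mean.

The end-to-end pipeline is also a CLI:

```bash
nodalmorph simulate --out study --node-type both --seed 0
nodalmorph run --study study --out results --figures
```

which writes `depth.csv`, `aligned_topology.csv`, `coverage.csv`,
`stats.csv`, a human-readable `report.txt`, and advisory figures that
are reconstructible from the CSVs alone.

## Layout

```
src/nodalmorph/
  phantom.py     synthetic sections, stacks, cohorts (+ ground truth)
  section_io.py  dataset and result-table I/O, validation
  surface.py     trace -> polyline -> smoothing spline -> resampling
  depth.py       distance maps, projection, depth profiles, alignment
  coverage.py    stain thresholds, ROI percentages, region partition
  stats.py       regressions, F-test, ANOVA + Tukey-Kramer, reporting
  pipeline.py    simulate/run orchestration, tables, report, figures
  cli.py         thin click CLI over the pipeline
docs/methods.md  models, parameters, conventions, limitations
```
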