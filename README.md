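# standcount

Seedling stand counts from UAV RGB orthomosaics, for field-trial
phenotyping at early, *mixed* growth stages.

Small-plot breeding trials need an established-plant count per plot soon
after emergence. Manual counting is slow; automated counting is hard
exactly when germination is heterogeneous — a plot can hold 2-leaf
cotyledon-stage seedlings next to 4-leaf rosettes, so no single appearance
model fits all plants. `standcount` implements an object-based pipeline
that handles this with a *grouped template*: a bank of k small exemplar
images covering the morphological variants, matched by normalized
cross-correlation against a vegetation-classified image layer.

## Method

Given an orthomosaic at ground sampling distance ~0.19 cm/px:

1. **Vegetation classification.** Each pixel's green ratio
   `G / (R + G + B)` is computed; pixels with ratio > 0.36 classify as
   plant. Plant pixels are merged into connected components
   (8-connectivity) and components smaller than 30 px are discarded as
   soil speckle. The green channel is copied where the surviving mask is
   true and zeroed elsewhere, giving the *classified plant layer*.
2. **Grouped template.** ~1000 sample patches (20 × 20 px) centred on
   marked seedlings are cut from the plant layer, normalized to zero mean
   and unit norm, and clustered into k = 10 subgroups (k-means); each
   subgroup's mean patch is a template. Template quality
   `R = mean corr(patch, its subgroup template)` summarises how well the
   bank fits the population (higher for masked layers, higher with more
   subgroups).
3. **Matching.** Every candidate centre whose 20 × 20 footprint overlaps
   the plant mask is scored with the zero-normalized cross-correlation
   (ZNCC = Pearson correlation of window and template, invariant to
   affine intensity changes) against all k templates; the best subgroup
   wins. Candidates with score > 0.5 pass, and greedy non-maximum
   suppression with a 10 px radius removes duplicate hits.
4. **Aggregation & evaluation.** Detections are mapped to world
   coordinates through the raster's affine transform, assigned to plot
   polygons by point-in-polygon, and summarised as counts and densities
   (plants/m²). Against manual counts the package reports R² (squared
   Pearson correlation), MAE and RMSE.

Because no reference imagery ships with the package, a synthetic-field
generator produces soil-textured tiles with rendered 2–4-leaf rosettes at
known positions (heterogeneous densities, clustered overlap, optional
weeds), so the whole pipeline runs and is tested end-to-end from code
alone. See `docs/methods.md` for the model details and its limits.

## Worked example

```python
from standcount import FieldConfig, generate_experiment, run_experiment

config = FieldConfig(n_plots=30, seed=2017)     # 5 m x 1 m plots, 0.19 cm/px
result = run_experiment(generate_experiment(config), n_patches=1000)
print(f"template quality R = {result.quality_R:.3f}")
print(result.report)
```

```
template quality R = 0.676
n=30 plots  R^2=0.9971  MAE=3.17  RMSE=3.66
```

The template quality (R = 0.676) is the mean correlation between the 1000
training patches and their subgroup templates — a realistic mid-range
value for mixed growth stages. The per-plot digital counts track the true
counts closely (R² near 1 because true counts span 40–200 per plot), with
a mean absolute error of ~3 plants per plot, mostly from tightly
clustered seedlings and the occasional weed.

The same pipeline is scriptable from the shell:

```bash
standcount all --out-dir runs/demo --n-plots 10 --seed 7
standcount simulate --out-dir runs/sim --n-plots 3 --seed 7
standcount build-template --sim-dir runs/sim --out runs/sim/template.json
standcount detect --image runs/sim/tiles/P001.tif --template runs/sim/template.json --out runs/sim/points.csv
standcount count --points runs/sim/points.csv --plots runs/sim/plots.geojson --manual runs/sim/manual_counts.csv --out runs/sim/summary.csv
standcount evaluate --summary runs/sim/summary.csv --out runs/sim/report.json
```

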