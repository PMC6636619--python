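# phenoclim

Herbarium specimens are the richest long-term record of plant reproductive
phenology, but a collection date alone says little: two sheets collected on
the same day may show one plant in full bud and another shedding mature
seed. **phenoclim** scores each specimen's reproductive stage as a
*phenological index* (PI), and uses it to build *pheno-climatic models*
that estimate climate sensitivity of flowering time and forecast the day
of year of any phenophase under specified climate. It is aimed at
herbarium-based phenology researchers and collection curators.

## The model

Each reproductive unit on a plant is classed as bud, open flower, immature
fruit or mature fruit and the classes carry increasing stage weights
*i* = 1…4. The plant's PI is the weighted mean

PI = Σₓ pₓ · iₓ,

where pₓ is the proportion of units in phenophase *x*. PI = 1 means all
buds; PI = 4 all mature fruits; a sheet with several plants gets the
unweighted mean of its plants' PIs. Counts come from ImageJ **Cell
Counter** XML marker files (read and written natively) or a plain counts
CSV.

Collection day of year (DOY) is then modelled by ordinary least squares:

* Model 1 (climate only): DOY ~ winterPPT + springTmax
* Model 2 (stage-aware): DOY ~ PI + winterPPT + springTmax

with winterPPT the cumulative December–February precipitation of the
previous winter (mm) and springTmax the March–May mean monthly maximum
temperature (°C). Fits report sequential (Type I) sums of squares in the
model's term order, F ratios against the full-model error mean square,
R², AICc (parameter count k = p + 2, including intercept and error
variance), the per-term variance partition, and seeded k-fold
cross-validated R². Because the PI coefficient is the mean number of days
per unit PI, (k−1)·coefficient estimates the total reproductive duration
of a k-stage scheme, and the fitted linear predictor evaluated at a target
PI (2.5 ≈ peak flowering) forecasts that phenophase's DOY under any
climate scenario.

A synthetic-data generator emulates herbarium datasets with this exact
structure — including collector-bias modes (pre-peak / post-peak /
uniform sampling of the reproductive window) — for end-to-end testing and
parameter-recovery studies.

## Worked example

```python
import phenoclim as pc

# one scored sheet: 0 buds, 12 flowers, 7 immature fruits, 26 mature fruits
counts = pc.PlantCounts("CAS0087560", "P1",
    {"bud": 0, "flower": 12, "immature_fruit": 7, "mature_fruit": 26})
print(f"PI: {pc.compute_pi(counts):.2f}")          # PI: 3.31 — late progression

# a synthetic campaign of 119 specimens, then both models
ds = pc.generate(pc.GeneratorConfig(n_specimens=119, seed=1))
table = ds.analysis_table()
f1, f2 = pc.fit(pc.MODEL1, table), pc.fit(pc.MODEL2, table)
print(pc.compare(f1, f2).summary())
dur = pc.stage_duration(f2)
print(f"per stage {dur.per_stage_days:.2f} ± {dur.per_stage_se:.2f} d, "
      f"total {dur.total_days:.2f} d")
pred = pc.predict_doy(f2, pc.peak_flowering(),
                      {"winter_ppt_mm": 400.0, "spring_tmax_c": 15.0})
print(f"peak flowering DOY {pred.doy:.1f} ± {pred.se:.1f}")
```

prints

```
PI: 3.31
R² 0.17 -> 0.31 (83% more variation explained); AICc 1125.78 -> 1105.95 (Δ -19.83); error variance 20% higher without the second model's terms
per stage 13.00 ± 2.69 d, total 39.00 d
peak flowering DOY 168.3 ± 2.4
```

The stage-aware model explains markedly more variance and a lower AICc at
identical climate terms; its PI coefficient says a plant advances one
phenophase every ~13 days in this noisy replicate, so the whole
bud-to-mature-fruit phase spans ~39 days, and plants at PI 2.5 (peak
flowering) are expected near day 168 under a 400 mm winter and a 15 °C
spring.

The same workflow is available from the shell:

```sh
phenoclim simulate --seed 1 --n 119 --out sim/
phenoclim model --counts sim/counts.csv --metadata sim/metadata.csv \
    --climate sim/climate.csv --seed 1 --out fit/
phenoclim forecast --fit fit/model2_fit.json --scenarios scenarios.csv --out doy.csv
```

(`phenoclim score --xml-dir <dir>` turns a folder of Cell Counter XML
files into the counts CSV.)

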