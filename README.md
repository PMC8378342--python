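# esdm — ensemble species distribution modelling

`esdm` builds habitat-suitability models for species known only from presence
records (e.g. GBIF/OBIS occurrence downloads) and gridded environmental
layers, and projects how their suitable range shifts under future climate
scenarios. It was written for marine distribution problems — the motivating
case is a coastal, shallow-water cetacean in the Indo-West Pacific whose
range is shaped primarily by ocean depth and distance to shore — but nothing
in the code is specific to that system.

The pipeline is the standard ensemble-SDM protocol:

1. **Occurrences** — clip records to the study extent, thin to one record per
   grid cell, and draw pseudo-absence points from sea cells in *contrasting*
   environmental conditions (outside the presence surface range envelope).
2. **Learner zoo** — ten algorithms behind one fit/predict contract: GLM,
   GAM, CTA (classification tree), GBM (boosted trees), ANN, SRE
   (surface range envelope / BIOCLIM), FDA, MARS, RF, and a
   maxent-style penalized presence/background logistic. Every model maps a
   predictor vector to a suitability score in [0, 1].
3. **Evaluation** — stratified 5-fold cross-validation with 10 repetitions;
   each held-out fold is scored with the rank-based AUC and the true skill
   statistic, TSS = sensitivity + specificity − 1, evaluated at its
   TSS-maximizing threshold.
4. **Gating and ensembling** — algorithms with mean TSS > 0.80 **and** mean
   AUC > 0.85 are refitted on all data and combined as a weighted average
   with weights proportional to their mean TSS:
   `w_i = TSS_i / Σ_j TSS_j`.
5. **Binarization and projection** — the ensemble map is thresholded at the
   TSS-maximizing cutoff, future layer stacks are built by shifting the
   dynamic predictors (temperature, salinity, current velocity, ice) by
   per-scenario deltas while depth and distance to shore stay constant, and
   range change is tabulated per scenario as

   ```
   PercLoss   = 100 · lost   / current      PercStable = 100 · stable / current
   PercGain   = 100 · gained / current      SpeciesRangeChange = PercGain − PercLoss
                                            = 100 · (future − current) / current
   ```

   so `PercLoss + PercStable = 100` holds exactly.

Variable importance is the randomization measure
`1 − Pearson(predictions, predictions with one predictor column shuffled)`,
reported as mean ± SE over permutation runs, plus evaluation-strip response
curves per predictor.

A virtual-species generator (`esdm.synthetic_data`) produces spatially
autocorrelated environmental stacks on a synthetic land–sea geometry,
presence samples from a known niche, and ground-truth suitability maps, so
the entire pipeline runs and validates offline.

## Worked example

```python
import esdm
from esdm.workflow import fit_ensemble_pipeline, project_scenarios

grid = esdm.GridSpec(lon_min=100, lon_max=140, lat_min=-20, lat_max=20, cell_size=1.0)
stack = esdm.generate_env_stack(grid, seed=11)
presences, truth = esdm.generate_virtual_species(
    stack, esdm.default_niche(n_presences=120), seed=12
)

result = fit_ensemble_pipeline(
    stack, presences, n_pseudo=1000, k=5, repetitions=2, seed=13,
    algorithms=("GLM", "GAM", "MARS", "CTA", "MAXENT", "SRE"),
)
print("retained:", result.retained)
print("threshold:", round(result.threshold, 3))
print(result.importance.table.round(3))

summaries, table, maps = project_scenarios(result, stack, esdm.default_scenarios())
print(table.round(2))
```

Output:

```
retained: ['CTA', 'GAM', 'GLM', 'MARS', 'MAXENT']
threshold: 0.467
         mean     se
T       0.002  0.000
Sal     0.005  0.000
CV      0.018  0.001
Ice     0.000  0.000
Depth   0.862  0.010
Dshore  0.100  0.003
                    RCP26_2050s  RCP45_2050s  ...  RCP60_2100s  RCP85_2100s
PercLoss                   0.72        28.52  ...        11.19        23.47
PercGain                   0.00         2.17  ...         4.69         2.17
PercStable                99.28        71.48  ...        88.81        76.53
SpeciesRangeChange        -0.72       -26.35  ...        -6.50       -21.30
```

Reading it: the envelope model (SRE) failed the TSS gate and was dropped;
the five retained learners are averaged with TSS-proportional weights. The
importance table recovers the generating niche — this virtual species is
depth- and shore-dominated, and those two predictors carry almost all of the
permutation importance. Each range-change column satisfies
`PercLoss + PercStable = 100` and `SpeciesRangeChange = PercGain − PercLoss`;
under the warmest scenario this species loses a net 21.3% of its current
range on this small demonstration grid.

The same analysis runs from the shell with a YAML config:

```bash
esdm simulate -c run.yaml     # or bring your own GeoTIFFs + presence CSV
esdm prepare  -c run.yaml
esdm fit      -c run.yaml
esdm evaluate -c run.yaml
esdm ensemble -c run.yaml
esdm project  -c run.yaml
esdm rangechange -c run.yaml
```

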