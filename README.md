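# reservesar

Species–area relationships (SARs) and SAR-based extinction projections for
beetle assemblages in protected-area networks.

Protected areas behave like habitat isolates: larger reserves hold more
species, and the relationship is well described by the power law

    S = c · A^z        ⇔        log₁₀ S = log₁₀ c + z · log₁₀ A

where *S* is species richness, *A* is reserve area, *c* is the expected
number of species per unit area (larger for vagile groups), and *z* is the
log–log slope (typically 0.2–0.4 for isolates).  Run in reverse, the same
law forecasts extinctions: shrinking a reserve from *A₀* to *A₁* reduces
richness to *S₁ = S₀ (A₁/A₀)^z*, so a fraction `1 − (1 − loss)^z` of the
species is expected to disappear when a fraction `loss` of the area is
lost.

The package is aimed at conservation biogeographers working with
per-reserve richness tables.  It implements, as a tested reusable pipeline:

- **Data model** (`reservesar.data`) — per-reserve covariates (latitude,
  longitude, area, four elevation summaries) and per-group richness with
  explicit missingness (a never-surveyed group is not a zero count).  All
  variables are log₁₀-transformed before analysis; variables that can be
  exactly zero (dung-beetle counts, coastal minimum elevations) use
  log₁₀(x + 1).  A built-in dataset covers 23 Italian reserves spanning
  0.17–1700 km² with richness for six beetle groups: Carabidae (terrestrial
  predators), Hydradephaga (aquatic predators), coprophagous and
  phytophagous Scarabaeoidea (dung feeders, herbivores), total
  Scarabaeoidea, and Tenebrionidae (detritivores).
- **SAR fitting** (`reservesar.sar`) — OLS on the linearised power law with
  classical inference, plus AICc under the Gaussian-ML convention
  (residual variance counted as a parameter).
- **ANCOVA** (`reservesar.ancova`) — incremental F-tests for homogeneity of
  *z* (slopes) and differences in *c* (intercepts) across groups, overall
  and pairwise, with a significance-annotated *c*-value ordering.
- **Model selection** (`reservesar.selection`) — exhaustive all-subsets OLS
  over {area, latitude, min/max/mean elevation, elevational range}, ranked
  by AICc; models within ΔAICc ≤ 2 are reported as equally supported.  When
  the best model keeps area alongside other covariates, its area
  coefficient serves as the projection exponent (geography and orography
  held fixed while area shrinks).
- **Extinction projection** (`reservesar.extinction`) — loss curves, expected
  whole-species counts, and the closed-form smallest area loss at which one
  extinction becomes expectable.
- **Synthetic reserves** (`reservesar.synthetic`) — a generator with known
  (c, z) and covariate structure for parameter-recovery and
  model-selection validation.
- **CLI** (`reservesar`) — subcommands `fit-sar`, `ancova`, `select`,
  `project`, `simulate`, `full`.

## Worked example

```python
import reservesar as rs

table = rs.load_italian_reserves()
carabidae = rs.subset_group(table, "Carabidae")

fit = rs.fit_sar(carabidae)
print(f"n = {fit.n}  log10(c) = {fit.log_c:.2f} ± {fit.log_c_se:.2f}   "
      f"z = {fit.z:.3f} ± {fit.z_se:.3f}   R² = {fit.r_squared:.2f}")
print(f"expected species in a 1 km² reserve: c = {fit.c:.1f}")

sel = rs.select_models(carabidae)
for cand in sel.best_set:
    print(f"{'+'.join(cand.predictors):30s} AICc = {cand.aicc:6.2f}  "
          f"ΔAICc = {cand.delta_aicc:.2f}")

z_mult = float(sel.best.fit.params["log_area"])
for loss in (0.25, 1/3, 0.50):
    frac = rs.extinction_fraction(z_mult, loss)
    print(f"area loss {loss:.0%} -> {100*frac:.1f}% of species expected lost")
print(f"smallest loss giving one expected extinction at S0=100: "
      f"{rs.min_loss_for_first_extinction(100, z_mult):.1%}")
```

prints

```
n = 18  log10(c) = 1.68 ± 0.11   z = 0.212 ± 0.053   R² = 0.50
expected species in a 1 km² reserve: c = 48.2
log_area+log_elev_range        AICc =   7.72  ΔAICc = 0.00
log_area                       AICc =   8.85  ΔAICc = 1.13
area loss 25% -> 9.3% of species expected lost
area loss 33% -> 12.9% of species expected lost
area loss 50% -> 21.0% of species expected lost
smallest loss giving one expected extinction at S0=100: 2.9%
```

Reading this: a one-km² reserve is expected to hold ~48 carabid species;
richness grows slowly with area (z ≈ 0.21), so halving a reserve's area
costs "only" ~21 % of its species under the multiple-model exponent
(z ≈ 0.34, which also accounts for the negative influence of elevational
range).  Losses are hard to notice in species-poor reserves — with 100
species a 3 % loss of area already predicts one extinction, but with 10
species more than a quarter of the reserve must vanish first.

The same pipeline runs from a shell and writes a report directory
(`sar.tsv`, `ancova.json`, `selection_<group>.tsv`, extinction curve/count
CSVs, provenance):

```sh
reservesar full --out-dir report/
reservesar ancova --groups Carabidae,Hydradephaga,coprophagous_Scarabaeoidea,phytophagous_Scarabaeoidea,Tenebrionidae
```

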