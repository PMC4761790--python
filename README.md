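# frost

Leaf freezing resistance and community functional structure for alpine
plant ecology.

Alpine plants face freezing events even in mid-summer, and which species
can pass that abiotic filter shapes whole communities. This package
implements the full analysis chain used in multi-species freezing
resistance surveys of high-mountain grasslands:

1. **Thermal analysis** — detect the latent-heat exotherm in a leaf
   cooling thermogram (2 °C·h⁻¹ ramp, 1 Hz sampling) and read off the
   **ice nucleation temperature** NT (lowest temperature before the
   exotherm) and the **freezing point** FP (highest point of the
   exotherm).
2. **Freezing damage** — score each frozen-and-thawed leaf by
   photoinactivation from chlorophyll fluorescence,
   `PhI = 1 − F_fT / F_max`, and estimate **LT50** (the temperature of
   50 % damage) by linear interpolation between the treatment temperature
   with the highest mean PhI < 50 % and the one with the lowest
   mean PhI > 50 %, on the −5 / −10 / −15 / −19 °C test grid.
3. **Resistance mechanism** — classify each species as freezing
   **tolerant** (LT50 significantly below NT), **avoidant** (LT50 ≈ NT)
   or **sensitive** (LT50 above NT), switching between t and
   Mann–Whitney tests on normality/homogeneity checks.
4. **Community structure** — per plot, the cover-weighted mean
   `CWM = Σ pᵢ xᵢ` and Rao quadratic entropy
   `FD_Rao = Σᵢ Σⱼ pᵢ pⱼ dᵢⱼ` on range-standardized Gower distances
   `dᵢⱼ = |xᵢ − xⱼ| / range`, with the dominant engineer species
   (*Festuca curvifolia*) excluded so it does not mask the accompanying
   flora.
5. **Trends and contrasts** — linear models of CWM / FD / mechanism
   proportions against altitude, Kruskal–Wallis with a Nemenyi post hoc
   and compact letter display across growth forms, Pearson/Spearman trait
   correlations.

A synthetic-data generator (`frost.synthetic`) produces all four input
types — thermograms, damage assays, a 42-species trait table, a 38-plot
cover matrix on a 1940–2428 m gradient — with known truth, so every
stage is testable end-to-end without field data.

## Worked example

```python
from frost import *

scenario = SyntheticScenario(n_species=8, n_plots=12, replicates=5)
ds = simulate_dataset(scenario, seed=42)

# 1. exotherms -> NT / FP per species
results = [detect_exotherm(tr) for tr in ds.traces]
thermal = summarize_species_thermal(results)

# 2. damage -> LT50
from frost.damage import assays_from_frame
res = lt50_from_assay(assays_from_frame(ds.damage_records)[0])

# 3. mechanism
nts = [r.nt_C for r in results if r.species_id == res.species_id and r.detected]
cls = classify_mechanism(nts, [res.lt50_C])

# 4-5. community components and altitude trend
cm = exclude_engineer(ds.community, scenario.engineer_species)
trait = TraitVector("LT50", ds.trait_table.set_index("species_id")["lt50_true_C"])
comp = functional_components_table(cm, [trait])
fit = linear_trend(comp["cwm"], comp["altitude_m"])
```

Output:

```
  species_id  nt_mean_C   nt_se  fp_mean_C
sp01_cushion  -7.571358 0.29573  -5.641982
sp02_cushion  -5.939885 0.33488  -0.454675
sp01_cushion: LT50 = -12.63 C (true -13.54 C)
mechanism: FT (p = 6.84e-05, t_test); true FT
CWM(LT50) vs altitude: slope = -0.01458 C/m, R2 = 0.92, p = 7.48e-07
```

The first species nucleates ice around −7.6 °C but is only damaged near
−12.6 °C — it survives freezing well below ice formation, so it is
classified freezing **tolerant** (FT). At the community level the
cover-weighted mean LT50 falls with altitude: higher plots are assembled
from hardier species.

The same stages are available as a shell tool:

```sh
frost simulate --seed 7 --out study/
frost run --traces study/traces.csv --damage study/damage.csv \
          --matrix study/community.csv --traits study/traits.csv --out out/
```

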