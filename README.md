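# thermoreg

Leaf thermoregulation analysis from paired thermocouple records.

Plants are not strict poikilotherms: leaf temperature (T_leaf) can decouple
from air temperature (T_air) through passive structural traits and active
transpirational cooling. `thermoreg` is a library for quantifying that
decoupling in controlled (glasshouse) experiments, built for plant
ecophysiologists comparing species or provenances — for example cohorts
originating from alpine, coastal temperate and desert biomes measured under
a benign (25 °C) and a high-temperature (38 °C) treatment.

From per-plant 1-min paired (T_leaf, T_air) logger series it computes:

- **Thermal offset** ΔT = T_leaf − T_air (°C), averaged over the
  equilibrated analysis window (12:30–15:00 by default), after trimming
  minutes contaminated by evaporative-cooler cycles
  (T_air ≤ 16 °C benign / ≤ 31 °C high).
- **Thermal coupling strength** β: the mean of ordinary-least-squares
  slopes of T_leaf on T_air in non-overlapping 30-min windows, and the
  resulting class — limited homeothermy (β < 1), poikilothermy (β ≈ 1),
  megathermy (β > 1), with tolerance ε = 0.1 around 1.
- **Leaf structural traits** from raw leaf measurements: LWC = (wet−dry)/wet,
  LDMC = dry/wet, LMA = dry/area (kg m⁻²), LD = dry/(area·thickness)
  (g cm⁻³), plus a correlation-matrix PCA of six traits (area, width,
  thickness, LWC, LD, g_sw).
- **Leaf thermal time constant** τ = φ·LMA·[c_p,w/(LDMC·h) + (c_p,d−c_p,w)/h]
  (s), with h = a_h·√(u/width) the width-dependent heat transfer
  coefficient; defaults φ = 0.5, c_p,w = 4181, c_p,d = 2814 J kg⁻¹ K⁻¹.
- **Treatment × biome statistics**: fixed-effects Type III ANOVA,
  Tukey–Kramer pairwise contrasts, and seeded percentile-bootstrap 95 % CIs
  of group means.
- A **synthetic experiment generator** that emulates the full study design
  (75 plants, 15 species, 2 treatments, cooler-dip air profiles, linear
  leaf–air coupling, biome-clustered traits), so the entire pipeline runs
  and is testable without any raw data download.

## Worked example

```python
from thermoreg import RunConfig, run_pipeline

res = run_pipeline(RunConfig(simulate=True, seed=1))
print(res.metrics.groupby(["biome", "treatment"])["delta_t_mean"].mean().round(2))
```

```
biome      treatment
alpine     benign       0.63
           high        -1.25
desert     benign       0.49
           high        -1.66
temperate  benign       2.00
           high         0.60
```

Positive values: leaves warmer than air (temperate cohorts in both
treatments); negative values: transpirational/structural cooling below air
temperature under heat (alpine and desert cohorts). The same run yields the
per-plant β values and classes, the ANOVA (here treatment F ≈ 121.6, biome
F ≈ 50.8, interaction n.s. on the simulated design), Tukey contrasts,
bootstrap CIs, the 6-trait PCA and per-plant τ — written as tidy CSVs when
`out_dir` is set.

The `examples/` directory holds one short narrative script per capability
(simulation, coupling metrics, traits/PCA, τ, full pipeline). A thin CLI
wraps the same calls:

```bash
thermoreg demo --seed 0 --out demo_out      # zero-config end-to-end run
thermoreg simulate --seed 0 --out data/     # write synthetic CSV inputs
thermoreg run --in data/ --out results/     # analyse an input directory
thermoreg validate-climate                  # check biome climate presets
```

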