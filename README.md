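# clonalfish

Analysis pipeline for life-history individuality experiments on clonal fish
(e.g. the Amazon molly, *Poecilia formosa*): genetically identical
individuals reared separately in near-identical tanks still develop
consistent among-individual differences in behavior, growth, and
reproduction.  `clonalfish` quantifies that individuality and the links
between its layers:

- **Behavior metrics** — daily activity (cm/s, path length over time) and
  feeding time (minutes inside a 5 × 13 cm zone around a food patch) from
  xy trajectory tables sampled at 0.2 s.
- **Repeatability** — the intraclass correlation
  `R = V_ID / (V_ID + V_res)` from random-intercept linear mixed models fit
  by profiled REML, with 95% CIs from 1000 parametric model simulations;
  raw (intercept-only) and adjusted (covariate-controlled) variants.
- **Growth** — per-individual von Bertalanffy curves
  `L(t) = L_inf (1 − e^{−K(t−t0)})` by Levenberg–Marquardt least squares;
  predicted sizes feed all downstream size covariates.
- **Reproduction** — brood sequences, onset, cumulative offspring output,
  and the offspring-size / brood-size trade-off, with trade-off-adjusted
  repeatabilities ("life-history productivity").
- **Linkage** — stepwise-selected models chaining behavior → growth →
  reproduction (e.g. individuals that feed more grow to larger `L_inf`, and
  larger females produce larger offspring).
- **Synthetic cohorts** — a generator with the same latent structure
  (34 individuals, 28 behavior days, 280-day horizon, ~4.5 broods/female),
  so every stage is testable without experimental data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import clonalfish as cf

# simulate a study-scale cohort and run the full analysis
bundle, data = cf.run_synthetic(seed=2, n_sim=1000)
print(bundle.repeatability[["trait", "kind", "R", "ci_low", "ci_high"]].to_string(index=False))
```

```
         trait     kind     R  ci_low  ci_high
      activity      raw 0.329   0.207    0.441
      activity adjusted 0.379   0.248    0.494
       feeding      raw 0.187   0.106    0.265
       feeding adjusted 0.196   0.112    0.279
offspring_size      raw 0.323   0.143    0.492
offspring_size adjusted 0.172   0.000    0.349
    brood_size      raw 0.283   0.108    0.441
    brood_size adjusted 0.227   0.046    0.402
```

Each row is one trait's repeatability: `R` is the share of variance due to
consistent individual differences (33% for daily activity in this cohort),
and the CI comes from 1000 parametric simulations of the fitted model — an
interval excluding 0 means significant individuality.  Activity becomes
*more* repeatable after adjusting for growth and age (0.33 → 0.38) because
the shared within-individual age trend is removed; offspring-size
repeatability drops (0.32 → 0.17) once the brood-size trade-off and female
size are controlled, and what remains is productivity variation.  One
cohort of 34 is noisy: estimates move noticeably between seeds, exactly as
they would between real experiments.

The selected linkage models are in `bundle.final_specs`; with the default
generator the chain shows up as feeding retained in the `L_inf` model and
`L_inf` retained in the offspring-size model:

```python
print(bundle.final_specs["growth_linf"])
# L_inf ~ mean_feeding + mother_id
print(bundle.final_specs["growth_offspring_size"])
# mean_offspring_length ~ L_inf + age_at_parturition_days + mother_id + (1|individual_id)
```

The same pipeline runs from the shell:

```bash
clonalfish simulate --out-dir data/sim --seed 2
clonalfish analyze --behavior data/sim/behavior.csv --sizes data/sim/sizes.csv \
    --broods data/sim/broods.csv --offspring data/sim/offspring.csv \
    --out-dir results --seed 2
clonalfish run-all --out-dir results --seed 2      # simulate + analyze
```

Trajectory tables are converted to daily behavior with
`clonalfish metrics --trajectories tracks.csv --zone 7.5,0,5,13 --out behavior.csv`.
Externally deposited datasets plug in through a YAML column mapping
(template in `docs/deposited_mapping.yaml`,
loader in `clonalfish.deposited`).

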