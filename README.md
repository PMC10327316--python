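# longimpute

Single imputation for missing longitudinal data, MAR missingness
simulation, and longitudinal model evaluation.

Cohort studies that measure the same subjects over repeated waves — here, a
six-wave cardiometabolic cohort recording age, sex, BMI and diastolic blood
pressure (DBP) — routinely lose observations: subjects skip a visit and
return (intermittent missingness) or drop out entirely (monotone
missingness). `longimpute` provides the tools to study what such
missingness does to downstream longitudinal analyses:

* **a synthetic cohort generator** that draws complete six-wave panels
  (Bernoulli sex; truncated-normal baseline age advancing 3 years per wave;
  BMI and DBP from linear models with subject-level random intercepts) and
  then injects missing-at-random (MAR) missingness through wave-specific
  logistic models, `logit P(BMI_ij missing) = β0j + β1·Age_ij + β2·DBP_ij`
  and symmetrically for DBP;
* **all sixteen classical single-imputation (SI) methods** for trajectories:
  cross-sectional (`crossMean`, `crossMedian`, `crossHotDeck`), longitudinal
  (`trajMean`, `trajMedian`, `trajHotDeck`, `locf`, `nocb`, and the four
  `interpolation.*` variants — LOCF, global, local, bisector tail
  strategies), and the four `copyMean.*` methods that refine a
  within-trajectory completion by the population-level average variation
  `AV_k = ȳ·k − ȳ·k^initial`;
* **a random-intercept linear mixed model** (`DBP ~ Age + Sex + BMI + Time +
  (1|subject)`) with REML/ML estimation via a fast profiled likelihood;
* **the REEM longitudinal regression tree**, which alternates a CART-style
  variance-reduction tree on random-effect-adjusted responses
  `y_it − b̂_i` with a mixed model on terminal-node indicators
  `y_it = b_i + Σ_p I(x_it ∈ g_p) μ_p + ε_it` until the restricted
  log-likelihood stabilizes;
* **an evaluation harness**: standardized-residual MSE/RMSE/MAD, deviance
  and AIC; Rubin's-rules pooling for externally produced multiply-imputed
  datasets; and a Monte-Carlo replication driver that compares imputation
  method × analysis model combinations across simulated cohorts.

## Worked example

```python
import longimpute as li

cfg = li.SimulationConfig(n_subjects=1000)
complete = li.generate_complete(cfg, seed=1)
amputed = li.ampute_mar(complete, cfg, seed=1)
print(li.missing_proportions(amputed).round(3))

done = li.impute(amputed, "bmi", "trajMean", on_degenerate="skip").panel
done = li.impute(done, "dbp", "trajMean", on_degenerate="skip").panel
done = done[done.bmi.notna() & done.dbp.notna()]

fit = li.fit_lmm(done, "dbp", ["age", "sex", "bmi", "time"])
print(fit.params.round(4))
```

prints

```
        bmi    dbp
wave
1     0.249  0.241
2     0.245  0.263
3     0.204  0.187
4     0.191  0.163
5     0.229  0.194
6     0.298  0.303
intercept    55.9742
age           0.1376
sex          -3.2627
bmi           0.6172
time         -0.2222
```

Per-wave missing proportions of roughly 0.19–0.30 match the cohort the
generator emulates, and the BMI coefficient after trajectory-mean
imputation (0.617) is visibly attenuated relative to the generating value
0.707 — the attenuation the package exists to quantify. The same completed
panel can be fed to the tree model (`li.fit_reem(done)`), which here
finds 4 terminal nodes and a slightly smaller standardized-residual MSE
(0.849) than the linear mixed model (0.852).

The same pipeline is available from the shell:

```bash
longimpute simulate --n 1000 --seed 1 --out panel.csv
longimpute impute --in panel.csv --variable bmi --method copyMean.locf --out imputed.csv
longimpute fit --model lmm --in imputed.csv --out fit.json --metrics metrics.json
longimpute replicate --methods trajMean,crossMean --models lmm,reem \
    --reps 100 --seed 7 --out report.csv
```

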