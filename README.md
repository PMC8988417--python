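# hetsurv

Quantifying the impact of **predictor measurement heterogeneity** on the
performance of time-to-event prediction models.

A prognostic model is derived and validated with a predictor measured one
way (say, BMI from scale and tape at a medical examination) but implemented
in a setting where the same predictor is measured another way (self-reported
BMI). Even a well-validated model can then miscalibrate or lose
discrimination, without anything about the model changing. `hetsurv` is for
biostatisticians and prediction-model developers who want to *anticipate*
that degradation at validation time, before implementation.

## What it computes

The implementation-setting measurement W of a validation-setting predictor
X is modelled with a classical linear measurement-error form

```
W = ψ + θ·X + ε,   ε ~ N(0, σ_ε²)
```

(ψ: additive systematic shift; θ: multiplicative systematic association;
σ_ε: extra random variation). For each scenario (ψ, θ, σ_ε) in a grid, the
*unchanged* model is evaluated on the validation cohort with X replaced by
W, using a horizon-specific battery:

- **O/E ratio** — observed (Kaplan–Meier) over mean predicted event
  probability at the horizon t; < 1 means predicted risks are too high;
- **AUC(t)** — cumulative/dynamic time-dependent AUC with IPCW
  (inverse-probability-of-censoring, reverse-Kaplan–Meier) weights;
- **Brier(t)** — IPCW-weighted squared prediction error;
- **IPA(t)** — 1 − Brier_model/Brier_null, the index of prediction accuracy
  against a null model predicting the marginal Kaplan–Meier risk.

The package also provides a Cox-exponential cohort simulator (event times by
inverse-transform sampling of the cumulative hazard, three censoring
regimes), exponential and Cox proportional-hazards fitting (sklearn-style
estimators `ExponentialPHModel` / `CoxPHModel` or functional wrappers),
baseline recalibration via a linear-predictor offset, percentile bootstrap
CIs, and a seven-step *quantitative prediction error analysis* (QPEA)
report: per-scenario metrics, bands marginalized over the systematic
heterogeneity ranges per σ_ε level, figures, and a report skeleton.

## Worked example

Derive a Cox model on one simulated cohort, validate on another, and sweep
the default 27-scenario heterogeneity grid:

```python
import numpy as np
from hetsurv import (DGMConfig, QPEAConfig, build_grid, fit_cox,
                     generate_cohort, run_scenarios)

derivation = generate_cohort(DGMConfig(n=100_000, seed=1))
validation = generate_cohort(
    DGMConfig(n=100_000, censoring_mode="administrative", seed=2))
model = fit_cox(derivation, ["x"])
print(f"fitted hazard ratio: {np.exp(model.coefficients[0]):.3f}")

config = QPEAConfig(flagged_predictor="x", grid=build_grid(levels_per_param=3),
                    horizon=6.5, n_bootstrap=0, seed=7)
report = run_scenarios(validation, model, config)
ref = report.reference
print(f"homogeneity reference: O/E {ref.oe_ratio:.3f}  "
      f"AUC {ref.auc:.3f}  IPA {ref.ipa:.3f}")
cols = ["psi", "theta", "sigma_eps", "oe_ratio", "auc", "ipa"]
print(report.scenario_table[cols].round(3).head(6).to_string(index=False))
```

Output:

```
fitted hazard ratio: 2.008
homogeneity reference: O/E 1.006  AUC 0.736  IPA 0.170
 psi  theta  sigma_eps  oe_ratio   auc    ipa
-0.3   0.50      0.000     1.196 0.736  0.102
-0.3   0.50      0.707     1.159 0.633  0.022
-0.3   0.50      1.414     1.103 0.575 -0.154
-0.3   1.25      0.000     1.122 0.736  0.154
-0.3   1.25      0.707     1.107 0.704  0.091
-0.3   1.25      1.414     1.076 0.653 -0.052
```

Reading it: the fit recovers the generating hazard ratio of 2. Under
measurement homogeneity the model is mean-calibrated (O/E ≈ 1.0) with
AUC(6.5) ≈ 0.74 and IPA(6.5) ≈ 0.17. A negative shift ψ = −0.3 makes
predicted risks too low (O/E > 1) but — being rank-preserving — leaves the
AUC untouched; growing random heterogeneity σ_ε erodes discrimination
(AUC 0.736 → 0.575) and can make the model worse than predicting the
marginal risk for everyone (IPA < 0). `render_report(report, "out/")`
writes the tables, band figures and the seven-step report text.

The same workflow is scriptable from a shell:

```bash
hetsurv simulate --n 100000 --seed 1 --out cohort.csv
hetsurv fit --cohort cohort.csv --predictor x --out model.yaml
hetsurv validate --cohort cohort.csv --model model.yaml --horizon 6.5
hetsurv qpea --cohort cohort.csv --model model.yaml --config qpea.yaml --out report/
hetsurv fixture --out example_cohort.csv   # synthetic 15k-subject example
```

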