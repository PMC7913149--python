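# tamoxsim

Stochastic simulation of **endoxifen target attainment under tamoxifen
dosing strategies and medication non-adherence**.

Tamoxifen's clinical effect in oestrogen-receptor-positive breast cancer is
largely carried by its CYP2D6-formed active metabolite endoxifen; a minimum
endoxifen steady-state concentration (C_SS,min ENDX) of 5.97 ng/mL has been
proposed as a therapeutic threshold. Long-term adherence to tamoxifen is
poor, and individualised dosing that titrates a patient exactly *to* the
target leaves no buffer when doses are missed. `tamoxsim` quantifies that
trade-off: it simulates a virtual patient cohort on a joint
tamoxifen–endoxifen population PK model and compares five dosing
strategies — conventional 20 mg, CYP2D6 genotype-guided dosing, and three
variants of model-informed precision dosing (MIPD) with MAP-Bayesian
forecasting from virtual therapeutic-drug-monitoring (TDM) samples — under
full adherence and under one or two consecutive missed doses per week.

The package is aimed at pharmacometricians and clinical-pharmacology
researchers exploring dose-individualisation policies in silico.

## Model

Linear parent–metabolite cascade with first-order absorption (rate `ka`,
lag `t_lag`): tamoxifen central compartment (V_TAM/F) cleared by endoxifen
formation (CL23/F) and by other routes (CL20/F); endoxifen central
compartment (V_ENDX/F) eliminated linearly (CL30/F). CYP2D6 activity score
acts as a fractional change on CL23; age and body weight as power models on
CL20; interindividual variability is log-normal on both clearances.
Profiles are evaluated by closed-form tri-exponential superposition, and the
weekly-repeating intake patterns by an exact geometric-series periodic
steady state. MIPD estimates a patient's random effects by maximum a
posteriori (MAP) estimation from three trough samples (weeks 2–4), then
picks the smallest dose on a 5–120 mg grid whose predicted steady-state
trough reaches the target. See `docs/methods.md` for the full account.

The shipped PK parameter values are clearly-labelled placeholder defaults
that produce plausible exposure; every value is editable in
`src/tamoxsim/data/default_study.yaml`.

## Worked example

```python
import numpy as np
from tamoxsim import (Covariates, MapForecast, PopulationModel,
                      StudyConfig, NonAdherenceStudy, simulate_tdm,
                      default_strategies, select_mipd_dose)

# --- MAP-Bayesian forecast for one gIM patient on a 30 mg initial dose ---
model = PopulationModel()
cov = Covariates(activity_score=1.0, age=62, weight=75)
obs = simulate_tdm(model, cov, 0.35, -0.1, 30.0, rng=np.random.default_rng(7))
print([round(o.concentration, 2) for o in obs])   # [10.64, 13.88, 13.49] ng/mL
fit = MapForecast(model, cov, obs, 30.0).fit()
print(fit.summary())
dose, capped = select_mipd_dose(fit, default_strategies()[2])  # 5.97 ng/mL target
print(dose)                                        # 20.0 mg QD
```

```
MAP-Bayesian forecast (endoxifen troughs)
=============================================
observations: 3  dose: 30 mg QD  sigma: 0.2
converged: True  objective: 0.849178
effect          estimate   approx SE
eta_CL23          0.3366      0.1962
eta_CL20         -0.0856      0.2591
```

The estimated formation clearance sits ~40% above the gIM typical value
(`exp(0.34)`), so 20 mg already yields a predicted trough of ~9.9 ng/mL and
the selector steps down from the 30 mg starting dose.

```python
# --- the full study at n = 2,000 virtual patients ---
cfg = StudyConfig()
cfg = cfg.model_copy(update={"population": cfg.population.model_copy(update={"n": 2000})})
print(NonAdherenceStudy(cfg).run(seed=1).summary())
```

```
% of patients below target (adherent, 0 missed doses/week):
stratum         conventional     cyp2d6_guided         mipd_5.97  mipd_5.97_plus10            mipd_9
Overall                 31.1              18.4              11.2             0.673             0.253
...
% below target, non-adherent, 2 missed dose(s)/week:
Overall                 53.7              40.6                64              12.9              9.61
...
exposure distribution (adherent patients): median [CV%]:
  cyp2d6_guided        9.99 ng/mL [55%]  target attainment 81.6%
  mipd_9               11.2 ng/mL [21.9%]  target attainment 99.7%
```

Read: among adherent patients MIPD performs best, but when two consecutive
doses per week are missed, MIPD titrated exactly to the 5.97 ng/mL target
becomes the *worst* strategy (64% below target) because it leaves no
exposure buffer — whereas MIPD targeting the higher 9 ng/mL safeguard keeps
nearly everyone above target at a fraction of the between-patient
variability of genotype-guided dosing.

The same run is available from a shell:

```sh
tamoxsim run-study --n 2000 --seed 1 --out results/
tamoxsim summarize --results results/
tamoxsim validate-config src/tamoxsim/data/default_study.yaml
```

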