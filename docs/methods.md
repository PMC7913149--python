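# Methods

## Scientific setting

Tamoxifen is an oral endocrine therapy for oestrogen-receptor-positive
breast cancer. Its clinical activity is largely carried by the CYP2D6-formed
metabolite endoxifen, and a minimum endoxifen concentration at steady state
(C_SS,min ENDX) of 5.97 ng/mL has been proposed as a therapeutic threshold.
Two well-documented problems interact: (a) CYP2D6 genetic variability makes
endoxifen exposure under one-size-fits-all dosing highly variable, and
(b) long-term adherence to tamoxifen is poor. `tamoxsim` simulates how
medication non-adherence (one, or two consecutive, missed doses per week)
erodes target attainment under five dosing strategies, including
model-informed precision dosing (MIPD) with MAP-Bayesian forecasting.

## Pharmacokinetic model

A joint parent-metabolite compartmental model with first-order absorption:

```
depot --ka(lag tlag)--> tamoxifen central (V_TAM/F)
tamoxifen --CL23/F--> endoxifen central (V_ENDX/F) --CL30/F--> out
tamoxifen --CL20/F--> other metabolites
```

The system is linear, so concentrations follow the per-dose tri-exponential
closed form superposed over dose events. Eigenvalues are `ka`,
`k10 = (CL20 + CL23)/V_TAM`, `k30 = CL30/V_ENDX`. Covariate models: CYP2D6
activity score (AS) enters as a fractional change on CL23
(`CL23,i = CL23 · (1 + θ_AS)`); age and weight enter as power models on CL20
relative to 55 y / 70 kg references. Interindividual variability is
log-normal on CL23 and CL20. Doses are mg, volumes L, concentrations ng/mL
(1 mg into an L-scale volume is 1000 µg/L, i.e. the unit factor is 1000).

### Parameter values

The packaged parameter values (`src/tamoxsim/data/default_study.yaml`) are
placeholder defaults chosen once for physiological plausibility, not
estimates fitted to data: tamoxifen elimination half-life ≈ 6 d
(V_TAM 1200 L, total CL 5.76 L/h), endoxifen effective half-life ≈ 2 d
(V_ENDX 400 L, CL30 6 L/h), endoxifen trough ≈ 11 ng/mL at 20 mg once daily
in a reference normal metaboliser, and AS-class exposure fractions
(AS 0 ≈ 25%, AS 1 ≈ 60% of AS 2) consistent with the reported spread of
endoxifen exposure across CYP2D6 phenotypes. ω²(CL23) = 0.20 and
ω²(CL20) = 0.09 give an endoxifen-exposure CV of roughly 50–60% under
uniform dosing. To reproduce a specific published simulation exactly, the
source model's estimates must be transcribed into the config; all headline
percentages scale with that choice, while the qualitative strategy ordering
does not.

### Numerical choices

* Production path: closed-form superposition; an independent stiff-safe ODE
  integration lives in the test suite as an oracle and agrees to <1e-6
  relative error on randomized draws.
* Near-degenerate eigenvalues (e.g. `ka ≈ k30`) are separated by a 1e-8
  relative perturbation. This balances the O(ε) perturbation bias against
  the O(ulp/ε) cancellation error of the partial-fraction coefficients;
  both stay below ~1e-7, well under every tolerance used.
* Periodic steady state of a weekly-repeating intake pattern is computed
  exactly by summing each exponential over all past cycles (geometric
  series with ratio `exp(-168·λ)`), then taking the minimum over a 0.25 h
  grid augmented with the pre-dose instants. The cycle minimum after
  26 weeks of explicit simulation agrees with this limit to <0.5%.
* C_SS,min under non-adherence is the minimum over the whole steady-state
  weekly cycle (the trough at the end of the missed-dose gap) — the
  conservative reading of "minimum concentration at steady state". At
  periodic steady state the placement of the missed days within the cycle
  does not change this minimum (verified by test).

## Virtual population

Default cohort: 10,000 patients; phenotype mixture 56.6% gNM / 37.8% gIM /
5.6% gPM. Classification from the activity score: AS ≥ 1.5 → gNM (missing
AS imputed to 2), AS 0.5–1 → gIM, AS 0 → gPM. Because the within-class AS
composition of the original clinical database is not public, defaults are
gNM = 80% AS 2 + 20% AS 1.5 and gIM = 50% AS 1 + 50% AS 0.5 (configurable).
Age ~ truncated normal(55, 12) on [25, 90] y and weight ~ log-normal
(median 70 kg, CV 20%) are parametric stand-ins for resampling a private
covariate table. Random effects are drawn independently per patient
(no eta correlation is modelled, as none is specified).

What passing tests therefore show: the pipeline's behaviour under a
*synthetic* cohort with the stated mixture and plausible marginals. They do
not certify the absolute risk percentages of any real cohort, which depend
on the real covariate joint distribution and the fitted PK estimates.

## Dosing strategies

1. `conventional` — 20 mg QD.
2. `cyp2d6_guided` — 20/30/60 mg QD for gNM/gIM/gPM.
3. `mipd_5.97` — genotype-guided initial dose for 4 weeks; virtual trough
   samples at the end of the dosing interval on days 14/21/28 with
   multiplicative log-normal residual error (σ = 0.20, a standard magnitude
   for concentration data; the residual model form is a package choice);
   MAP estimation of (η_CL23, η_CL20); then the smallest dose on the grid
   {5, 10, 20, 30, 40, 60, 80, 100, 120} mg whose predicted full-adherence
   steady-state trough reaches 5.97 ng/mL (cap at 120 mg, the highest dose
   reported without additional toxicity). "Smallest dose meeting target"
   matches the threshold character of the target.
4. `mipd_5.97_plus10` — strategy 3 plus a fixed 10 mg on every selected
   dose, mimicking common practice; the increment is applied after the cap
   (a 130 mg result is possible and flagged `capped`).
5. `mipd_9` — strategy 3 targeting 9 ng/mL, the lowest reported mean trough
   in normal metabolisers, as a non-adherence safeguard.

The MAP objective is penalised least squares on the log scale,
`J(η) = Σ (ln y − ln f(η))²/σ² + η²₂₃/ω²₂₃ + η²₂₀/ω²₂₀`, minimised by
L-BFGS-B from the prior mode (objective tolerance 1e-8; the 2-D problem is
well-behaved and needs no multi-start). Non-convergence falls back to
η = 0 with a warning, i.e. the patient keeps the genotype-guided dose.
A zero prior variance pins the corresponding effect at 0. The reported
uncertainty is the Laplace approximation 2·H⁻¹ (the objective is −2·log
posterior up to a constant). All MIPD variants of a patient share the same
TDM samples and MAP fit — counterfactual arms differing only in the
selection rule — which makes the +10 mg arm exactly a 10 mg shift and the
9 ng/mL arm dose-dominant patient by patient.

## Adherence design and assessment

All patients take every dose for 26 weeks (the maintenance dose applies
from day 28 and is never revised). For the second 26 weeks a seeded
Bernoulli(0.40) split marks the non-adherent subset; that same subset is
run through both missed-dose arms (1 missed dose = day 7; 2 consecutive
missed = days 6–7 of each weekly cycle). "6 months" is implemented as 26
exact weeks for cycle alignment. At 12 months the weekly pattern has
reached its periodic steady state, so the assessment uses the closed-form
cycle minimum of the maintenance regimen; the tests verify agreement with
explicit 52-week timelines (364/338/312 dose events for 0/1/2 missed).
With <80% intake defining non-adherence, the boundary is 1.4 missed doses
per week: one missed dose (6/7 ≈ 86%) is technically adherent, two missed
doses (5/7 ≈ 71%) are not.

## Risk aggregation

Percent at risk = 100 × (count with C_SS,min ENDX < threshold)/n per
strategy × scenario × phenotype stratum (plus Overall); empty strata are
flagged missing, never reported as 0. Relative risk increase = stratum risk
under a missed-dose scenario divided by the full-adherence baseline risk,
undefined (flagged) at zero baseline. Distribution summaries report the
median and the arithmetic CV% (100·SD/mean) over adherent patients;
a geometric CV is available (`tamoxsim.risk.geometric_cv`) since "%CV" is
ambiguous in the literature. Shaped tables render values to 3 significant
figures.

## Reproducibility and problem sizes

A single master seed feeds `numpy.random.SeedSequence`, which spawns named
sub-streams (population, TDM noise, adherence assignment), so stages can be
re-run independently with identical streams and whole runs are bit-for-bit
reproducible. The bundled acceptance script and the heavier tests run the
study at n = 2,000 patients, the package's default demonstration size
(~15 s on one core; n = 10,000 runs in about a minute).

## Known limitations

* Placeholder PK parameters: absolute risk percentages are
  configuration-dependent; only structure and qualitative orderings are
  intrinsic.
* No comedication/CYP2D6-inhibitor effects, no time-varying covariates or
  adherence probability, no enterohepatic recirculation or nonlinearity,
  and no pharmacodynamic (recurrence) modelling — exposure only.
* The MIPD forecast assumes full adherence during titration and never
  revises the dose afterwards, by design of the simulated framework.
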