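"""Population PK model definition: typical parameters, covariate models, IIV.

The structural model is a linear parent-metabolite cascade: a depot (gut)
compartment from which tamoxifen is absorbed first-order (``ka``) after a lag
time (``tlag``) into a central tamoxifen compartment (apparent volume
``v_tam``), from which it is cleared either by formation of endoxifen
(``cl23``) or by all other metabolic routes lumped together (``cl20``).
Endoxifen distributes in its own central compartment (``v_endx``) and is
eliminated linearly (``cl30``).  All disposition parameters are apparent
(scaled by the unknown oral bioavailability F).

Covariate models:

* CYP2D6 activity score acts on the endoxifen formation clearance as a
  fractional change: ``CL23_i = cl23 * (1 + theta_as[AS])``.
* Age and body weight act on the competing tamoxifen clearance as power
  models: ``CL20_i = cl20 * (age/age_ref)**theta_age * (wt/wt_ref)**theta_wt``.

Between-patient variability is log-normal on both clearances
(``CL_i = CL_typ * exp(eta)``, ``eta ~ N(0, omega2)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Phenotype",
    "VALID_ACTIVITY_SCORES",
    "classify_phenotype",
    "CovariateError",
    "Covariates",
    "PopulationModel",
    "IndividualParameters",
]

#: Activity scores the CYP2D6 genotype panel can produce.
VALID_ACTIVITY_SCORES = (0.0, 0.5, 1.0, 1.5, 2.0)


class Phenotype(str, Enum):
    """CYP2D6 genotype-predicted metaboliser phenotype."""

    gNM = "gNM"  # normal metaboliser, activity score >= 1.5 (missing imputed to 2)
    gIM = "gIM"  # intermediate metaboliser, activity score 0.5-1
    gPM = "gPM"  # poor metaboliser, activity score 0


class CovariateError(ValueError):
    """Raised for covariates outside the domain the population can generate."""


def classify_phenotype(activity_score: Optional[float]) -> Phenotype:
    """Map a CYP2D6 activity score to its genotype-predicted phenotype.

    A missing score is imputed to AS 2 and hence classified gNM.  Scores
    outside {0, 0.5, 1, 1.5, 2} raise :class:`CovariateError`.
    """
    if activity_score is None or (
        isinstance(activity_score, float) and math.isnan(activity_score)
    ):
        return Phenotype.gNM
    score = float(activity_score)
    if score not in VALID_ACTIVITY_SCORES:
        raise CovariateError(
            f"activity score {activity_score!r} not in {VALID_ACTIVITY_SCORES}"
        )
    if score >= 1.5:
        return Phenotype.gNM
    if score >= 0.5:
        return Phenotype.gIM
    return Phenotype.gPM


class Covariates(BaseModel):
    """Patient covariates entering the PK model."""

    activity_score: Optional[float] = None
    age: float = Field(gt=0, description="age in years")
    weight: float = Field(gt=0, description="body weight in kg")

    @field_validator("activity_score")
    @classmethod
    def _check_score(cls, v):
        if v is not None and not math.isnan(v) and float(v) not in VALID_ACTIVITY_SCORES:
            raise ValueError(f"activity score {v!r} not in {VALID_ACTIVITY_SCORES}")
        return v

    @property
    def phenotype(self) -> Phenotype:
        return classify_phenotype(self.activity_score)

    @property
    def effective_activity_score(self) -> float:
        """Activity score with missing values imputed to 2."""
        if self.activity_score is None or math.isnan(self.activity_score):
            return 2.0
        return float(self.activity_score)


class PopulationModel(BaseModel):
    """Typical PK parameters, covariate coefficients and variability terms.

    Shipped defaults are placeholder values chosen to produce plausible
    tamoxifen/endoxifen exposure (endoxifen trough around 10 ng/mL at
    20 mg once daily in a reference gNM patient); replace them with published
    joint parent-metabolite model estimates to reproduce a specific study.
    Units: rate constants 1/h, times h, volumes L, clearances L/h.
    """

    ka: float = Field(default=0.5, gt=0, description="absorption rate constant (1/h)")
    tlag: float = Field(default=0.5, ge=0, description="absorption lag time (h)")
    v_tam: float = Field(default=1200.0, gt=0, description="tamoxifen V/F (L)")
    cl20: float = Field(default=5.3, gt=0, description="tamoxifen CL/F to other metabolites (L/h)")
    cl23: float = Field(default=0.46, gt=0, description="endoxifen formation CL/F (L/h)")
    v_endx: float = Field(default=400.0, gt=0, description="endoxifen V/F (L)")
    cl30: float = Field(default=6.0, gt=0, description="endoxifen elimination CL/F (L/h)")

    # CYP2D6 activity score -> fractional change on cl23 (reference AS 2)
    theta_as: dict[float, float] = Field(
        default_factory=lambda: {0.0: -0.75, 0.5: -0.55, 1.0: -0.40, 1.5: -0.15, 2.0: 0.0}
    )
    theta_age: float = -0.2
    theta_wt: float = 0.75
    age_ref: float = Field(default=55.0, gt=0)
    wt_ref: float = Field(default=70.0, gt=0)

    omega2_cl23: float = Field(default=0.20, ge=0, description="IIV variance on ln CL23")
    omega2_cl20: float = Field(default=0.09, ge=0, description="IIV variance on ln CL20")
    sigma_prop: float = Field(
        default=0.20, ge=0, description="SD of the log-scale proportional residual error"
    )

    @model_validator(mode="after")
    def _check_theta_as(self):
        for score, frac in self.theta_as.items():
            if float(score) not in VALID_ACTIVITY_SCORES:
                raise ValueError(f"theta_as key {score!r} is not a valid activity score")
            if 1.0 + frac <= 0:
                raise ValueError(f"theta_as[{score}]={frac} implies non-positive CL23")
        return self

    def fractional_change(self, activity_score: float) -> float:
        """CYP2D6 fractional-change multiplier ``1 + theta_AS`` on CL23."""
        score = float(activity_score)
        if score not in self.theta_as:
            raise CovariateError(
                f"no theta_as entry for activity score {score}; model defines "
                f"{sorted(self.theta_as)}"
            )
        return 1.0 + self.theta_as[score]

    def apply_covariates(self, cov: Covariates) -> tuple[float, float]:
        """Typical individual clearances ``(CL23_typ, CL20_typ)`` for covariates."""
        cl23_typ = self.cl23 * self.fractional_change(cov.effective_activity_score)
        cl20_typ = (
            self.cl20
            * (cov.age / self.age_ref) ** self.theta_age
            * (cov.weight / self.wt_ref) ** self.theta_wt
        )
        return cl23_typ, cl20_typ

    def individualize(
        self, cov: Covariates, eta_cl23: float = 0.0, eta_cl20: float = 0.0
    ) -> "IndividualParameters":
        """Individual parameter set from covariates and random effects."""
        if not (math.isfinite(eta_cl23) and math.isfinite(eta_cl20)):
            raise ValueError("random effects must be finite")
        cl23_typ, cl20_typ = self.apply_covariates(cov)
        return IndividualParameters(
            ka=self.ka,
            tlag=self.tlag,
            v_tam=self.v_tam,
            cl23_i=cl23_typ * math.exp(eta_cl23),
            cl20_i=cl20_typ * math.exp(eta_cl20),
            v_endx=self.v_endx,
            cl30=self.cl30,
            eta_cl23=eta_cl23,
            eta_cl20=eta_cl20,
        )


@dataclass(frozen=True)
class IndividualParameters:
    """Structural parameters of one (virtual) patient."""

    ka: float
    tlag: float
    v_tam: float
    cl23_i: float
    cl20_i: float
    v_endx: float
    cl30: float
    eta_cl23: float = 0.0
    eta_cl20: float = 0.0

    def __post_init__(self):
        for name in ("ka", "v_tam", "cl23_i", "cl20_i", "v_endx", "cl30"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.tlag < 0:
            raise ValueError("tlag must be non-negative")

    @property
    def k10(self) -> float:
        """Total tamoxifen elimination rate constant (1/h)."""
        return (self.cl20_i + self.cl23_i) / self.v_tam

    @property
    def k30(self) -> float:
        """Endoxifen elimination rate constant (1/h)."""
        return self.cl30 / self.v_endx
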