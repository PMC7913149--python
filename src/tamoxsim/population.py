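"""Virtual patient population emulating the simulation cohort.

Generates virtual breast-cancer patients with a CYP2D6 activity-score
mixture (56.6% gNM / 37.8% gIM / 5.6% gPM by default), age and body-weight
marginals, and independent log-normal random effects on the two clearances
carrying between-patient variability.  The age/weight distributions are
parametric stand-ins for a clinical covariate table that is not public:
age ~ truncated normal(55, 12) on [25, 90] years, weight ~ log-normal with
median 70 kg and ~20% CV.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .params import (
    Covariates,
    Phenotype,
    VALID_ACTIVITY_SCORES,
    classify_phenotype,
)

__all__ = [
    "PopulationSpec",
    "VirtualPatient",
    "generate_population",
    "population_to_frame",
    "write_population",
    "read_population",
    "PopulationFileError",
]

#: column order of the population CSV
POPULATION_COLUMNS = (
    "id",
    "activity_score",
    "phenotype",
    "age",
    "weight",
    "eta_cl23",
    "eta_cl20",
)


class PopulationSpec(BaseModel):
    """Sampling specification of the virtual population."""

    n: int = Field(default=10_000, ge=0)
    phenotype_probs: tuple[float, float, float] = (0.566, 0.378, 0.056)
    # activity-score composition within each phenotype class
    as_within_gnm: dict[float, float] = Field(default_factory=lambda: {2.0: 0.8, 1.5: 0.2})
    as_within_gim: dict[float, float] = Field(default_factory=lambda: {1.0: 0.5, 0.5: 0.5})
    age_mean: float = 55.0
    age_sd: float = Field(default=12.0, gt=0)
    age_range: tuple[float, float] = (25.0, 90.0)
    weight_median: float = Field(default=70.0, gt=0)
    weight_cv: float = Field(default=0.20, gt=0)
    omega2_cl23: float = Field(default=0.20, ge=0)
    omega2_cl20: float = Field(default=0.09, ge=0)
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self):
        probs = np.asarray(self.phenotype_probs)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("phenotype_probs must be non-negative and sum to 1")
        for name, dist in (("as_within_gnm", self.as_within_gnm), ("as_within_gim", self.as_within_gim)):
            vals = np.asarray(list(dist.values()))
            if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must be non-negative and sum to 1")
            for score in dist:
                if float(score) not in VALID_ACTIVITY_SCORES:
                    raise ValueError(f"{name} key {score!r} is not a valid activity score")
        expected = {"as_within_gnm": Phenotype.gNM, "as_within_gim": Phenotype.gIM}
        for name, pheno in expected.items():
            for score in getattr(self, name):
                if classify_phenotype(float(score)) is not pheno:
                    raise ValueError(f"{name} contains score {score} outside class {pheno.value}")
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] <= 0:
            raise ValueError("age_range must be a positive, increasing interval")
        return self


@dataclass(frozen=True)
class VirtualPatient:
    """One virtual patient: covariates plus individual random effects."""

    id: int
    covariates: Covariates
    eta_cl23: float
    eta_cl20: float

    @property
    def phenotype(self) -> Phenotype:
        return self.covariates.phenotype


def _sample_scores(rng: np.random.Generator, spec: PopulationSpec, n: int) -> np.ndarray:
    """Sample activity scores from the phenotype mixture."""
    classes = rng.choice(3, size=n, p=np.asarray(spec.phenotype_probs))
    scores = np.zeros(n)
    for idx, dist in ((0, spec.as_within_gnm), (1, spec.as_within_gim), (2, {0.0: 1.0})):
        mask = classes == idx
        if not mask.any():
            continue
        keys = np.asarray(list(dist.keys()), dtype=float)
        probs = np.asarray(list(dist.values()), dtype=float)
        scores[mask] = rng.choice(keys, size=mask.sum(), p=probs)
    return scores


def _sample_age(rng: np.random.Generator, spec: PopulationSpec, n: int) -> np.ndarray:
    """Truncated-normal ages by rejection (acceptance ~0.98 at defaults)."""
    lo, hi = spec.age_range
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(spec.age_mean, spec.age_sd, size=2 * (n - filled) + 16)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def generate_population(
    spec: PopulationSpec, seed: Optional[Union[int, np.random.SeedSequence]] = None
) -> list[VirtualPatient]:
    """Draw ``spec.n`` virtual patients; reproducible for a fixed seed."""
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    n = spec.n
    scores = _sample_scores(rng, spec, n)
    ages = _sample_age(rng, spec, n)
    sigma_wt = np.sqrt(np.log(1.0 + spec.weight_cv**2))
    weights = spec.weight_median * np.exp(rng.normal(0.0, sigma_wt, size=n))
    eta23 = rng.normal(0.0, np.sqrt(spec.omega2_cl23), size=n)
    eta20 = rng.normal(0.0, np.sqrt(spec.omega2_cl20), size=n)
    return [
        VirtualPatient(
            id=i,
            covariates=Covariates(
                activity_score=float(scores[i]), age=float(ages[i]), weight=float(weights[i])
            ),
            eta_cl23=float(eta23[i]),
            eta_cl20=float(eta20[i]),
        )
        for i in range(n)
    ]


def population_to_frame(patients: Sequence[VirtualPatient]) -> pd.DataFrame:
    """Tidy one-row-per-patient covariate table."""
    return pd.DataFrame(
        {
            "id": [p.id for p in patients],
            "activity_score": [p.covariates.activity_score for p in patients],
            "phenotype": [p.phenotype.value for p in patients],
            "age": [p.covariates.age for p in patients],
            "weight": [p.covariates.weight for p in patients],
            "eta_cl23": [p.eta_cl23 for p in patients],
            "eta_cl20": [p.eta_cl20 for p in patients],
        },
        columns=list(POPULATION_COLUMNS),
    )


class PopulationFileError(ValueError):
    """Malformed population file; message names the offending line."""


def write_population(patients: Sequence[VirtualPatient], path: Union[str, Path]) -> None:
    """Write the population CSV (header always present)."""
    population_to_frame(patients).to_csv(path, index=False)


def read_population(path: Union[str, Path, io.IOBase]) -> list[VirtualPatient]:
    """Read a population CSV back into patients, validating every row."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PopulationFileError(f"cannot parse population file: {exc}") from exc
    if list(frame.columns) != list(POPULATION_COLUMNS):
        raise PopulationFileError(
            f"header mismatch at line 1: expected {list(POPULATION_COLUMNS)}, got {list(frame.columns)}"
        )
    patients: list[VirtualPatient] = []
    for row_idx, row in frame.iterrows():
        line_no = int(row_idx) + 2  # header is line 1
        try:
            cov = Covariates(
                activity_score=None if pd.isna(row["activity_score"]) else float(row["activity_score"]),
                age=float(row["age"]),
                weight=float(row["weight"]),
            )
            patient = VirtualPatient(
                id=int(row["id"]),
                covariates=cov,
                eta_cl23=float(row["eta_cl23"]),
                eta_cl20=float(row["eta_cl20"]),
            )
            if str(row["phenotype"]) != patient.phenotype.value:
                raise ValueError(
                    f"phenotype {row['phenotype']!r} inconsistent with activity score"
                )
        except (ValueError, TypeError) as exc:
            raise PopulationFileError(f"invalid patient at line {line_no}: {exc}") from exc
        patients.append(patient)
    return patients
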