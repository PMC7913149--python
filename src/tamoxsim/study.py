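"""End-to-end orchestration of the in-silico non-adherence study.

:class:`NonAdherenceStudy` wires the pipeline together: virtual population
-> strategy dose decisions (including virtual TDM and MAP forecasting for
the MIPD arms) -> adherence assignment -> 12-month exposure assessment ->
risk aggregation.  ``run()`` returns a :class:`StudyResults` object holding
the tidy result tables, with ``summary()`` and ``save()``.

Randomness is controlled by a single master seed from which named
sub-streams (population, TDM noise, adherence assignment) are derived
hierarchically, so arms can be re-run independently with identical streams.

All MIPD variants of one patient share the same TDM samples and MAP
estimate; they differ only in the target (and increment) applied to the
dose-selection step.  This counterfactual sharing is what makes the
"+10 mg" arm exactly the 5.97 ng/mL arm shifted by 10 mg, and the 9 ng/mL
arm dose-dominant over it, patient by patient.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import __version__ as _pkg_version
from .adherence import AdherenceSettings, assign_adherence
from .dosing import (
    MapForecast,
    StrategyConfig,
    conventional_dose,
    default_strategies,
    genotype_guided_dose,
    select_mipd_dose,
    simulate_tdm,
)
from .params import Phenotype, PopulationModel
from .pk import cycle_min_endx_per_mg
from .population import PopulationSpec, generate_population, population_to_frame
from .risk import (
    distribution_summary,
    plot_risk_bars,
    relative_risk_increase,
    risk_table,
    write_tables,
)

__all__ = [
    "StudyConfig",
    "StudyError",
    "NonAdherenceStudy",
    "StudyResults",
    "run_study",
    "load_config",
    "validate_config_file",
]

_PATTERNS = {0: (1, 1, 1, 1, 1, 1, 1), 1: (1, 1, 1, 1, 1, 1, 0), 2: (1, 1, 1, 1, 1, 0, 0)}


class StudyError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class StudyConfig(BaseModel):
    """Complete configuration of one study run."""

    model: PopulationModel = Field(default_factory=PopulationModel)
    population: PopulationSpec = Field(default_factory=PopulationSpec)
    strategies: list[StrategyConfig] = Field(default_factory=default_strategies)
    adherence: AdherenceSettings = Field(default_factory=AdherenceSettings)
    seed: int = 20210203
    target_threshold: float = Field(default=5.97, gt=0, description="risk threshold (ng/mL)")

    @model_validator(mode="after")
    def _check(self):
        ids = [s.id for s in self.strategies]
        if len(set(ids)) != len(ids):
            raise ValueError("strategy ids must be unique")
        return self

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path: Union[str, Path]) -> StudyConfig:
    """Load and schema-validate a YAML study configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return StudyConfig.model_validate(raw)


def validate_config_file(path: Union[str, Path]) -> list[str]:
    """Return a list of violated invariants (empty when the file is valid)."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise
    except yaml.YAMLError as exc:
        return [f"(file): not parseable as YAML: {exc}"]
    try:
        StudyConfig.model_validate(raw)
    except ValidationError as exc:
        return [
            ".".join(str(p) for p in err["loc"]) + f": {err['msg']}" for err in exc.errors()
        ]
    return []


@dataclass
class StudyResults:
    """Tidy outputs of one study run, with summary and persistence helpers."""

    config: StudyConfig
    seed: int
    population: pd.DataFrame
    doses: pd.DataFrame
    assessment: pd.DataFrame
    risks: pd.DataFrame = field(init=False)
    relative_risks: pd.DataFrame = field(init=False)
    distributions: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.risks = risk_table(self.reported_assessment, self.config.target_threshold)
        self.relative_risks = relative_risk_increase(self.risks)
        rows = []
        adherent0 = self.assessment[
            (self.assessment["missed_per_week"] == 0) & self.assessment["adherent"]
        ]
        for strat, grp in adherent0.groupby("strategy", sort=False):
            median, cv = distribution_summary(grp["css_min_endx"])
            rows.append(
                {
                    "strategy": strat,
                    "n": len(grp),
                    "median_css_min_endx": median,
                    "cv_pct": cv,
                    "pct_above_target": 100.0
                    * float((grp["css_min_endx"] >= self.config.target_threshold).mean()),
                }
            )
        self.distributions = pd.DataFrame(rows)

    @property
    def reported_assessment(self) -> pd.DataFrame:
        """Assessment rows as reported: adherent patients at 0 missed doses,
        the non-adherent subset under the missed-dose scenarios."""
        a = self.assessment
        keep = ((a["missed_per_week"] == 0) & a["adherent"]) | (
            (a["missed_per_week"] > 0) & ~a["adherent"]
        )
        return a[keep]

    def percent_at_risk(self, strategy: str, phenotype: str = "Overall", missed: int = 0) -> float:
        sub = self.risks
        row = sub[
            (sub["strategy"] == strategy)
            & (sub["phenotype"] == phenotype)
            & (sub["missed_per_week"] == missed)
        ]
        return float(row["percent_below_target"].iloc[0])

    def summary(self) -> str:
        """Plain-text report of the headline tables."""
        strategies = [s.id for s in self.config.strategies]
        lines = [
            "In-silico tamoxifen non-adherence study",
            "=" * 55,
            f"patients: {len(self.population)}   seed: {self.seed}   "
            f"target: {self.config.target_threshold} ng/mL",
            "",
            "% of patients below target (adherent, 0 missed doses/week):",
        ]
        header = f"{'stratum':<10}" + "".join(f"{s:>18}" for s in strategies)
        lines.append(header)
        for ph in ("Overall", "gNM", "gIM", "gPM"):
            vals = []
            for s in strategies:
                try:
                    vals.append(f"{self.percent_at_risk(s, ph, 0):>18.3g}")
                except IndexError:
                    vals.append(f"{'':>18}")
            lines.append(f"{ph:<10}" + "".join(vals))
        for missed in sorted(set(self.assessment["missed_per_week"]) - {0}):
            lines.append("")
            lines.append(f"% below target, non-adherent, {missed} missed dose(s)/week:")
            lines.append(header)
            for ph in ("Overall", "gNM", "gIM", "gPM"):
                vals = []
                for s in strategies:
                    try:
                        vals.append(f"{self.percent_at_risk(s, ph, missed):>18.3g}")
                    except IndexError:
                        vals.append(f"{'':>18}")
                lines.append(f"{ph:<10}" + "".join(vals))
        lines.append("")
        lines.append("exposure distribution (adherent patients): median [CV%]:")
        for _, row in self.distributions.iterrows():
            lines.append(
                f"  {row['strategy']:<18} {row['median_css_min_endx']:6.3g} ng/mL "
                f"[{row['cv_pct']:.3g}%]  target attainment {row['pct_above_target']:.3g}%"
            )
        return "\n".join(lines)

    def save(self, outdir: Union[str, Path], plot: bool = False) -> dict[str, Path]:
        """Write all result CSVs, the shaped tables and a run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        try:
            for name, frame in (
                ("population", self.population),
                ("dose_decisions", self.doses),
                ("assessment", self.assessment),
                ("risk_summary", self.risks),
                ("relative_risk", self.relative_risks),
                ("distribution_summary", self.distributions),
            ):
                path = outdir / f"{name}.csv"
                frame.to_csv(path, index=False)
                written[name] = path
            written.update(
                write_tables(self.risks, outdir, [s.id for s in self.config.strategies])
            )
            manifest = {
                "package": "tamoxsim",
                "version": _pkg_version,
                "seed": self.seed,
                "n_patients": int(len(self.population)),
                "config_hash": self.config.config_hash(),
                "strategies": [s.id for s in self.config.strategies],
            }
            path = outdir / "run_manifest.json"
            path.write_text(json.dumps(manifest, indent=2))
            written["manifest"] = path
            if plot:
                path = outdir / "risk_by_strategy.png"
                plot_risk_bars(self.risks, path)
                written["plot"] = path
        except Exception as exc:
            for path in written.values():
                path.unlink(missing_ok=True)
            raise StudyError(f"stage 'save-outputs' failed: {exc}") from exc
        return written


class NonAdherenceStudy:
    """The full simulation study as a fit-like model object."""

    def __init__(self, config: Optional[StudyConfig] = None):
        self.config = config or StudyConfig()

    # -- pipeline stages -------------------------------------------------

    def _stage(self, name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StudyError:
            raise
        except Exception as exc:
            raise StudyError(f"stage '{name}' failed: {exc}") from exc

    def _individual_clearances(self, patients):
        model = self.config.model
        cl23 = np.empty(len(patients))
        cl20 = np.empty(len(patients))
        for i, p in enumerate(patients):
            t23, t20 = model.apply_covariates(p.covariates)
            cl23[i] = t23 * np.exp(p.eta_cl23)
            cl20[i] = t20 * np.exp(p.eta_cl20)
        return cl23, cl20

    def _per_mg_minima(self, cl23_i, cl20_i):
        m = self.config.model
        return {
            missed: cycle_min_endx_per_mg(
                m.ka, m.tlag, m.v_tam, cl20_i, cl23_i, m.v_endx, m.cl30, pattern
            )
            for missed, pattern in _PATTERNS.items()
        }

    def _dose_decisions(self, patients, tdm_rng):
        """Per-patient selected dose for every strategy (tidy frame)."""
        model = self.config.model
        mipd = [s for s in self.config.strategies if s.kind == "mipd"]
        eta_hat = np.zeros((len(patients), 2))
        trough_per_mg_hat = np.zeros(len(patients))
        if mipd:
            ref = mipd[0]  # all MIPD variants share TDM design and MAP fit
            for i, p in enumerate(patients):
                initial = genotype_guided_dose(p.phenotype)
                obs = simulate_tdm(
                    model, p.covariates, p.eta_cl23, p.eta_cl20, initial,
                    tdm_days=ref.tdm_days, rng=tdm_rng,
                )
                res = MapForecast(model, p.covariates, obs, initial).fit()
                eta_hat[i] = res.eta
                trough_per_mg_hat[i] = res.predict_ss_trough(1.0)
        rows = []
        for strat in self.config.strategies:
            for i, p in enumerate(patients):
                initial = genotype_guided_dose(p.phenotype)
                if strat.kind == "conventional":
                    dose, capped, init = conventional_dose(), False, conventional_dose()
                    e23 = e20 = 0.0
                elif strat.kind == "cyp2d6_guided":
                    dose, capped, init = initial, False, initial
                    e23 = e20 = 0.0
                else:
                    dose, capped = select_mipd_dose(
                        None, strat, trough_per_mg=trough_per_mg_hat[i]
                    )
                    init = initial
                    e23, e20 = eta_hat[i]
                rows.append(
                    {
                        "id": p.id,
                        "strategy": strat.id,
                        "initial_dose": init,
                        "eta_hat_cl23": e23,
                        "eta_hat_cl20": e20,
                        "selected_dose": dose,
                        "capped_flag": capped,
                    }
                )
        return pd.DataFrame(rows)

    def _assessment(self, patients, doses, per_mg, nonadherent):
        thr = self.config.target_threshold
        phenos = np.array([p.phenotype.value for p in patients])
        ids = np.array([p.id for p in patients])
        frames = []
        for strat in self.config.strategies:
            dose = doses[doses["strategy"] == strat.id].set_index("id").loc[ids, "selected_dose"].to_numpy()
            for missed in (0, *self.config.adherence.missed_scenarios):
                if missed == 0:
                    mask = np.ones(len(patients), dtype=bool)
                else:
                    mask = nonadherent  # same counterfactual subset in both arms
                css = dose[mask] * per_mg[missed][mask]
                frames.append(
                    pd.DataFrame(
                        {
                            "id": ids[mask],
                            "strategy": strat.id,
                            "missed_per_week": missed,
                            "phenotype": phenos[mask],
                            "adherent": ~nonadherent[mask],
                            "css_min_endx": css,
                            "below_597": css < 5.97,
                            "below_9": css < 9.0,
                            "below_target": css < thr,
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)

    def run(self, seed: Optional[int] = None) -> StudyResults:
        """Execute the complete study; deterministic for a fixed seed."""
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        ss = np.random.SeedSequence(seed)
        pop_ss, tdm_ss, adh_ss = ss.spawn(3)
        patients = self._stage(
            "generate-population", generate_population, cfg.population, pop_ss
        )
        pop_frame = population_to_frame(patients)
        cl23_i, cl20_i = self._stage("individual-parameters", self._individual_clearances, patients)
        per_mg = self._stage("steady-state-exposure", self._per_mg_minima, cl23_i, cl20_i)
        doses = self._stage(
            "dose-decisions", self._dose_decisions, patients, np.random.default_rng(tdm_ss)
        )
        nonadherent = self._stage(
            "adherence-assignment",
            assign_adherence,
            len(patients),
            cfg.adherence.nonadherent_fraction,
            np.random.default_rng(adh_ss),
        )
        assessment = self._stage(
            "assessment", self._assessment, patients, doses, per_mg, nonadherent
        )
        return StudyResults(
            config=cfg, seed=seed, population=pop_frame, doses=doses, assessment=assessment
        )


def run_study(
    config: Optional[StudyConfig] = None,
    seed: Optional[int] = None,
    outdir: Optional[Union[str, Path]] = None,
    plot: bool = False,
) -> StudyResults:
    """Convenience wrapper: run the study and optionally persist outputs."""
    results = NonAdherenceStudy(config).run(seed=seed)
    if outdir is not None:
        results.save(outdir, plot=plot)
    return results
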