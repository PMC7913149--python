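"""Aggregation of per-patient assessments into the study outcome tables.

Works on the tidy assessment table (one row per patient x strategy x
scenario) and produces: percent of patients at risk of target non-attainment
(below the endoxifen trough threshold), relative risk increases versus the
full-adherence baseline, and exposure-distribution summaries (median, CV%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "RiskSummary",
    "RelativeRiskIncrease",
    "percent_at_risk",
    "risk_table",
    "relative_risk_increase",
    "distribution_summary",
    "format_sig",
    "write_tables",
    "plot_risk_bars",
]

PHENOTYPE_ORDER = ("Overall", "gNM", "gIM", "gPM")


@dataclass(frozen=True)
class RiskSummary:
    """Target non-attainment risk in one stratum."""

    strategy: str
    phenotype: str  # gNM/gIM/gPM or "Overall"
    missed_per_week: int
    n: int
    percent_below_target: float  # % of the stratum


@dataclass(frozen=True)
class RelativeRiskIncrease:
    """Risk of a missed-dose scenario relative to the full-adherence baseline."""

    strategy: str
    phenotype: str
    missed_per_week: int
    ratio: Optional[float]  # None when the baseline risk is 0 (undefined)


def percent_at_risk(
    results: pd.DataFrame,
    threshold: float = 5.97,
    strategy: Optional[str] = None,
    phenotype: Optional[str] = None,
    missed_per_week: Optional[int] = None,
) -> float:
    """Percent of patients in a stratum below the trough threshold.

    Strata are strategy x scenario x phenotype; ``phenotype=None`` (or
    ``"Overall"``) pools phenotypes.  An empty stratum yields NaN (flagged
    missing), never 0.
    """
    sub = results
    if strategy is not None:
        sub = sub[sub["strategy"] == strategy]
    if phenotype is not None and phenotype != "Overall":
        sub = sub[sub["phenotype"] == phenotype]
    if missed_per_week is not None:
        sub = sub[sub["missed_per_week"] == missed_per_week]
    if len(sub) == 0:
        return float("nan")
    return 100.0 * float((sub["css_min_endx"] < threshold).mean())


def risk_table(results: pd.DataFrame, threshold: float = 5.97) -> pd.DataFrame:
    """All stratum risks as a tidy frame (phenotype includes Overall)."""
    rows = []
    for (strategy, missed), grp in results.groupby(["strategy", "missed_per_week"], sort=False):
        strata = [("Overall", grp)] + [
            (ph, grp[grp["phenotype"] == ph]) for ph in ("gNM", "gIM", "gPM")
        ]
        for ph, sub in strata:
            pct = 100.0 * float((sub["css_min_endx"] < threshold).mean()) if len(sub) else float("nan")
            rows.append(
                {
                    "strategy": strategy,
                    "phenotype": ph,
                    "missed_per_week": missed,
                    "n": len(sub),
                    "percent_below_target": pct,
                }
            )
    return pd.DataFrame(rows)


def relative_risk_increase(
    risks: pd.DataFrame,
) -> pd.DataFrame:
    """Scenario risk divided by the full-adherence baseline risk, per stratum.

    Input is the output of :func:`risk_table` and must contain the
    ``missed_per_week == 0`` baseline.  Where the baseline risk is 0 the
    ratio is undefined and reported as NaN with ``undefined=True``.
    """
    base = risks[risks["missed_per_week"] == 0].set_index(["strategy", "phenotype"])[
        "percent_below_target"
    ]
    rows = []
    for _, row in risks[risks["missed_per_week"] > 0].iterrows():
        key = (row["strategy"], row["phenotype"])
        if key not in base.index:
            raise ValueError(f"missing full-adherence baseline for stratum {key}")
        b = base.loc[key]
        undefined = not (b > 0)
        rows.append(
            {
                "strategy": row["strategy"],
                "phenotype": row["phenotype"],
                "missed_per_week": row["missed_per_week"],
                "ratio": float("nan") if undefined else row["percent_below_target"] / b,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)


def distribution_summary(values: Sequence[float]) -> tuple[float, float]:
    """Median and arithmetic CV% (100 * sample SD / mean) of concentrations.

    CV is flagged missing (NaN) for fewer than two values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    median = float(np.median(arr))
    if arr.size < 2:
        return median, float("nan")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    cv = float("nan") if mean == 0 else 100.0 * sd / mean
    return median, cv


def geometric_cv(values: Sequence[float]) -> float:
    """Geometric CV% = 100 * sqrt(exp(var(ln x)) - 1); reporting option."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or np.any(arr <= 0):
        return float("nan")
    return 100.0 * math.sqrt(math.exp(np.log(arr).var(ddof=1)) - 1.0)


def format_sig(x: float, sig: int = 3) -> str:
    """Format to ``sig`` significant figures, as in the study tables."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if x == 0:
        return "0.00"
    return f"{x:.{sig}g}"


def write_tables(
    risks: pd.DataFrame,
    outdir: Union[str, Path],
    strategy_order: Optional[Sequence[str]] = None,
) -> dict[str, Path]:
    """Write the two study-shaped risk tables as CSVs.

    ``table1_like.csv``: adherent patients (0 missed), rows Overall/gNM/gIM/
    gPM, one column per strategy.  ``table2_like.csv``: non-adherent
    patients, one column per strategy x missed-dose scenario.  Strata absent
    from the input appear as empty cells, not dropped rows.  Values are
    rendered to 3 significant figures.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if strategy_order is None:
        strategy_order = list(dict.fromkeys(risks["strategy"]))
    indexed = risks.set_index(["strategy", "phenotype", "missed_per_week"])[
        "percent_below_target"
    ]

    def cell(strategy, phenotype, missed):
        try:
            return format_sig(indexed.loc[(strategy, phenotype, missed)])
        except KeyError:
            return ""

    table1 = pd.DataFrame(
        {s: [cell(s, ph, 0) for ph in PHENOTYPE_ORDER] for s in strategy_order},
        index=pd.Index(PHENOTYPE_ORDER, name="patient_subpopulation"),
    )
    cols = {}
    for s in strategy_order:
        for missed in (1, 2):
            cols[f"{s}_missed{missed}"] = [cell(s, ph, missed) for ph in PHENOTYPE_ORDER]
    table2 = pd.DataFrame(cols, index=pd.Index(PHENOTYPE_ORDER, name="patient_subpopulation"))
    paths = {
        "table1_like": outdir / "table1_like.csv",
        "table2_like": outdir / "table2_like.csv",
    }
    table1.to_csv(paths["table1_like"])
    table2.to_csv(paths["table2_like"])
    return paths


def plot_risk_bars(risks: pd.DataFrame, path: Union[str, Path]) -> None:
    """Cosmetic bar chart of risk by strategy, phenotype and scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strategies = list(dict.fromkeys(risks["strategy"]))
    scenarios = sorted(risks["missed_per_week"].unique())
    fig, axes = plt.subplots(1, len(scenarios), figsize=(4 * len(scenarios), 3.5), sharey=True)
    if len(scenarios) == 1:
        axes = [axes]
    colors = {"Overall": "tab:blue", "gNM": "tab:green", "gIM": "gold", "gPM": "tab:red"}
    for ax, missed in zip(axes, scenarios):
        sub = risks[risks["missed_per_week"] == missed]
        width = 0.2
        for k, ph in enumerate(PHENOTYPE_ORDER):
            vals = [
                sub[(sub["strategy"] == s) & (sub["phenotype"] == ph)]["percent_below_target"].mean()
                for s in strategies
            ]
            ax.bar(np.arange(len(strategies)) + k * width, vals, width, label=ph, color=colors[ph])
        ax.set_xticks(np.arange(len(strategies)) + 1.5 * width)
        ax.set_xticklabels(strategies, rotation=45, ha="right", fontsize=7)
        ax.set_title(f"{missed} missed dose(s)/week")
    axes[0].set_ylabel("% below target")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
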