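"""Concentration-time computation for the tamoxifen-endoxifen cascade.

The model is linear, so every profile is a superposition of per-dose
closed-form solutions.  For a single oral dose ``D`` (mg) administered at
time ``td``, with ``t' = t - td - tlag`` the time since absorption starts,

* tamoxifen:  ``C_TAM(t') = F_u * D * ka / (v_tam * (k10 - ka)) *
  (exp(-ka t') - exp(-k10 t'))``
* endoxifen:  ``C_ENDX(t') = F_u * D * ka * k23 / v_endx *
  sum_l exp(-l t') / prod_{m != l} (m - l)`` over ``l in {ka, k10, k30}``

with ``k10 = (cl20_i + cl23_i)/v_tam``, ``k23 = cl23_i/v_tam``,
``k30 = cl30/v_endx`` and the unit factor ``F_u = 1000`` converting a mg dose
in an L-scale volume to ng/mL (1 mg / 1 L = 1000 ug/L = 1000 ng/mL).

Near-degenerate rate constants (two eigenvalues closer than 1e-9 relative)
are separated by a 1e-9 relative perturbation, which keeps the closed form
finite with error far below the comparison tolerances used in this package.

Periodic steady state under a weekly-repeating intake pattern is obtained in
closed form by summing each exponential over all past cycles (a geometric
series with ratio ``exp(-168 l)``), rather than by long simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import IndividualParameters

__all__ = [
    "MG_TO_NG_PER_ML",
    "CYCLE_HOURS",
    "DoseEventList",
    "ConcentrationProfile",
    "simulate_profile",
    "endx_concentrations",
    "cycle_min_endx_per_mg",
    "steady_state_min_endx",
]

MG_TO_NG_PER_ML = 1000.0  # 1 mg dose in L-scale volumes -> ug/L = ng/mL
CYCLE_HOURS = 168.0  # one weekly dosing cycle
_SEP_REL = 1e-8  # relative separation applied to near-equal eigenvalues
# (balances the O(eps) perturbation bias against the O(ulp/eps) cancellation
# error of the tri-exponential coefficients; both stay below ~1e-7)


class DoseEventList:
    """Ordered oral dose events: times in hours, amounts in mg."""

    def __init__(self, times: Sequence[float], amounts: Sequence[float]):
        times = np.asarray(times, dtype=float)
        amounts = np.asarray(amounts, dtype=float)
        if times.shape != amounts.shape or times.ndim != 1:
            raise ValueError("times and amounts must be 1-D arrays of equal length")
        if times.size and (np.any(times < 0) or np.any(np.diff(times) <= 0)):
            raise ValueError("dose times must be non-negative and strictly increasing")
        if np.any(amounts < 0):
            raise ValueError("dose amounts must be non-negative")
        self.times = times
        self.amounts = amounts

    @classmethod
    def once_daily(cls, dose_mg: float, n_days: int, start_h: float = 0.0) -> "DoseEventList":
        times = start_h + 24.0 * np.arange(n_days)
        return cls(times, np.full(n_days, float(dose_mg)))

    def __len__(self) -> int:
        return int(self.times.size)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DoseEventList)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.amounts, other.amounts)
        )

    def __repr__(self) -> str:
        total = float(self.amounts.sum()) if len(self) else 0.0
        return f"DoseEventList(n={len(self)}, total={total:g} mg)"


@dataclass
class ConcentrationProfile:
    """Tamoxifen/endoxifen concentration-time profile (ng/mL)."""

    times: np.ndarray
    tamoxifen: np.ndarray
    endoxifen: np.ndarray


def _separate_rates(ka, k10, k30):
    """Perturb near-equal eigenvalues so the tri-exponential form stays finite."""
    scale = np.maximum(np.abs(ka), np.abs(k10))
    k10 = np.where(np.abs(k10 - ka) < _SEP_REL * scale, ka * (1.0 + _SEP_REL), k10)
    scale = np.maximum(np.abs(ka), np.abs(k30))
    k30 = np.where(np.abs(k30 - ka) < _SEP_REL * scale, ka * (1.0 - _SEP_REL), k30)
    scale = np.maximum(np.abs(k10), np.abs(k30))
    k30 = np.where(np.abs(k30 - k10) < _SEP_REL * scale, k10 * (1.0 + 2.0 * _SEP_REL), k30)
    return ka, k10, k30


def _endx_terms(ka, tlag, v_tam, cl20_i, cl23_i, v_endx, cl30):
    """Eigenvalues and coefficients of the per-mg endoxifen solution.

    Vectorized over patients: ``cl20_i``/``cl23_i`` may be arrays of shape
    (n,).  Returns ``(lam, coef)`` each of shape (n, 3) such that the
    endoxifen concentration after a 1 mg dose is ``sum_j coef_j exp(-lam_j t')``.
    """
    cl20_i = np.atleast_1d(np.asarray(cl20_i, dtype=float))
    cl23_i = np.atleast_1d(np.asarray(cl23_i, dtype=float))
    k10 = (cl20_i + cl23_i) / v_tam
    k30 = np.full_like(k10, cl30 / v_endx)
    ka_arr = np.full_like(k10, ka)
    ka_arr, k10, k30 = _separate_rates(ka_arr, k10, k30)
    k23 = cl23_i / v_tam
    pref = MG_TO_NG_PER_ML * ka_arr * k23 / v_endx
    c_ka = pref / ((k10 - ka_arr) * (k30 - ka_arr))
    c_k10 = pref / ((ka_arr - k10) * (k30 - k10))
    c_k30 = pref / ((ka_arr - k30) * (k10 - k30))
    lam = np.stack([ka_arr, k10, k30], axis=-1)
    coef = np.stack([c_ka, c_k10, c_k30], axis=-1)
    return lam, coef


def _tam_terms(ka, v_tam, cl20_i, cl23_i):
    """Eigenvalues and coefficients of the per-mg tamoxifen solution."""
    cl20_i = np.atleast_1d(np.asarray(cl20_i, dtype=float))
    cl23_i = np.atleast_1d(np.asarray(cl23_i, dtype=float))
    k10 = (cl20_i + cl23_i) / v_tam
    ka_arr = np.full_like(k10, ka)
    ka_arr, k10, _ = _separate_rates(ka_arr, k10, np.full_like(k10, np.inf))
    pref = MG_TO_NG_PER_ML * ka_arr / (v_tam * (k10 - ka_arr))
    lam = np.stack([ka_arr, k10], axis=-1)
    coef = np.stack([pref, -pref], axis=-1)
    return lam, coef


def _superpose(lam, coef, tlag, dose_times, amounts, times):
    """Sum per-dose exponential solutions at the requested times.

    ``lam``/``coef``: (n, q) term arrays; returns (n, m) concentrations.
    Contributions are zero before ``dose_time + tlag``.
    """
    times = np.asarray(times, dtype=float)
    elapsed = times[None, :] - np.asarray(dose_times, dtype=float)[:, None] - tlag
    active = elapsed > 0.0
    elapsed = np.where(active, elapsed, 0.0)
    amounts = np.asarray(amounts, dtype=float)
    n, q = lam.shape
    d, m = elapsed.shape
    out = np.zeros((n, m))
    if n * d * m <= 4_000_000:
        weighted = amounts[:, None] * active  # (d, m)
        for j in range(q):
            terms = np.exp(-lam[:, j, None, None] * elapsed[None, :, :])  # (n, d, m)
            out += coef[:, j, None] * np.einsum("ndm,dm->nm", terms, weighted)
    else:
        for j in range(q):
            for k in range(d):
                if amounts[k] == 0.0:
                    continue
                term = np.exp(-np.outer(lam[:, j], elapsed[k]))
                term[:, ~active[k]] = 0.0
                out += coef[:, j, None] * amounts[k] * term
    return out


def simulate_profile(
    ind: IndividualParameters, doses: DoseEventList, times: Sequence[float]
) -> ConcentrationProfile:
    """Concentration-time profile for one patient under a dose-event list."""
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(times < 0) or np.any(np.diff(times) < 0)):
        raise ValueError("times must be sorted and non-negative")
    if len(doses) == 0:
        zero = np.zeros_like(times)
        return ConcentrationProfile(times, zero, zero.copy())
    lam_e, coef_e = _endx_terms(
        ind.ka, ind.tlag, ind.v_tam, ind.cl20_i, ind.cl23_i, ind.v_endx, ind.cl30
    )
    lam_t, coef_t = _tam_terms(ind.ka, ind.v_tam, ind.cl20_i, ind.cl23_i)
    endx = _superpose(lam_e, coef_e, ind.tlag, doses.times, doses.amounts, times)[0]
    tam = _superpose(lam_t, coef_t, ind.tlag, doses.times, doses.amounts, times)[0]
    # clip tiny negative round-off near the lag boundary
    return ConcentrationProfile(times, np.maximum(tam, 0.0), np.maximum(endx, 0.0))


def endx_concentrations(
    ka: float,
    tlag: float,
    v_tam: float,
    cl20_i,
    cl23_i,
    v_endx: float,
    cl30: float,
    dose_times: Sequence[float],
    amounts: Sequence[float],
    times: Sequence[float],
) -> np.ndarray:
    """Endoxifen concentrations (ng/mL), vectorized over patients.

    ``cl20_i``/``cl23_i`` may be scalars or (n,) arrays; returns (n, m) for m
    requested times.  Used for virtual TDM sampling and MAP forecasting.
    """
    lam, coef = _endx_terms(ka, tlag, v_tam, cl20_i, cl23_i, v_endx, cl30)
    return np.maximum(_superpose(lam, coef, tlag, dose_times, amounts, times), 0.0)


def _cycle_grid(pattern_days: np.ndarray, tlag: float, grid_step: float) -> np.ndarray:
    """Evaluation grid over one weekly cycle, including pre-dose instants."""
    tau = np.arange(0.0, CYCLE_HOURS, grid_step)
    pre_dose = (24.0 * pattern_days + tlag - 1e-6) % CYCLE_HOURS
    return np.unique(np.concatenate([tau, pre_dose]))


def cycle_min_endx_per_mg(
    ka: float,
    tlag: float,
    v_tam: float,
    cl20_i,
    cl23_i,
    v_endx: float,
    cl30: float,
    pattern: Sequence[int],
    grid_step: float = 0.25,
) -> np.ndarray:
    """Minimum endoxifen concentration over the steady-state weekly cycle, per mg.

    ``pattern`` is a length-7 binary intake vector (1 = dose taken that day).
    The periodic steady state of the infinitely repeated pattern is evaluated
    in closed form: each exponential term of each intra-cycle dose is summed
    over all past cycles via the geometric series ``1/(1 - exp(-168 lam))``.
    Vectorized over patients; returns an (n,) array of per-mg cycle minima.
    """
    pattern = np.asarray(pattern)
    if pattern.shape != (7,) or not np.all(np.isin(pattern, (0, 1))):
        raise ValueError("pattern must be a length-7 binary intake vector")
    lam, coef = _endx_terms(ka, tlag, v_tam, cl20_i, cl23_i, v_endx, cl30)
    n = lam.shape[0]
    days = np.flatnonzero(pattern)
    if days.size == 0:
        return np.zeros(n)
    tau = _cycle_grid(days, tlag, grid_step)
    geo = coef / -np.expm1(-CYCLE_HOURS * lam)  # (n, 3)
    conc = np.zeros((n, tau.size))
    for d in days:
        elapsed = (tau - 24.0 * d - tlag) % CYCLE_HOURS
        for j in range(3):
            conc += geo[:, j, None] * np.exp(-np.outer(lam[:, j], elapsed))
    return conc.min(axis=1)


def steady_state_min_endx(
    ind: IndividualParameters,
    daily_dose_mg: float,
    pattern: Sequence[int] = (1, 1, 1, 1, 1, 1, 1),
    grid_step: float = 0.25,
) -> float:
    """C_SS,min of endoxifen (ng/mL) under a weekly-repeating intake pattern.

    ``daily_dose_mg`` is the amount of each taken dose; ``pattern`` marks
    which days of the 7-day cycle are taken.  Returns 0 for a zero dose or an
    all-zero pattern.  PK linearity makes the result proportional to dose.
    """
    if daily_dose_mg < 0:
        raise ValueError("dose must be non-negative")
    if daily_dose_mg == 0:
        return 0.0
    per_mg = cycle_min_endx_per_mg(
        ind.ka, ind.tlag, ind.v_tam, ind.cl20_i, ind.cl23_i, ind.v_endx, ind.cl30,
        pattern, grid_step=grid_step,
    )
    return float(daily_dose_mg * per_mg[0])
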