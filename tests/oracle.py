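"""Independent numerical oracle: stiff-safe ODE integration of the cascade.

Used only to cross-check the closed-form superposition; kept free of any
code from the production solution path.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def ode_concentrations(ind, dose_times, amounts, times, rtol=1e-11, atol=1e-14):
    """Tamoxifen/endoxifen concentrations (ng/mL) by direct ODE integration.

    Integrates depot -> tamoxifen -> endoxifen amounts piecewise between
    absorption-start events (dose time + lag), adding each dose to the depot
    as a bolus.  Returns ``(c_tam, c_endx)`` arrays aligned with ``times``.
    """
    k10 = (ind.cl20_i + ind.cl23_i) / ind.v_tam
    k23 = ind.cl23_i / ind.v_tam
    k30 = ind.cl30 / ind.v_endx

    def rhs(t, y):
        return [-ind.ka * y[0], ind.ka * y[0] - k10 * y[1], k23 * y[1] - k30 * y[2]]

    starts = [t + ind.tlag for t in dose_times]
    bolus = dict(zip(starts, amounts))
    checkpoints = sorted(set(starts) | set(float(t) for t in times))
    y = np.zeros(3)
    cur = 0.0
    out = {}
    for t in checkpoints:
        if t > cur:
            sol = solve_ivp(rhs, (cur, t), y, method="LSODA", rtol=rtol, atol=atol)
            y = sol.y[:, -1]
            cur = t
        if t in bolus:
            y = y + np.array([bolus[t], 0.0, 0.0])
        out[t] = y.copy()
    c_tam = np.array([1000.0 * out[float(t)][1] / ind.v_tam for t in times])
    c_endx = np.array([1000.0 * out[float(t)][2] / ind.v_endx for t in times])
    return c_tam, c_endx
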