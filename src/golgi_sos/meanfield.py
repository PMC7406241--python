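"""Mean-field companions to the stochastic simulator.

Two asymptotic regimes admit closed-form treatment:

* the **well-sorted limit** (kb >> km), where compartments are pure and the
  total amounts of each identity obey linear balance equations; this yields
  the steady-state species amounts, the influx calibration used to pin the
  mean system size, and the typical compartment size N/(1+kb);
* the **maturation-dominated regime** (kb << 1), where each compartment
  grows from a cis vesicle by fusion with a constant vesicle pool while its
  patches convert, giving the composition trajectory
  phi(t) = (e^{-km t}, km t e^{-km t}, 1 - (1 + km t) e^{-km t}).

These functions are used to calibrate the injection rate of the simulator
and to validate it in the corresponding regimes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "steady_state_amounts",
    "calibrate_influx",
    "wellsorted_compartment_size",
    "denovo_growth",
    "maturation_composition",
    "medial_maximum",
]


def steady_state_amounts(
    j: float, km: float, alpha_er: float, alpha_tgn: float
) -> tuple[float, float, float]:
    """Steady-state total patch amounts per identity in the well-sorted limit.

    Balance of influx j, conversion km and homotypic boundary exit gives

        N_cis = N_medial = j / (alpha_ER + km),
        N_trans = (km / alpha_TGN) * j / (alpha_ER + km).
    """
    if alpha_er + km <= 0:
        raise ValueError("alpha_er + km must be positive")
    if alpha_tgn <= 0:
        raise ValueError("alpha_tgn must be positive")
    n_cis = j / (alpha_er + km)
    n_trans = km / alpha_tgn * n_cis
    return (n_cis, n_cis, n_trans)


def calibrate_influx(
    n_target: float, km: float, alpha_er: float, alpha_tgn: float
) -> float:
    """Injection rate j that makes the well-sorted steady state sum to N.

        j = N (alpha_ER + km) alpha_TGN / (2 alpha_TGN + km)

    Exact inverse of :func:`steady_state_amounts` summed over identities.
    """
    if 2 * alpha_tgn + km <= 0:
        raise ValueError("2*alpha_tgn + km must be positive")
    return n_target * (alpha_er + km) * alpha_tgn / (2 * alpha_tgn + km)


def wellsorted_compartment_size(n_species: float, kb: float) -> float:
    """Typical compartment size in the well-sorted limit.

    A single compartment of size n per species exchanges with a vesicle pool
    (growth by vesicle fusion, loss by budding at rate kb*n), giving the
    steady state n = N_species / (1 + kb).
    """
    if kb < 0 or n_species < 0:
        raise ValueError("n_species and kb must be non-negative")
    return n_species / (1.0 + kb)


def denovo_growth(
    j: float,
    km: float,
    alpha_er: float,
    alpha_tgn: float,
    t_grid: np.ndarray,
) -> pd.DataFrame:
    """Growth of an initially empty system, by the well-sorted balance ODEs.

        dN_cis/dt    = j - N_cis (alpha_ER + km)
        dN_medial/dt = km (N_cis - N_medial)
        dN_trans/dt  = km N_medial - alpha_TGN N_trans

    Integrated from (0, 0, 0); converges to the steady-state amounts.
    Returns a DataFrame with columns time, n_cis, n_medial, n_trans.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a non-empty increasing 1-d array")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at t >= 0")

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        nc, nm, nt = y
        return [
            j - nc * (alpha_er + km),
            km * (nc - nm),
            km * nm - alpha_tgn * nt,
        ]

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1]) if t_grid[-1] > 0 else 1e-12),
        [0.0, 0.0, 0.0],
        t_eval=t_grid,
        rtol=1e-8,
        atol=1e-10,
        method="RK45",
    )
    if not sol.success:  # pragma: no cover - linear non-stiff system
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return pd.DataFrame(
        {
            "time": t_grid,
            "n_cis": sol.y[0],
            "n_medial": sol.y[1],
            "n_trans": sol.y[2],
        }
    )


def maturation_composition(t, km: float):
    """Composition of a maturing compartment born as a cis vesicle at t = 0.

    In the maturation-dominated regime (negligible budding, growth from a
    symmetric vesicle pool) the fractions depend only on km*t:

        phi_cis    = e^{-km t}
        phi_medial = km t e^{-km t}
        phi_trans  = 1 - (1 + km t) e^{-km t}

    ``t`` may be a scalar or array; returns an array of shape (..., 3) whose
    components sum to 1 exactly.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or km < 0:
        raise ValueError("t and km must be non-negative")
    x = km * t
    e = np.exp(-x)
    phi = np.stack([e, x * e, 1.0 - (1.0 + x) * e], axis=-1)
    return phi


def medial_maximum(km: float) -> tuple[float, float]:
    """Time and height of the medial-fraction peak of a maturing compartment.

    phi_medial(t) = km t e^{-km t} is maximal at km*t = 1 with value 1/e,
    independent of km.
    """
    if km <= 0:
        raise ValueError("the medial fraction has no finite-time maximum for km <= 0")
    return (1.0 / km, 1.0 / np.e)
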