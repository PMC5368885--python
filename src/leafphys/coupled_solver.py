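"""Coupled leaf model: FvCB biochemistry + stomatal and mesophyll diffusion.

Given ambient CO2 (Ca), irradiance, leaf temperature and VPD, the solver finds
the operating point that simultaneously satisfies

    (i)   An = FvCB(Cc)                      (biochemical demand)
    (ii)  Cc = Ci − An / gm                  (mesophyll diffusion)
    (iii) gs = g0 + (An + Rd)/(Ci − Ci*)·fvpd (stomatal response)
    (iv)  Ci = Ca − An / gs                  (stomatal diffusion)

Each limitation branch (Rubisco / electron transport) is solved separately by
a bracketed Brent root-find on Ci of the mismatch between the
diffusion-implied and biochemistry-implied Ci; net assimilation is the
minimum over branches.  Within a branch, the Ci-based quadratic (NRH-A form)
gives the assimilation rate consistent with gm in closed form, so the scalar
root-find on Ci is exact up to its tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model_core import (
    BiochemParams,
    DEFAULT_KINETICS,
    Environment,
    KineticConstants,
    RatesAtT,
    j_from_light,
    nrh_a_ci,
    rates_at_t,
)
from .conductance import StomatalParams, ci_star, fvpd, gs_model

__all__ = ["LeafSolution", "solve_leaf", "residuals", "solve_batch"]

#: Bracket guard above Ci*, μbar.
CI_BRACKET_EPS = 1.0
#: Convergence tolerance on Ci, μbar.
CI_XTOL = 1e-10


@dataclass
class LeafSolution:
    """Converged operating point of the coupled leaf model."""

    an: float
    ci: float
    cc: float
    gs: float
    limitation: str
    residuals: tuple[float, float, float]
    ac: float = field(default=np.nan)
    aj: float = field(default=np.nan)
    j: float = field(default=np.nan)


def _branch_x(branch: str, rates: RatesAtT, j: float, o: float) -> tuple[float, float]:
    if branch == "Rubisco":
        return rates.vcmax, rates.kmc * (1.0 + o / rates.kmo)
    return j / 4.0, 2.0 * rates.gamma_star


def _branch_an(ci: float, branch: str, rates: RatesAtT, j: float, o: float) -> float:
    x1, x2 = _branch_x(branch, rates, j, o)
    return nrh_a_ci(ci, x1, x2, rates.rd, rates.gm, rates.gamma_star)


def _solve_branch(branch: str, env: Environment, rates: RatesAtT, j: float,
                  stomatal: StomatalParams, fv: float) -> tuple[float, float, float]:
    """Return (an, ci, gs) for one limitation branch."""
    cistar = ci_star(rates.gamma_star, rates.rd, rates.gm)
    g0 = max(stomatal.g0, 1e-9)

    def implied_ci(ci: float) -> float:
        an = _branch_an(ci, branch, rates, j, o=env.o)
        gs = g0 + (an + rates.rd) / (ci - cistar) * fv
        return env.ca - an / gs

    # An >= -Rd on the whole bracket, so implied_ci <= Ca + Rd/g0 < hi and the
    # mismatch is strictly negative at hi; a sign change is then guaranteed
    # unless the demand is so strong that even at the guard the implied Ci
    # falls below it, in which case the solution is pinned at the guard.
    lo = cistar + CI_BRACKET_EPS
    hi = env.ca + rates.rd / g0 + CI_BRACKET_EPS

    def mismatch(ci: float) -> float:
        return implied_ci(ci) - ci

    if mismatch(lo) <= 0.0:
        ci = lo
    else:
        try:
            ci = brentq(mismatch, lo, hi, xtol=CI_XTOL, maxiter=200)
        except ValueError as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"coupled solve failed to bracket on Ci in ({lo:.3f}, {hi:.3f}); "
                f"mismatch(lo)={mismatch(lo):.3e}, mismatch(hi)={mismatch(hi):.3e}"
            ) from exc
    an = _branch_an(ci, branch, rates, j, o=env.o)
    gs = g0 + (an + rates.rd) / (ci - cistar) * fv
    return an, ci, gs


def solve_leaf(env: Environment, biochem: BiochemParams, stomatal: StomatalParams,
               constants: KineticConstants = DEFAULT_KINETICS) -> LeafSolution:
    """Solve the coupled FvCB + stomatal + mesophyll system with Ca as input."""
    rates = rates_at_t(biochem, env.t, constants=constants, o=env.o)
    j = float(j_from_light(env.iinc, biochem.kappa2ll, rates.jmax, biochem.theta))
    fv = fvpd(env.vpd, stomatal.a1, stomatal.b1, clamp=False)

    solutions = {}
    for branch in ("Rubisco", "electron-transport"):
        solutions[branch] = _solve_branch(branch, env, rates, j, stomatal, fv)

    an_c = solutions["Rubisco"][0]
    an_j = solutions["electron-transport"][0]
    limitation = "Rubisco" if an_c < an_j else "electron-transport"
    an, ci, gs = solutions[limitation]
    cc = ci - an / rates.gm
    sol = LeafSolution(an=an, ci=ci, cc=cc, gs=gs, limitation=limitation,
                       residuals=(np.nan,) * 3, ac=an_c, aj=an_j, j=j)
    sol.residuals = residuals(sol, env, biochem, stomatal, constants)
    return sol


def residuals(solution: LeafSolution, env: Environment, biochem: BiochemParams,
              stomatal: StomatalParams,
              constants: KineticConstants = DEFAULT_KINETICS) -> tuple[float, float, float]:
    """Balance-equation residuals at a reported solution (diagnostics).

    Returns (An − FvCB(Cc), gs − gs_model(...), Ci − (Ca − An/gs)); all three
    are below 1e−8 at a converged solution.
    """
    rates = rates_at_t(biochem, env.t, constants=constants, o=env.o)
    j = float(j_from_light(env.iinc, biochem.kappa2ll, rates.jmax, biochem.theta))
    x1, x2 = _branch_x(solution.limitation, rates, j, env.o)
    an_biochem = (solution.cc - rates.gamma_star) * x1 / (solution.cc + x2) - rates.rd
    cistar = ci_star(rates.gamma_star, rates.rd, rates.gm)
    gs_pred = gs_model(solution.an, rates.rd, solution.ci, cistar, stomatal,
                       env.vpd, clamp=False)
    r1 = solution.an - an_biochem
    r2 = solution.gs - gs_pred
    r3 = solution.ci - (env.ca - solution.an / solution.gs)
    return (float(r1), float(r2), float(r3))


def solve_batch(env_table: pd.DataFrame, biochem: BiochemParams,
                stomatal: StomatalParams,
                constants: KineticConstants = DEFAULT_KINETICS) -> pd.DataFrame:
    """Solve the coupled model for each row of an environment table.

    ``env_table`` needs columns Iinc, Ca, Tleaf, VPD (O2 partial pressure
    optional as column ``O``).  Returns one row per input row with the solved
    An, Ci, Cc, gs, the limitation flag and the three balance residuals.
    """
    records = []
    for row in env_table.itertuples(index=False):
        env = Environment(iinc=row.Iinc, ca=row.Ca, t=row.Tleaf, vpd=row.VPD,
                          o=getattr(row, "O", 210.0))
        sol = solve_leaf(env, biochem, stomatal, constants)
        records.append({
            "Iinc": env.iinc, "Ca": env.ca, "Tleaf": env.t, "VPD": env.vpd,
            "An": sol.an, "Ci": sol.ci, "Cc": sol.cc, "gs": sol.gs,
            "limitation": sol.limitation,
            "resid_biochem": sol.residuals[0],
            "resid_gs": sol.residuals[1],
            "resid_diffusion": sol.residuals[2],
        })
    return pd.DataFrame.from_records(records)
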