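"""Two-state thermal-melt analysis of CD spectral series.

The melt is modelled as a two-state transition with van't Hoff enthalpy
dH_vH and zero heat-capacity change, so only an apparent melting
temperature is extracted:

    dG(T) = dH_vH * (1 - T/Tm),   f_U = K/(1+K),  K = exp(-dG/RT)

The fit is global: Tm and dH_vH are shared across all wavelengths while
each wavelength gets its own folded/unfolded linear-in-T baselines,
solved by linear least squares inside the nonlinear search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .constants import R_KCAL
from .equilibrium import SpectralSeries

_KELVIN = 273.15


@dataclass
class MeltFit:
    Tm: float          # degC
    dH_vH: float       # kcal/mol
    Tm_err: float
    dH_err: float
    baselines: np.ndarray  # (n_wavelengths, 4): fA, fB, uA, uB
    residual_norm: float
    success: bool
    message: str


def fraction_unfolded(Tm: float, dH_vH: float, T) -> np.ndarray:
    """Unfolded fraction at temperature T (degC) for midpoint Tm (degC)."""
    T_K = np.asarray(T, dtype=float) + _KELVIN
    Tm_K = Tm + _KELVIN
    dG = dH_vH * (1.0 - T_K / Tm_K)
    K = np.exp(-dG / (R_KCAL * T_K))
    return K / (1.0 + K)


def fit_melt(series: SpectralSeries, init: dict | None = None) -> MeltFit:
    """Global two-state fit of a CD melt series; returns apparent Tm."""
    if series.kind != "CD":
        raise ValueError("fit_melt expects a CD series")
    T = series.axis2
    if T.size < 8:
        raise ValueError("need at least 8 temperatures")
    Y = series.matrix  # (n_wl, n_T)

    init = dict(init or {})
    p0 = [init.get("Tm", float(np.median(T))), init.get("dH_vH", 50.0)]
    lo = [T.min() - 50.0, 1.0]
    hi = [T.max() + 50.0, 1000.0]

    Tc = T - T.mean()  # centred baseline coordinate for conditioning

    def solve_linear(p):
        fU = fraction_unfolded(p[0], p[1], T)
        fN = 1.0 - fU
        X = np.stack([fN, fN * Tc, fU, fU * Tc], axis=1)
        coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
        return X @ coef, coef

    def resid(p):
        Yhat, _ = solve_linear(p)
        return (Yhat - Y.T).ravel()

    sol = least_squares(resid, p0, bounds=(lo, hi), x_scale="jac")
    Yhat, coef = solve_linear(sol.x)

    dof = max(sol.fun.size - sol.x.size, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        perr = np.array([np.nan, np.nan])

    return MeltFit(
        Tm=float(sol.x[0]),
        dH_vH=float(sol.x[1]),
        Tm_err=float(perr[0]),
        dH_err=float(perr[1]),
        baselines=coef.T,
        residual_norm=float(np.linalg.norm(sol.fun)),
        success=bool(sol.success),
        message=str(sol.message),
    )
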