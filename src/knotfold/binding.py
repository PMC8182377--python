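"""Single-site binding isotherm model and thermodynamic bookkeeping.

Per-injection heats follow the Wiseman 1:1 model: after injection i the
cell holds macromolecule M_t at n binding sites and cumulative titrant
X_t,i; the bound concentration is the exact root of the binding
quadratic, and the heat of injection i is the increment in bound ligand
times dH and the cell volume.  Raw thermogram integration is out of
scope; inputs are integrated heats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

from .constants import R_KCAL, T_DEFAULT

#: VP-ITC style cell volume, litres.
V_CELL_DEFAULT = 1.4e-3


@dataclass
class BindingResult:
    Kd: float        # M
    dH: float        # kcal/mol
    n_sites: float
    T: float = T_DEFAULT
    Kd_err: float = np.nan
    dH_err: float = np.nan
    n_err: float = np.nan

    @property
    def dG(self) -> float:
        """Standard-state (1 M) binding free energy, RT ln Kd (negative)."""
        return R_KCAL * self.T * np.log(self.Kd)

    @property
    def TdS(self) -> float:
        return self.dH - self.dG


def bound_fraction(Kd: float, n_sites: float, M_t, X_t) -> np.ndarray:
    """Bound-ligand concentration from the exact binding quadratic.

    Solves [MX] for M_t total macromolecule (n_sites sites) and X_t total
    ligand:  [MX]^2 - (nM + X + Kd)[MX] + nM X = 0, taking the physical root.
    """
    M_t = np.asarray(M_t, dtype=float)
    X_t = np.asarray(X_t, dtype=float)
    sites = n_sites * M_t
    b = sites + X_t + Kd
    disc = b * b - 4.0 * sites * X_t
    return 0.5 * (b - np.sqrt(np.clip(disc, 0.0, None)))


def bound_fraction_numeric(Kd: float, n_sites: float, M_t: float, X_t: float) -> float:
    """Brute-force mass-action equilibrium solver (oracle for the quadratic)."""
    sites = n_sites * M_t
    if X_t == 0 or sites == 0:
        return 0.0

    def f(mx):
        return (sites - mx) * (X_t - mx) - Kd * mx

    return brentq(f, 0.0, min(sites, X_t), xtol=1e-18, rtol=1e-14)


def isotherm(
    Kd: float,
    dH: float,
    n_sites: float,
    cell_conc: float,
    injections: np.ndarray,
    V_cell: float = V_CELL_DEFAULT,
) -> np.ndarray:
    """Heat per injection (kcal) for cumulative titrant concentrations.

    ``injections`` is the cumulative total ligand concentration in the
    cell after each injection (M).  Dilution/displacement corrections are
    not modelled.  A low-c titration (final X_t below the site
    concentration) is flagged.
    """
    injections = np.asarray(injections, dtype=float)
    if cell_conc <= 0 or np.any(injections < 0):
        raise ValueError("concentrations must be positive")
    if np.any(np.diff(injections) < 0):
        raise ValueError("cumulative titrant must be non-decreasing")
    if injections[-1] < n_sites * cell_conc:
        import warnings

        warnings.warn("titrant never exceeds cell site capacity (low c)", stacklevel=2)
    B = bound_fraction(Kd, n_sites, cell_conc, injections)
    Q = V_cell * dH * B
    return np.diff(np.concatenate([[0.0], Q]))


def fit_isotherm(
    heats: np.ndarray,
    injections: np.ndarray,
    cell_conc: float,
    T: float = T_DEFAULT,
    V_cell: float = V_CELL_DEFAULT,
) -> BindingResult:
    """Fit (Kd, dH, n) to per-injection heats; fills dG and TdS."""
    heats = np.asarray(heats, dtype=float)
    injections = np.asarray(injections, dtype=float)
    if heats.size < 10:
        raise ValueError("need at least 10 injections")

    total = heats.sum()
    dH0 = total / (cell_conc * V_cell) if total != 0 else -10.0
    scale = max(np.abs(heats).max(), 1e-300)  # heats are tiny in kcal

    def resid(p):
        lnKd, dH, n = p
        model = isotherm(np.exp(lnKd), dH, n, cell_conc, injections, V_cell)
        return (model - heats) / scale

    p0 = [np.log(cell_conc / 10.0), dH0, 1.0]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = least_squares(
            resid, p0, bounds=([-35.0, -1e4, 0.05], [0.0, 1e4, 20.0]), x_scale="jac"
        )
    dof = max(sol.fun.size - 3, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        perr = np.full(3, np.nan)
    Kd = float(np.exp(sol.x[0]))
    if not sol.success:
        raise RuntimeError(f"isotherm fit did not converge: {sol.message}")
    return BindingResult(
        Kd=Kd,
        dH=float(sol.x[1]),
        n_sites=float(sol.x[2]),
        T=T,
        Kd_err=Kd * float(perr[0]),
        dH_err=float(perr[1]),
        n_err=float(perr[2]),
    )
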