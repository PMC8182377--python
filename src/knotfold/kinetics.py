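"""Folding-kinetics analysis: exponential traces, chevrons, derived thermodynamics.

Kinetic fluorescence traces are fitted to linear combinations of 1-4
exponentials; observed rate constants assembled over denaturant
concentration form a chevron, fitted per phase to the two-state rate law

    k_obs([D]) = kf0 * exp(mf [D] / RT) + ku0 * exp(mu [D] / RT)

with mf <= 0 (refolding arm) and mu >= 0 (unfolding arm); m-values carry
energy units (kcal mol^-1 M^-1).  The derived quantities follow the
standard chevron bookkeeping: m_kin = mu - mf, beta_T = -mf/m_kin,
dG_kin = RT ln(kf0/ku0), [D]50,kin = dG_kin/m_kin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .constants import R_KCAL, T_DEFAULT


@dataclass
class KineticTrace:
    t: np.ndarray
    signal: np.ndarray
    D_final: float = np.nan
    direction: Literal["unfolding", "refolding"] = "refolding"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.t.size != self.signal.size:
            raise ValueError("t and signal length mismatch")


@dataclass
class TraceFit:
    rates: np.ndarray       # s^-1, sorted descending
    amplitudes: np.ndarray
    offset: float
    rate_errors: np.ndarray
    n_exp: int
    aicc: float
    degenerate: bool
    residual_norm: float


@dataclass
class ChevronDataset:
    D: np.ndarray
    k_obs: np.ndarray
    phase: np.ndarray | None = None
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        if np.any(self.k_obs <= 0):
            raise ValueError("observed rates must be positive")


@dataclass
class ChevronPhaseFit:
    kf0: float
    mf: float
    ku0: float
    mu: float
    T: float = T_DEFAULT
    errors: dict = field(default_factory=dict)
    fixed_mu_zero: bool = False

    @property
    def m_kin(self) -> float:
        return self.mu - self.mf

    @property
    def beta_T(self) -> float:
        return -self.mf / self.m_kin

    @property
    def dG_kin(self) -> float:
        return float(R_KCAL * self.T * np.log(self.kf0 / self.ku0))

    @property
    def D50_kin(self) -> float:
        return self.dG_kin / self.m_kin

    def derived(self) -> dict:
        return {
            "m_kin": self.m_kin,
            "beta_T": self.beta_T,
            "D50_kin": self.D50_kin,
            "dG_kin": self.dG_kin,
        }


def _fit_n_exp(trace: KineticTrace, n_exp: int) -> TraceFit:
    """Variable-projection fit: nonlinear in ln k, linear in amplitudes."""
    t, y = trace.t, trace.signal
    t_scale = t[-1] - t[0]
    # log-spaced rate guesses spanning the observable window
    lnk0 = np.log(np.geomspace(0.5 / t_scale, n_exp * 20.0 / t_scale, n_exp))

    def amplitudes_for(lnk):
        X = np.column_stack(
            [np.ones_like(t)] + [np.exp(-np.exp(lk) * t) for lk in lnk]
        )
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef, X

    def resid(lnk):
        coef, X = amplitudes_for(lnk)
        return X @ coef - y

    sol = least_squares(resid, lnk0, x_scale="jac")
    coef, X = amplitudes_for(sol.x)
    rates = np.exp(sol.x)
    amps = coef[1:]
    offset = float(coef[0])

    dof = max(t.size - (2 * n_exp + 1), 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        errs = rates * np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        errs = np.full(n_exp, np.nan)

    order = np.argsort(rates)[::-1]
    rates, amps, errs = rates[order], amps[order], errs[order]
    # AICc for small-sample model comparison
    n, k = t.size, 2 * n_exp + 1
    rss = float(sol.fun @ sol.fun)
    aic = n * np.log(max(rss / n, 1e-300)) + 2 * k
    aicc = aic + (2.0 * k * (k + 1)) / max(n - k - 1, 1)
    degenerate = bool(
        n_exp > 1 and np.any(rates[:-1] / np.maximum(rates[1:], 1e-300) < 1.5)
    )
    return TraceFit(
        rates=rates,
        amplitudes=amps,
        offset=offset,
        rate_errors=errs,
        n_exp=n_exp,
        aicc=float(aicc),
        degenerate=degenerate,
        residual_norm=float(np.sqrt(rss)),
    )


def fit_trace(trace: KineticTrace, n_exp: int | Literal["auto"] = "auto") -> TraceFit:
    """Fit a kinetic trace to offset + sum of 1-4 decaying exponentials.

    ``n_exp='auto'`` tries 1..4 and selects by corrected AIC; rates come
    back sorted descending.  A fit whose rates are separated by <1.5x is
    flagged ``degenerate``.
    """
    if n_exp == "auto":
        best = None
        for n in range(1, 5):
            if trace.t.size < 10 * n:
                break
            fit = _fit_n_exp(trace, n)
            if fit.degenerate:
                continue
            if best is None or fit.aicc < best.aicc - 2.0:
                best = fit
        if best is None:
            best = _fit_n_exp(trace, 1)
        return best
    if not 1 <= n_exp <= 4:
        raise ValueError("n_exp must be in 1..4")
    if trace.t.size < 10 * n_exp:
        raise ValueError("need >=10 time points per fitted exponential")
    fit = _fit_n_exp(trace, n_exp)
    if fit.degenerate:
        warnings.warn("fitted rates are nearly degenerate", stacklevel=2)
    return fit


def chevron_rate(fit: ChevronPhaseFit, D) -> np.ndarray:
    """Observed rate k_obs([D]) of the two-state chevron law."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("denaturant concentration must be >= 0")
    RT = R_KCAL * fit.T
    return fit.kf0 * np.exp(fit.mf * D / RT) + fit.ku0 * np.exp(fit.mu * D / RT)


def chevron_minimum(fit: ChevronPhaseFit, D_max: float = 10.0) -> float:
    """Denaturant concentration at the chevron minimum (closed form)."""
    RT = R_KCAL * fit.T
    # d/dD [kf0 e^{mf D/RT} + ku0 e^{mu D/RT}] = 0
    if fit.mf >= 0 or fit.mu <= 0:
        raise ValueError("minimum requires mf < 0 < mu")
    return float(
        RT / (fit.mu - fit.mf) * np.log(-fit.mf * fit.kf0 / (fit.mu * fit.ku0))
    )


def fit_chevron(
    data: ChevronDataset,
    phase: str | None = None,
    fix_mu_zero: bool = False,
    T: float = T_DEFAULT,
) -> ChevronPhaseFit:
    """Least-squares fit of one kinetic phase's chevron in ln k space.

    Rates spanning many orders of magnitude are weighted equally on the
    log scale.  ``fix_mu_zero`` pins the unfolding m-value to zero, the
    convention used when the unfolding arm shows no denaturant
    dependence (beta_T is then exactly 1).
    """
    if phase is not None and data.phase is not None:
        sel = np.asarray(data.phase) == phase
        D, k = data.D[sel], data.k_obs[sel]
    else:
        D, k = data.D, data.k_obs
    if D.size < (3 if fix_mu_zero else 4):
        raise ValueError("too few chevron points")
    RT = R_KCAL * T
    lnk = np.log(k)

    kmin_idx = np.argmin(lnk)
    span = max(D.max() - D.min(), 1.0)
    if kmin_idx == 0 or kmin_idx == D.size - 1:
        warnings.warn(
            "chevron points do not bracket a minimum; one arm is unconstrained",
            stacklevel=2,
        )

    # parameters: ln kf0, mf (<=0), ln ku0, mu (>=0)
    p0 = [float(lnk[np.argmin(D)]), -1.5, float(lnk[kmin_idx] - 3.0), 1.0]
    lo = [-60.0, -10.0, -60.0, 0.0]
    hi = [60.0, 0.0, 60.0, 10.0]
    if fix_mu_zero:
        p0[3], lo[3], hi[3] = 0.0, 0.0, 1e-12

    def resid(p):
        model = np.logaddexp(p[0] + p[1] * D / RT, p[2] + p[3] * D / RT)
        return model - lnk

    sol = least_squares(resid, p0, bounds=(lo, hi), x_scale="jac")
    dof = max(sol.fun.size - (3 if fix_mu_zero else 4), 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        perr = np.full(4, np.nan)
    kf0, ku0 = float(np.exp(sol.x[0])), float(np.exp(sol.x[2]))
    errors = {
        "kf0": kf0 * perr[0],
        "mf": perr[1],
        "ku0": ku0 * perr[2],
        "mu": 0.0 if fix_mu_zero else perr[3],
    }
    return ChevronPhaseFit(
        kf0=kf0,
        mf=float(sol.x[1]),
        ku0=ku0,
        mu=0.0 if fix_mu_zero else float(sol.x[3]),
        T=T,
        errors=errors,
        fixed_mu_zero=fix_mu_zero,
    )


def derive_thermo(
    kf0: float, mf: float, ku0: float, mu: float, T: float = T_DEFAULT
) -> dict:
    """Chevron-derived thermodynamics for one kinetic phase.

    Returns m_kin = mu - mf, beta_T = -mf/m_kin, dG_kin = RT ln(kf0/ku0)
    and D50_kin = dG_kin/m_kin (all at temperature T in K).
    """
    if kf0 <= 0 or ku0 <= 0:
        raise ValueError("rate constants must be positive")
    return ChevronPhaseFit(kf0, mf, ku0, mu, T=T).derived()


def rate_ratio(k_a: float, k_b: float) -> float:
    """Fold-difference k_a / k_b between two rate constants."""
    if k_a <= 0 or k_b <= 0:
        raise ValueError("rates must be positive")
    return k_a / k_b
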