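"""Equilibrium chemical-denaturation analysis.

A denaturation experiment yields a matrix of spectra (wavelength x
denaturant concentration).  The number of thermodynamically distinct
states is estimated by singular value decomposition; the series is then
fitted to a linear three-state unfolding model

    N <-> I <-> D,   K_i([D]) = exp(-(dG_i - m_i [D]) / RT)

whose fractional populations weight per-state basis spectra.  An
optional multiplicative Gaussian window models the concentration-local
fluorescence loss produced by aggregation of the intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .constants import R_KCAL, T_DEFAULT


@dataclass
class SpectralSeries:
    """A spectral matrix over a condition series.

    ``matrix`` has shape (n_wavelengths, n_conditions); ``axis1`` is the
    wavelength grid (nm), ``axis2`` the condition grid ([D] in M, or T in
    degC for melts).
    """

    axis1: np.ndarray
    axis2: np.ndarray
    matrix: np.ndarray
    kind: Literal["fluorescence", "CD"] = "fluorescence"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis1 = np.asarray(self.axis1, dtype=float)
        self.axis2 = np.asarray(self.axis2, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.axis1.size, self.axis2.size):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match grids "
                f"({self.axis1.size}, {self.axis2.size})"
            )
        d = np.diff(self.axis2)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("condition grid must be strictly monotone")


@dataclass
class SignalLoss:
    """Multiplicative Gaussian signal-loss window 1 - A*exp(-([D]-mu)^2/2s^2)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("loss amplitude must be in [0, 1]")
        if self.width <= 0:
            raise ValueError("loss width must be positive")

    def factor(self, D: np.ndarray) -> np.ndarray:
        D = np.asarray(D, dtype=float)
        return 1.0 - self.amplitude * np.exp(-0.5 * ((D - self.center) / self.width) ** 2)


@dataclass
class ThreeStateModel:
    """Linear three-state equilibrium N <-> I <-> D.

    ``dG1``/``m1`` govern the N<->I step, ``dG2``/``m2`` the I<->D step;
    free energies are water values in kcal/mol, m-values in
    kcal mol^-1 M^-1 (positive).
    """

    dG1: float
    m1: float
    dG2: float
    m2: float
    T: float = T_DEFAULT
    baselines: dict | None = None

    def __post_init__(self) -> None:
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("m-values must be positive")


def populations(model: ThreeStateModel, D) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fractional populations (f_N, f_I, f_D) at denaturant concentration D.

    f_N = 1/(1 + K1 + K1 K2), f_I = K1 f_N, f_D = K1 K2 f_N with
    K_i = exp(-(dG_i - m_i D)/RT).  The three always sum to 1.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("denaturant concentration must be >= 0")
    RT = R_KCAL * model.T
    # log-space evaluation avoids overflow at high [D]
    lnK1 = -(model.dG1 - model.m1 * D) / RT
    lnK2 = -(model.dG2 - model.m2 * D) / RT
    # normalize against the largest exponent
    g = np.stack([np.zeros_like(lnK1), lnK1, lnK1 + lnK2])
    g -= g.max(axis=0, keepdims=True)
    w = np.exp(g)
    w /= w.sum(axis=0, keepdims=True)
    return w[0], w[1], w[2]


def transition_midpoints(model: ThreeStateModel) -> tuple[float, float]:
    """Midpoints [D]50 of each transition: dG_i / m_i (M)."""
    return model.dG1 / model.m1, model.dG2 / model.m2


def default_rank_rule(s: np.ndarray) -> int:
    """Count singular values exceeding 3x the median of the trailing half."""
    s = np.asarray(s, dtype=float)
    tail = s[s.size // 2:]
    floor = 3.0 * np.median(tail)
    return int(np.sum(s > max(floor, s[0] * 1e-10)))


@dataclass
class SVDResult:
    rank: int
    singular_values: np.ndarray
    left: np.ndarray   # wavelength-space basis vectors (columns)
    right: np.ndarray  # condition-space amplitude vectors (rows)


def svd_rank(series: SpectralSeries, threshold_rule=default_rank_rule) -> SVDResult:
    """Estimate the number of spectrally distinct states by SVD.

    Returns the rank under ``threshold_rule`` together with the full
    singular spectrum and the left/right singular vectors.
    """
    if series.axis1.size < 3 or series.axis2.size < 3:
        raise ValueError("need at least 3 wavelengths and 3 conditions")
    if not np.any(series.matrix):
        raise ValueError("all-zero spectral matrix")
    U, s, Vt = np.linalg.svd(series.matrix, full_matrices=False)
    return SVDResult(rank=threshold_rule(s), singular_values=s, left=U, right=Vt)


@dataclass
class EquilibriumFit:
    model: ThreeStateModel
    loss: SignalLoss | None
    errors: dict
    populations: np.ndarray      # (n_states, n_conditions)
    aggregated: np.ndarray       # lost-signal fraction per condition
    residual_norm: float
    n_states: int
    svd: SVDResult
    success: bool
    message: str


def _design_matrix(f: np.ndarray, D: np.ndarray, loss_factor: np.ndarray) -> np.ndarray:
    """Columns: per-state population and population*[D] terms, times loss."""
    cols = []
    for fs in f:
        cols.append(fs * loss_factor)
        cols.append(fs * D * loss_factor)
    return np.stack(cols, axis=1)


def fit_equilibrium(
    series: SpectralSeries,
    n_states: int = 3,
    loss: Literal["auto", "none"] | SignalLoss = "none",
    init: dict | None = None,
    bounds: dict | None = None,
    T: float = T_DEFAULT,
) -> EquilibriumFit:
    """Fit a two- or three-state equilibrium model to a denaturation series.

    The fit target is the leading SVD amplitude vectors (rank =
    ``n_states``) rather than the raw matrix, which conditions the
    problem; per-state linear-in-[D] baselines are solved by linear least
    squares inside the nonlinear optimisation (variable projection).

    ``loss='auto'`` co-fits a Gaussian signal-loss window; a
    :class:`SignalLoss` instance fixes the window; ``'none'`` disables it.
    """
    if n_states not in (2, 3):
        raise ValueError("n_states must be 2 or 3")
    if loss == "auto":
        # nested-model selection: keep the loss window only if it earns
        # its three parameters on corrected AIC
        fit_without = fit_equilibrium(series, n_states, "none", init, bounds, T)
        # multi-start the loss-window centre: the window/transition
        # degeneracy makes the forced fit sensitive to initialisation
        D = series.axis2
        fit_with = None
        for frac in (0.2, 0.35, 0.5, 0.65, 0.8):
            trial_init = dict(init or {})
            trial_init.setdefault("loss_width", 0.06 * (D.max() - D.min()))
            trial_init["loss_center"] = D.min() + frac * (D.max() - D.min())
            cand = fit_equilibrium(series, n_states, "_forced", trial_init, bounds, T)
            if fit_with is None or cand.residual_norm < fit_with.residual_norm:
                fit_with = cand

        def aicc(fit, k):
            n = series.axis2.size * n_states
            rss = fit.residual_norm**2
            a = n * np.log(max(rss / n, 1e-300)) + 2 * k
            return a + 2.0 * k * (k + 1) / max(n - k - 1, 1)

        if aicc(fit_with, 7) < aicc(fit_without, 4) - 2.0:
            return fit_with
        # report an explicitly zero-amplitude window for the nested check
        fit_without.loss = SignalLoss(0.0, 0.5 * (D.min() + D.max()), 1.0)
        return fit_without
    svd = svd_rank(series)
    if svd.rank != n_states:
        import warnings

        warnings.warn(
            f"SVD suggests {svd.rank} states but fitting {n_states}", stacklevel=2
        )
    D = series.axis2
    k = n_states
    # amplitude vectors scaled by singular values: what the model must reproduce
    A = (svd.singular_values[:k, None] * svd.right[:k])  # (k, n_conditions)

    fit_loss = loss == "_forced"
    RT = R_KCAL * T

    init = dict(init or {})
    span = D.max() - D.min() if D.max() > D.min() else 1.0
    p0 = [
        init.get("dG1", 3.0),
        init.get("m1", 2.0),
        init.get("dG2", 6.0),
        init.get("m2", 2.0),
    ]
    lo = [0.01, 0.05, 0.01, 0.05]
    hi = [30.0, 10.0, 30.0, 10.0]
    if fit_loss:
        p0 += [
            init.get("loss_amplitude", 0.3),
            init.get("loss_center", 0.5 * (D.min() + D.max())),
            init.get("loss_width", 0.15 * span),
        ]
        lo += [0.0, D.min(), 0.01 * span]
        hi += [1.0, D.max(), span]
    if bounds:
        for i, name in enumerate(["dG1", "m1", "dG2", "m2"]):
            if name in bounds:
                lo[i], hi[i] = bounds[name]

    def unpack(p):
        if n_states == 3:
            model = ThreeStateModel(p[0], p[1], p[2], p[3], T=T)
        else:
            # two-state: push the intermediate out of reach
            model = ThreeStateModel(p[0], p[1], 1e3, p[3], T=T)
        if fit_loss:
            lw = SignalLoss(min(max(p[4], 0.0), 1.0), p[5], max(p[6], 1e-6))
        elif isinstance(loss, SignalLoss):
            lw = loss
        else:
            lw = None
        return model, lw

    def model_amplitudes(p):
        model, lw = unpack(p)
        f = np.stack(populations(model, D))
        lf = lw.factor(D) if lw is not None else np.ones_like(D)
        X = _design_matrix(f, D, lf)
        coef, *_ = np.linalg.lstsq(X, A.T, rcond=None)
        return X @ coef, model, lw

    def resid(p):
        Ahat, *_ = model_amplitudes(p)
        return (Ahat - A.T).ravel()

    sol = least_squares(resid, p0, bounds=(lo, hi), x_scale="jac")
    Ahat, model, lw = model_amplitudes(sol.x)

    # asymptotic standard errors from the Jacobian
    dof = max(sol.fun.size - sol.x.size, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        JTJ = sol.jac.T @ sol.jac
        cov = s2 * np.linalg.pinv(JTJ)
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        perr = np.full(sol.x.size, np.nan)
    err_names = ["dG1", "m1", "dG2", "m2"]
    if fit_loss:
        err_names += ["loss_amplitude", "loss_center", "loss_width"]
    errors = dict(zip(err_names, perr))

    f = np.stack(populations(model, D))
    lf = lw.factor(D) if lw is not None else np.ones_like(D)
    return EquilibriumFit(
        model=model,
        loss=lw,
        errors=errors,
        populations=f,
        aggregated=1.0 - lf,
        residual_norm=float(np.linalg.norm(sol.fun)),
        n_states=n_states,
        svd=svd,
        success=bool(sol.success),
        message=str(sol.message),
    )
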