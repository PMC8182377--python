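"""15N spin-relaxation analysis: rate extraction, reduced spectral density
mapping, model-free reference curves, and Gaussian T1/T2 residue profiles.

The forward model is the standard dipolar + CSA expression set for an
amide 15N relaxed by its attached proton, evaluated on the isotropic
model-free spectral density

    J(w) = (2/5) [ S^2 tau_m / (1 + (w tau_m)^2)
                 + (1 - S^2) tau' / (1 + (w tau')^2) ],
    1/tau' = 1/tau_m + 1/tau_e.

Reduced mapping inverts (R1, R2, NOE) into J(0), J(wN) and an effective
high-frequency value J(0.87 wH) under the usual assumption that J is
flat around the proton frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import GAMMA_H, GAMMA_N, PhysicalConstants


@dataclass
class ModelFreeParams:
    """Isotropic model-free motional parameters."""

    S2: float       # order parameter squared, [0, 1]
    tau_m: float    # overall correlation time, ns
    tau_e: float = 50.0  # internal correlation time, ps
    R_ex: float = 0.0    # exchange contribution to R2, s^-1

    def __post_init__(self) -> None:
        if not 0.0 <= self.S2 <= 1.0:
            raise ValueError("S2 must lie in [0, 1]")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.tau_e < 0 or self.R_ex < 0:
            raise ValueError("tau_e and R_ex must be non-negative")


@dataclass
class RelaxationRecord:
    residue: int
    R1: float       # s^-1
    R2: float       # s^-1
    NOE: float
    R1_err: float = np.nan
    R2_err: float = np.nan
    NOE_err: float = np.nan

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.R2 <= 0:
            raise ValueError("relaxation rates must be positive")

    @property
    def T1(self) -> float:
        """Longitudinal relaxation time, s."""
        return 1.0 / self.R1

    @property
    def T2(self) -> float:
        """Transverse relaxation time, s."""
        return 1.0 / self.R2


@dataclass
class SpectralDensityTriple:
    J0: float        # s/rad
    JwN: float
    JwH_eff: float   # at 0.87 wH
    field: float
    physical: bool = True


def model_free_J(params: ModelFreeParams, omega) -> np.ndarray:
    """Isotropic model-free spectral density J(omega), s/rad."""
    omega = np.asarray(omega, dtype=float)
    tm = params.tau_m * 1e-9
    te = params.tau_e * 1e-12
    tp = tm * te / (tm + te) if te > 0 else 0.0
    J = params.S2 * tm / (1.0 + (omega * tm) ** 2)
    if tp > 0:
        J = J + (1.0 - params.S2) * tp / (1.0 + (omega * tp) ** 2)
    return 0.4 * J


def forward_rates(
    params: ModelFreeParams, constants: PhysicalConstants | None = None
) -> tuple[float, float, float]:
    """(R1, R2, NOE) from the standard dipolar + CSA expressions."""
    c0 = constants or PhysicalConstants()
    d2 = c0.d**2
    c2 = c0.c**2
    wh, wn = c0.omega_h, c0.omega_n

    def J(w):
        return float(model_free_J(params, abs(w)))

    Jh_m_n = J(wh - wn)
    Jn = J(wn)
    Jh_p_n = J(wh + wn)
    Jh = J(wh)
    J0 = J(0.0)

    R1 = (d2 / 4.0) * (Jh_m_n + 3.0 * Jn + 6.0 * Jh_p_n) + c2 * Jn
    R2 = (
        (d2 / 8.0) * (4.0 * J0 + Jh_m_n + 3.0 * Jn + 6.0 * Jh + 6.0 * Jh_p_n)
        + (c2 / 6.0) * (4.0 * J0 + 3.0 * Jn)
        + params.R_ex
    )
    NOE = 1.0 + (d2 / 4.0) * (GAMMA_H / GAMMA_N) * (6.0 * Jh_p_n - Jh_m_n) / R1
    return R1, R2, NOE


def reduced_mapping(
    rec: RelaxationRecord, constants: PhysicalConstants | None = None
) -> SpectralDensityTriple:
    """Reduced spectral density mapping of one residue's (R1, R2, NOE).

    sigma_NH = R1 (NOE - 1) gammaN/gammaH;
    J(0.87 wH) = 4 sigma_NH / (5 d^2);
    J(wN) = [R1 - (7 d^2/4) J(0.87 wH)] / (3 d^2/4 + c^2);
    J(0)  = [R2 - (3 d^2/8 + c^2/2) J(wN) - (13 d^2/8) J(0.87 wH)]
            / (d^2/2 + 2 c^2/3).
    """
    c0 = constants or PhysicalConstants()
    d2 = c0.d**2
    c2 = c0.c**2
    sigma = rec.R1 * (rec.NOE - 1.0) * (GAMMA_N / GAMMA_H)
    JwH = 4.0 * sigma / (5.0 * d2)
    JwN = (rec.R1 - (7.0 * d2 / 4.0) * JwH) / (3.0 * d2 / 4.0 + c2)
    J0 = (
        rec.R2 - (3.0 * d2 / 8.0 + c2 / 2.0) * JwN - (13.0 * d2 / 8.0) * JwH
    ) / (d2 / 2.0 + 2.0 * c2 / 3.0)
    physical = J0 >= JwN >= JwH >= 0
    if not physical:
        warnings.warn(
            f"residue {rec.residue}: spectral densities not ordered "
            "J0 >= JwN >= JwH (exchange or noise)",
            stacklevel=2,
        )
    noe_max = 1.0 + (GAMMA_H / GAMMA_N) * 0.5  # crude sanity ceiling
    if rec.NOE > 1.0 and rec.NOE > abs(noe_max):
        warnings.warn(f"residue {rec.residue}: NOE above theoretical maximum", stacklevel=2)
    return SpectralDensityTriple(
        J0=J0, JwN=JwN, JwH_eff=JwH, field=c0.field, physical=physical
    )


def fit_decay(delays, intensities) -> tuple[float, float]:
    """Single-exponential decay rate (s^-1) from peak intensities vs delay (s)."""
    delays = np.asarray(delays, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if delays.size < 4:
        raise ValueError("need at least 4 relaxation delays")
    if intensities[-1] >= intensities[0] * (1.0 - 1e-9):
        warnings.warn("series does not decay; rate ~ 0", stacklevel=2)

    def f(t, I0, k):
        return I0 * np.exp(-k * t)

    span = delays[-1] - delays[0]
    k0 = max(np.log(max(intensities[0], 1e-30) / max(intensities[-1], 1e-30)), 1e-9) / span
    popt, pcov = curve_fit(
        f, delays, intensities, p0=[intensities[0], k0], maxfev=10000
    )
    err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    return float(popt[1]), err


def order_parameter_curve(
    S2: float,
    tau_m_range,
    constants: PhysicalConstants | None = None,
    tau_e: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric (J0, JwN) reference curve at fixed S^2, tau_m swept (ns).

    Used to overlay residue clusters on spectral-density maps; the
    convention for quoting S vs S^2 is the caller's choice (pass S**2).
    """
    c0 = constants or PhysicalConstants()
    tau_m_range = np.asarray(tau_m_range, dtype=float)
    J0 = np.empty_like(tau_m_range)
    JwN = np.empty_like(tau_m_range)
    for i, tm in enumerate(tau_m_range):
        p = ModelFreeParams(S2=S2, tau_m=tm, tau_e=tau_e)
        J0[i] = float(model_free_J(p, 0.0))
        JwN[i] = float(model_free_J(p, abs(c0.omega_n)))
    return J0, JwN


@dataclass
class GaussianMixtureProfile:
    n_components: int
    baseline: float
    centers: np.ndarray     # residue index
    widths: np.ndarray      # residues
    amplitudes: np.ndarray
    bic: float
    overlapping: bool

    def predict(self, residues) -> np.ndarray:
        x = np.asarray(residues, dtype=float)
        y = np.full_like(x, self.baseline)
        for a, c, w in zip(self.amplitudes, self.centers, self.widths):
            y = y + a * np.exp(-0.5 * ((x - c) / w) ** 2)
        return y


def _fit_gaussian_sum(x, y, k: int) -> GaussianMixtureProfile:
    if k == 0:
        resid = y - y.mean()
        n_par = 1
        rss = float(resid @ resid)
        n = x.size
        bic = n * np.log(max(rss / n, 1e-300)) + n_par * np.log(n)
        return GaussianMixtureProfile(
            0, float(y.mean()), np.array([]), np.array([]), np.array([]), float(bic), False
        )

    # variable projection: centres/widths nonlinear, baseline+amplitudes linear
    base = float(np.median(y))
    dev = np.abs(y - base)
    order = np.argsort(dev)[::-1]
    centers, min_sep = [], (x.max() - x.min()) / (2.0 * k + 1.0)
    for idx in order:
        if all(abs(x[idx] - c) > min_sep for c in centers):
            centers.append(float(x[idx]))
        if len(centers) == k:
            break
    while len(centers) < k:
        centers.append(float(x.min() + (len(centers) + 0.5) * (x.max() - x.min()) / k))
    w0 = max(min_sep / 2.0, 2.0)
    p0 = np.concatenate([centers, np.full(k, w0)])
    lo = np.concatenate([np.full(k, x.min() - 5), np.full(k, 0.5)])
    hi = np.concatenate([np.full(k, x.max() + 5), np.full(k, x.max() - x.min())])

    def design(p):
        c, w = p[:k], p[k:]
        cols = [np.ones_like(x)] + [
            np.exp(-0.5 * ((x - c[i]) / w[i]) ** 2) for i in range(k)
        ]
        return np.stack(cols, axis=1)

    def solve(p):
        X = design(p)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef, X

    def resid(p):
        coef, X = solve(p)
        return X @ coef - y

    from scipy.optimize import least_squares

    res = least_squares(resid, p0, bounds=(lo, hi), x_scale="jac")
    coef, X = solve(res.x)
    cen, wid = res.x[:k], res.x[k:]
    amp = coef[1:]
    n, n_par = x.size, 1 + 3 * k
    rss = float(res.fun @ res.fun)
    bic = n * np.log(max(rss / n, 1e-300)) + n_par * np.log(n)
    overlap = False
    if k > 1:
        srt = np.argsort(cen)
        cs, ws = cen[srt], wid[srt]
        overlap = bool(np.any(np.diff(cs) < 0.5 * (ws[:-1] + ws[1:])))
    return GaussianMixtureProfile(k, float(coef[0]), cen, wid, amp, float(bic), overlap)


def fit_t1t2_profile(
    residues, t1t2, n_gaussians: int | str = "auto", k_max: int = 4
) -> GaussianMixtureProfile:
    """Fit a T1/T2-vs-residue profile to baseline + sum of Gaussians.

    ``'auto'`` compares k = 0..k_max by BIC; a flat profile
    selects k = 0 (or one broad component).  Overlapping unresolvable
    components are flagged on the returned profile.
    """
    x = np.asarray(residues, dtype=float)
    y = np.asarray(t1t2, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 residues")
    if n_gaussians == "auto":
        best = _fit_gaussian_sum(x, y, 0)
        for k in range(1, k_max + 1):
            try:
                cand = _fit_gaussian_sum(x, y, k)
            except Exception:
                continue
            if cand.bic < best.bic - 2.0:
                best = cand
        if best.overlapping:
            warnings.warn("overlapping Gaussian components", stacklevel=2)
        return best
    prof = _fit_gaussian_sum(x, y, int(n_gaussians))
    if prof.overlapping:
        warnings.warn("overlapping Gaussian components", stacklevel=2)
    return prof


def mean_T2(records: list[RelaxationRecord]) -> float:
    """Mean transverse relaxation time (s) over a residue set."""
    return float(np.mean([r.T2 for r in records]))
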