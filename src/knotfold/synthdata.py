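"""Seeded synthetic-data generators for every pipeline stage.

Each generator draws from the forward model its analysis module inverts
and attaches a :class:`GroundTruth` record, so parameter-recovery tests
never need external data.  Noise is additive i.i.d. Gaussian on the
signal (SAXS optionally Poisson-like, sigma ~ sqrt(I)); seeds are always
explicit arguments, never global state.

Default basis spectra emulate tryptophan fluorescence: Gaussian emission
bands whose peak red-shifts and dims as the protein unfolds (native
~330 nm, intermediate ~340 nm, denatured ~355 nm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .constants import PhysicalConstants
from .equilibrium import SignalLoss, SpectralSeries, ThreeStateModel, populations
from .kinetics import KineticTrace
from .knots import Curve3D
from .relaxation import ModelFreeParams, RelaxationRecord, forward_rates
from .saxs import SAXSProfile
from .thermal import fraction_unfolded


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters attached to every synthetic dataset."""

    stage: str
    params: dict
    seed: int | None
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------- spectra


def default_basis_spectra(
    wavelengths: np.ndarray, n_states: int = 3
) -> np.ndarray:
    """Gaussian emission bands for up to three states (rows: N, I, D)."""
    wl = np.asarray(wavelengths, dtype=float)
    bands = [
        (1.00, 330.0, 22.0),   # native: blue-shifted, bright
        (0.70, 340.0, 25.0),   # intermediate
        (0.45, 355.0, 30.0),   # denatured: red-shifted, quenched
    ]
    out = np.stack(
        [a * np.exp(-0.5 * ((wl - mu) / sd) ** 2) for a, mu, sd in bands[:n_states]]
    )
    return out


def gen_denaturation_series(
    model: ThreeStateModel,
    basis_spectra: np.ndarray | None = None,
    denaturant_grid: np.ndarray | None = None,
    loss: SignalLoss | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
) -> SpectralSeries:
    """Three-state denaturation spectral series with optional signal loss.

    Defaults mirror a typical titration: 41 urea points 0-7 M (linear
    2.5% increments) and emission spectra 300-450 nm.
    """
    if denaturant_grid is None:
        denaturant_grid = np.linspace(0.0, 7.0, 41)
    D = np.asarray(denaturant_grid, dtype=float)
    if np.any(np.diff(D) <= 0):
        raise ValueError("denaturant grid must be strictly increasing")
    if np.any(D < 0):
        raise ValueError("negative denaturant concentration")
    if wavelengths is None:
        wavelengths = np.arange(300.0, 451.0, 2.0)
    wl = np.asarray(wavelengths, dtype=float)
    if basis_spectra is None:
        basis_spectra = default_basis_spectra(wl, 3)
    B = np.asarray(basis_spectra, dtype=float)
    if B.shape[1] != wl.size:
        raise ValueError("basis spectra not on the wavelength grid")
    f = np.stack(populations(model, D))[: B.shape[0]]  # (n_states, n_D)
    M = B.T @ f                                        # (n_wl, n_D)
    if loss is not None:
        M = M * loss.factor(D)[None, :]
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        M = M + rng.normal(0.0, noise_sd, M.shape)
    truth = GroundTruth(
        "equilibrium",
        {
            "dG1": model.dG1, "m1": model.m1, "dG2": model.dG2, "m2": model.m2,
            "loss": None if loss is None else vars(loss).copy(),
        },
        seed,
        noise_sd,
    )
    return SpectralSeries(wl, D, M, kind="fluorescence", meta={"truth": truth})


def gen_melt_series(
    Tm: float,
    dH_vH: float,
    baselines: tuple | None = None,
    T_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
) -> SpectralSeries:
    """Two-state CD thermal melt; Gibbs-Helmholtz unfolded fraction.

    Defaults: temperatures 25-80 degC every 2 degC, far-UV CD 210-250 nm.
    ``baselines`` supplies (folded_spectrum, unfolded_spectrum) rows; a
    smooth default difference spectrum is used otherwise.
    """
    if dH_vH <= 0:
        raise ValueError("dH_vH must be positive")
    if T_grid is None:
        T_grid = np.arange(25.0, 80.0, 2.0)
    T = np.asarray(T_grid, dtype=float)
    if np.any(T < -50) or np.any(T > 150):
        raise ValueError("temperature grid outside physical range")
    if wavelengths is None:
        wavelengths = np.arange(210.0, 251.0, 2.0)
    wl = np.asarray(wavelengths, dtype=float)
    if baselines is None:
        folded = -10.0 * np.exp(-0.5 * ((wl - 222.0) / 12.0) ** 2)
        unfolded = -3.0 * np.exp(-0.5 * ((wl - 215.0) / 18.0) ** 2)
    else:
        folded, unfolded = (np.asarray(b, dtype=float) for b in baselines)
    fU = fraction_unfolded(Tm, dH_vH, T)
    M = np.outer(folded, 1.0 - fU) + np.outer(unfolded, fU)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        M = M + rng.normal(0.0, noise_sd, M.shape)
    meta = {
        "truth": GroundTruth("melt", {"Tm": Tm, "dH_vH": dH_vH}, seed, noise_sd),
        "Tm_in_range": bool(T.min() <= Tm <= T.max()),
    }
    return SpectralSeries(wl, T, M, kind="CD", meta=meta)


# ---------------------------------------------------------------- kinetics


def gen_kinetic_trace(
    rates: Sequence[float],
    amplitudes: Sequence[float],
    offset: float = 0.0,
    t_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    D_final: float = np.nan,
    direction: str = "refolding",
) -> KineticTrace:
    """Multi-exponential kinetic trace: offset + sum a_i exp(-k_i t) + noise."""
    rates = np.asarray(rates, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if rates.size == 0:
        raise ValueError("empty rate list")
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    if t_grid is None:
        t_grid = np.linspace(0.0, 5.0 / rates.min(), 500)
    t = np.asarray(t_grid, dtype=float)
    y = offset + (amplitudes[None, :] * np.exp(-np.outer(t, rates))).sum(axis=1)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, y.shape)
    truth = GroundTruth(
        "kinetics",
        {"rates": rates.tolist(), "amplitudes": amplitudes.tolist(), "offset": offset},
        seed,
        noise_sd,
    )
    return KineticTrace(t, y, D_final=D_final, direction=direction, meta={"truth": truth})


def gen_chevron_points(
    kf0: float,
    mf: float,
    ku0: float,
    mu: float,
    D_grid: np.ndarray,
    noise_lnk_sd: float = 0.0,
    seed: int = 0,
    T: float = 298.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed rates on a chevron with Gaussian noise on ln k."""
    from .kinetics import ChevronPhaseFit, chevron_rate

    fit = ChevronPhaseFit(kf0, mf, ku0, mu, T=T)
    D = np.asarray(D_grid, dtype=float)
    k = chevron_rate(fit, D)
    rng = np.random.default_rng(seed)
    if noise_lnk_sd > 0:
        k = np.exp(np.log(k) + rng.normal(0.0, noise_lnk_sd, k.shape))
    return D, k


# ---------------------------------------------------------------- relaxation


def gen_relaxation_table(
    mf_params: Sequence[ModelFreeParams],
    constants: PhysicalConstants | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    residues: Sequence[int] | None = None,
) -> list[RelaxationRecord]:
    """Per-residue (R1, R2, NOE) from the model-free forward model.

    ``noise_sd`` is the fractional Gaussian noise on the rates and the
    absolute noise on the NOE.
    """
    c0 = constants or PhysicalConstants()
    rng = np.random.default_rng(seed)
    if residues is None:
        residues = range(1, len(mf_params) + 1)
    out = []
    for resi, p in zip(residues, mf_params):
        R1, R2, NOE = forward_rates(p, c0)
        if noise_sd > 0:
            R1 *= 1.0 + rng.normal(0.0, noise_sd)
            R2 *= 1.0 + rng.normal(0.0, noise_sd)
            NOE += rng.normal(0.0, noise_sd)
        out.append(
            RelaxationRecord(
                residue=int(resi), R1=R1, R2=R2, NOE=NOE,
                R1_err=noise_sd * R1, R2_err=noise_sd * R2, NOE_err=noise_sd,
            )
        )
    return out


def gen_decay_series(
    rate: float,
    delays: np.ndarray,
    I0: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-exponential intensity decay over relaxation delays (s)."""
    d = np.asarray(delays, dtype=float)
    y = I0 * np.exp(-rate * d)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd * I0, y.shape)
    return d, y


# ---------------------------------------------------------------- SAXS


def debye_coil_intensity(q: np.ndarray, Rg: float, I0: float = 1.0) -> np.ndarray:
    """Debye form factor of an ideal Gaussian chain."""
    x = (np.asarray(q, dtype=float) * Rg) ** 2
    # series expansion below x ~ 1e-3 avoids catastrophic cancellation
    out = I0 * (1.0 - x / 3.0 + x**2 / 12.0)
    big = x > 1e-3
    out[big] = I0 * 2.0 * (np.exp(-x[big]) + x[big] - 1.0) / x[big] ** 2
    return out


def sphere_intensity(q: np.ndarray, Rg: float, I0: float = 1.0) -> np.ndarray:
    """Homogeneous-sphere form factor with matching Rg (R = Rg sqrt(5/3))."""
    R = Rg * np.sqrt(5.0 / 3.0)
    u = np.asarray(q, dtype=float) * R
    out = I0 * (1.0 - u**2 / 5.0)  # small-u series, avoids cancellation
    big = u > 1e-2
    out[big] = I0 * (3.0 * (np.sin(u[big]) - u[big] * np.cos(u[big])) / u[big] ** 3) ** 2
    return out


def gen_saxs_profile(
    shape: Literal["debye_coil", "sphere"],
    Rg: float,
    I0: float = 1.0,
    q_grid: np.ndarray | None = None,
    noise_model: tuple[str, float] | None = None,
    seed: int = 0,
) -> SAXSProfile:
    """Synthetic 1-D SAXS profile for a coil or compact globule.

    ``noise_model``: ``('relative', f)`` for sigma = f*I, or
    ``('poisson', s)`` for sigma = s*sqrt(I).  Default q grid spans the
    instrument range 0.005-0.434 1/angstrom.
    """
    if Rg <= 0:
        raise ValueError("Rg must be positive")
    if q_grid is None:
        q_grid = np.linspace(0.005, 0.434, 300)
    q = np.asarray(q_grid, dtype=float)
    if shape == "debye_coil":
        I = debye_coil_intensity(q, Rg, I0)
    elif shape == "sphere":
        I = sphere_intensity(q, Rg, I0)
    else:
        raise ValueError(f"unknown shape: {shape}")
    sigma = None
    rng = np.random.default_rng(seed)
    if noise_model is not None:
        kind, scale = noise_model
        if kind == "relative":
            sigma = scale * I
        elif kind == "poisson":
            sigma = scale * np.sqrt(np.abs(I))
        else:
            raise ValueError(f"unknown noise model: {kind}")
        I = I + rng.normal(0.0, 1.0, I.shape) * sigma
    truth = GroundTruth(
        "saxs", {"shape": shape, "Rg": Rg, "I0": I0}, seed,
        0.0 if noise_model is None else noise_model[1],
    )
    return SAXSProfile(q, I, sigma, meta={"truth": truth})


# ---------------------------------------------------------------- curves


def gen_curve3d(
    kind: Literal[
        "unknot_circle", "trefoil", "figure8", "random_walk", "random_polygon"
    ],
    n_vertices: int = 200,
    seed: int = 0,
    scale: float = 10.0,
) -> Curve3D:
    """Parametric or random 3-D backbone curves with known topology.

    ``trefoil`` and ``figure8`` use standard parameterizations (closed);
    ``random_walk`` is an open Gaussian chain; ``random_polygon`` a
    closed Gaussian bridge.
    """
    if n_vertices < 3:
        raise ValueError("need at least 3 vertices")
    if kind == "unknot_circle":
        t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
        v = scale * np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        return Curve3D(v, closed=True, meta={"kind": kind})
    if kind == "trefoil":
        t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
        v = scale * np.stack(
            [
                np.sin(t) + 2.0 * np.sin(2 * t),
                np.cos(t) - 2.0 * np.cos(2 * t),
                -np.sin(3 * t),
            ],
            axis=1,
        )
        return Curve3D(v, closed=True, meta={"kind": kind})
    if kind == "figure8":
        t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
        v = scale * np.stack(
            [
                (2.0 + np.cos(2 * t)) * np.cos(3 * t),
                (2.0 + np.cos(2 * t)) * np.sin(3 * t),
                np.sin(4 * t),
            ],
            axis=1,
        )
        return Curve3D(v, closed=True, meta={"kind": kind})
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_vertices, 3))
    pts = np.cumsum(steps, axis=0) * scale / np.sqrt(n_vertices)
    if kind == "random_walk":
        return Curve3D(pts, closed=False, meta={"kind": kind})
    if kind == "random_polygon":
        frac = (np.arange(1, n_vertices + 1) / n_vertices)[:, None]
        pts = pts - frac * pts[-1]
        return Curve3D(pts, closed=True, meta={"kind": kind})
    raise ValueError(f"unknown curve kind: {kind}")


def gen_open_trefoil(n_vertices: int = 200, trim: int = 10, seed: int = 0) -> Curve3D:
    """Open, deeply knotted chain: a parametric trefoil with a short gap."""
    closed = gen_curve3d("trefoil", n_vertices + trim, seed=seed)
    v = closed.vertices[: n_vertices]
    return Curve3D(v, closed=False, meta={"kind": "open_trefoil"})


# ---------------------------------------------------------------- binding


def gen_isotherm(
    Kd: float,
    dH: float,
    n_sites: float = 1.0,
    cell_conc: float = 20e-6,
    n_injections: int = 28,
    titrant_max_ratio: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-injection heats for a 1:1 titration; noise relative to max |heat|.

    Returns (cumulative titrant concentrations, heats in kcal).
    """
    from .binding import isotherm

    X = np.linspace(1, n_injections, n_injections) * (
        titrant_max_ratio * n_sites * cell_conc / n_injections
    )
    q = isotherm(Kd, dH, n_sites, cell_conc, X)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        q = q + rng.normal(0.0, noise_sd * np.abs(q).max(), q.shape)
    return X, q
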