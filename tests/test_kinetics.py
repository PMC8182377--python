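"""Kinetic traces, chevron fits, and chevron-derived thermodynamics."""

import numpy as np
import pytest

from knotfold import kinetics, synthdata
from knotfold.constants import RT_DEFAULT
from knotfold.kinetics import (
    ChevronDataset,
    ChevronPhaseFit,
    chevron_minimum,
    chevron_rate,
    derive_thermo,
    fit_chevron,
    fit_trace,
    rate_ratio,
)

# chevron parameters of the four observed kinetic phases (linear and
# cyclized construct, fast and slow phase) with their derived quantities
# and printed uncertainties
PHASES = [
    # kf0, mf, ku0, mu, m_kin+-, beta_T+-, dG_kin+-
    ("linear-fast", 47.6, -2.87, 0.036, 0.19, (3.06, 0.06), (0.94, 0.05), (4.25, 0.06)),
    ("linear-slow", 6.42, -2.30, 9.50e-6, 1.33, (3.63, 0.16), (0.63, 0.06), (7.94, 0.30)),
    ("cyclized-fast", 124.0, -2.28, 0.360, 0.0, (2.28, 0.45), (1.00, 0.005), (3.46, 0.62)),
    ("cyclized-slow", 2.41, -1.71, 6.55e-7, 1.35, (3.06, 0.15), (0.56, 0.05), (8.95, 0.43)),
]


@pytest.mark.parametrize("name,kf0,mf,ku0,mu,mk,bt,dg", PHASES,
                         ids=[p[0] for p in PHASES])
def test_derived_thermodynamics_reproduce_reference_values(name, kf0, mf, ku0, mu, mk, bt, dg):
    d = derive_thermo(kf0, mf, ku0, mu)
    assert d["m_kin"] == pytest.approx(mk[0], abs=mk[1])
    assert d["beta_T"] == pytest.approx(bt[0], abs=max(bt[1], 0.005))
    assert d["dG_kin"] == pytest.approx(dg[0], abs=dg[1])


def test_derive_thermo_equal_rates_gives_zero_free_energy():
    d = derive_thermo(1.0, -2.0, 1.0, 1.0)
    assert d["dG_kin"] == 0.0
    assert d["D50_kin"] == 0.0


def test_free_energies_and_m_values_add_across_sequential_phases():
    d1 = derive_thermo(47.6, -2.87, 0.036, 0.19)
    d2 = derive_thermo(6.42, -2.30, 9.50e-6, 1.33)
    total_dG = d1["dG_kin"] + d2["dG_kin"]
    total_m = d1["m_kin"] + d2["m_kin"]
    assert total_dG == pytest.approx(
        RT_DEFAULT * (np.log(47.6 / 0.036) + np.log(6.42 / 9.50e-6))
    )
    assert total_m == pytest.approx((0.19 + 2.87) + (1.33 + 2.30))


def test_rate_ratio_of_slow_unfolding_rates_is_about_20fold():
    r = rate_ratio(9.5e-6, 4.9e-7)
    assert r == pytest.approx(19.39, abs=0.01)
    assert rate_ratio(2.0, 2.0) == 1.0
    assert rate_ratio(4.9e-7, 9.5e-6) == pytest.approx(1.0 / r)


def test_chevron_rate_at_zero_denaturant():
    fit = ChevronPhaseFit(47.6, -2.87, 0.036, 0.19)
    assert float(chevron_rate(fit, 0.0)) == pytest.approx(47.6 + 0.036)


def test_chevron_unfolding_arm_dominates_at_high_denaturant():
    fit = ChevronPhaseFit(47.6, -2.87, 0.036, 0.19)
    k = float(chevron_rate(fit, 9.0))
    unfolding_arm = 0.036 * np.exp(0.19 * 9.0 / RT_DEFAULT)
    assert k == pytest.approx(unfolding_arm, rel=1e-3)


def test_chevron_minimum_matches_brute_force_grid_search():
    fit = ChevronPhaseFit(47.6, -2.87, 0.036, 0.19)
    D = np.linspace(0, 10, 200001)
    brute = D[np.argmin(chevron_rate(fit, D))]
    assert chevron_minimum(fit) == pytest.approx(brute, abs=1e-4)


def test_log_chevron_is_convex_between_the_arms():
    fit = ChevronPhaseFit(6.42, -2.30, 9.50e-6, 1.33)
    D = np.linspace(0, 10, 400)
    lnk = np.log(chevron_rate(fit, D))
    assert np.all(np.diff(lnk, 2) > -1e-10)


def test_single_exponential_noiseless_exact():
    tr = synthdata.gen_kinetic_trace([3.7], [1.2], 0.4)
    fit = fit_trace(tr, n_exp=1)
    assert fit.rates[0] == pytest.approx(3.7, rel=1e-6)
    assert fit.offset == pytest.approx(0.4, abs=1e-8)


def test_biphasic_rates_recovered_within_10pct():
    tr = synthdata.gen_kinetic_trace(
        [47.6, 6.42], [0.5, 0.5], 1.0, noise_sd=0.01 * 1.0, seed=4
    )
    fit = fit_trace(tr, n_exp=2)
    assert fit.rates[0] == pytest.approx(47.6, rel=0.10)
    assert fit.rates[1] == pytest.approx(6.42, rel=0.10)


def test_auto_model_selection_picks_two_exponentials():
    tr = synthdata.gen_kinetic_trace([47.6, 6.42], [0.5, 0.5], 1.0,
                                     noise_sd=0.01, seed=4)
    fit = fit_trace(tr, n_exp="auto")
    assert fit.n_exp == 2


def test_trace_fit_input_validation():
    tr = synthdata.gen_kinetic_trace([1.0], [1.0], 0.0, t_grid=np.linspace(0, 5, 15))
    with pytest.raises(ValueError):
        fit_trace(tr, n_exp=2)  # too few points for 2 exponentials
    with pytest.raises(ValueError):
        fit_trace(tr, n_exp=5)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_chevron_recovery_within_15pct_at_5pct_lnk_noise(seed):
    D, k = synthdata.gen_chevron_points(
        47.6, -2.87, 0.036, 0.19, np.linspace(0.2, 8.0, 30), 0.05, seed=seed
    )
    fit = fit_chevron(ChevronDataset(D, k))
    assert fit.kf0 == pytest.approx(47.6, rel=0.15)
    assert fit.mf == pytest.approx(-2.87, rel=0.15)
    assert fit.ku0 == pytest.approx(0.036, rel=0.15)
    assert fit.mu == pytest.approx(0.19, rel=0.15)


def test_noiseless_chevron_exact_recovery():
    D, k = synthdata.gen_chevron_points(6.42, -2.30, 9.50e-6, 1.33,
                                        np.linspace(0.2, 9.0, 25))
    fit = fit_chevron(ChevronDataset(D, k))
    assert fit.kf0 == pytest.approx(6.42, rel=1e-5)
    assert fit.ku0 == pytest.approx(9.50e-6, rel=1e-4)


def test_fix_mu_zero_yields_exactly_native_like_beta():
    D, k = synthdata.gen_chevron_points(124.0, -2.28, 0.36, 0.0,
                                        np.linspace(0.2, 8.0, 30), 0.05, seed=6)
    fit = fit_chevron(ChevronDataset(D, k), fix_mu_zero=True)
    assert fit.beta_T == 1.0
    assert fit.mu == 0.0


def test_chevron_recovery_bias_below_reported_error():
    # simulation suite: bias over replicates stays below the per-fit
    # standard error at n=30 points, 5% ln-k noise
    vals = []
    errs = []
    for seed in range(12):
        D, k = synthdata.gen_chevron_points(
            47.6, -2.87, 0.036, 0.19, np.linspace(0.2, 8.0, 30), 0.05, seed=100 + seed
        )
        fit = fit_chevron(ChevronDataset(D, k))
        vals.append(fit.mf)
        errs.append(fit.errors["mf"])
    bias = abs(np.mean(vals) - (-2.87))
    assert bias < np.mean(errs)


def test_chevron_dataset_rejects_nonpositive_rates():
    with pytest.raises(ValueError):
        ChevronDataset(np.array([1.0]), np.array([-0.1]))
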