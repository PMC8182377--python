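"""15N relaxation: decay fits, model-free spectral densities, reduced
mapping round-trips, and T1/T2 residue profiles."""

import numpy as np
import pytest
from scipy.integrate import quad

from knotfold import relaxation, synthdata
from knotfold.constants import PhysicalConstants
from knotfold.relaxation import (
    ModelFreeParams,
    RelaxationRecord,
    fit_decay,
    fit_t1t2_profile,
    forward_rates,
    mean_T2,
    model_free_J,
    order_parameter_curve,
    reduced_mapping,
)

CONST = PhysicalConstants()

# the paper-style delay sets, in seconds
T1_DELAYS = np.array([20, 60, 120, 200, 300, 500, 800, 1000]) * 1e-3
T2_DELAYS = np.array([16, 32, 64, 96, 128, 160, 192, 224, 256]) * 1e-3


def test_decay_rate_from_122ms_t2_is_exact():
    rate = 1.0 / 0.122
    d, y = synthdata.gen_decay_series(rate, T2_DELAYS)
    got, _ = fit_decay(d, y)
    assert got == pytest.approx(rate, rel=1e-8)
    assert got == pytest.approx(8.1967, abs=1e-3)


def test_constant_intensities_flagged_with_near_zero_rate():
    with pytest.warns(UserWarning, match="does not decay"):
        rate, _ = fit_decay(T2_DELAYS, np.ones(9))
    assert abs(rate) < 1e-6


def test_decay_recovery_within_5pct_at_2pct_noise():
    rate = 1.0 / 0.238
    errs = []
    for seed in range(6):
        d, y = synthdata.gen_decay_series(rate, T2_DELAYS, noise_sd=0.02, seed=seed)
        got, _ = fit_decay(d, y)
        errs.append(abs(got / rate - 1.0))
    assert np.mean(errs) < 0.05


def test_rigid_limit_is_single_lorentzian():
    p = ModelFreeParams(1.0, 8.0)
    w = np.linspace(0, 5e9, 7)
    tm = 8e-9
    expected = 0.4 * tm / (1 + (w * tm) ** 2)
    np.testing.assert_allclose(model_free_J(p, w), expected, rtol=1e-12)


def test_zero_frequency_closed_form():
    p = ModelFreeParams(0.7, 6.0, tau_e=80.0)
    tm, te = 6e-9, 80e-12
    tp = tm * te / (tm + te)
    expected = 0.4 * (0.7 * tm + 0.3 * tp)
    assert float(model_free_J(p, 0.0)) == pytest.approx(expected, rel=1e-12)


def test_spectral_density_integral_matches_analytic_normalization(rng):
    # integral of J over [0, inf) is pi/5 for any model-free parameters;
    # split the integral at the two Lorentzian widths so quad resolves both
    for _ in range(50):
        p = ModelFreeParams(
            S2=rng.uniform(0.1, 1.0),
            tau_m=rng.uniform(1.0, 15.0),
            tau_e=rng.uniform(10.0, 200.0),
        )
        w1 = 1.0 / (p.tau_m * 1e-9)
        w2 = 1.0 / (p.tau_e * 1e-12)
        val = sum(
            quad(lambda w: model_free_J(p, w), a, b, limit=400)[0]
            for a, b in [(0, w1), (w1, w2)]
        )
        # tail via w = w2/t so the slowly-decaying Lorentzian is resolved
        val += quad(
            lambda t: float(model_free_J(p, w2 / t)) * w2 / t**2, 0.0, 1.0, limit=400
        )[0]
        assert val == pytest.approx(np.pi / 5.0, rel=1e-6)


def test_extreme_narrowing_r2_over_r1_approaches_one():
    # flat J makes the dipolar parts of R1 and R2 equal; the residual
    # ~3% offset is the CSA term's different weighting
    R1, R2, _ = forward_rates(ModelFreeParams(1.0, 1e-3))
    assert R2 / R1 == pytest.approx(1.0, abs=0.05)


def test_slow_tumbling_r2_over_r1_large():
    R1, R2, _ = forward_rates(ModelFreeParams(1.0, 10.0))
    assert R2 / R1 > 10.0


def test_forward_rates_agree_with_brute_force_sums():
    # independent literal evaluation of the dipolar + CSA sums
    p = ModelFreeParams(0.85, 7.0, tau_e=50.0)
    d2, c2 = CONST.d**2, CONST.c**2
    wh, wn = CONST.omega_h, CONST.omega_n

    def J(w):
        return float(model_free_J(p, abs(w)))

    R1 = d2 / 4 * (J(wh - wn) + 3 * J(wn) + 6 * J(wh + wn)) + c2 * J(wn)
    R2 = d2 / 8 * (4 * J(0) + J(wh - wn) + 3 * J(wn) + 6 * J(wh) + 6 * J(wh + wn)) \
        + c2 / 6 * (4 * J(0) + 3 * J(wn))
    got = forward_rates(p)
    assert got[0] == pytest.approx(R1, rel=1e-12)
    assert got[1] == pytest.approx(R2, rel=1e-12)


@pytest.mark.parametrize("S2", [0.3, 0.5, 0.8, 1.0])
@pytest.mark.parametrize("tau_m", [1.0, 5.0, 15.0])
def test_reduced_mapping_round_trip_within_2pct(S2, tau_m):
    p = ModelFreeParams(S2, tau_m, tau_e=50.0)
    R1, R2, NOE = forward_rates(p)
    tri = reduced_mapping(RelaxationRecord(1, R1, R2, NOE))
    J0 = float(model_free_J(p, 0.0))
    JwN = float(model_free_J(p, abs(CONST.omega_n)))
    assert tri.J0 == pytest.approx(J0, rel=0.02)
    assert tri.JwN == pytest.approx(JwN, rel=0.02)


def test_unit_noe_gives_zero_high_frequency_density():
    tri = reduced_mapping(RelaxationRecord(1, 1.5, 8.0, 1.0))
    assert tri.JwH_eff == 0.0


def test_exchange_broadening_elevates_j0_not_jwn():
    p = ModelFreeParams(0.8, 5.0)
    R1, R2, NOE = forward_rates(p)
    plain = reduced_mapping(RelaxationRecord(1, R1, R2, NOE))
    broadened = reduced_mapping(RelaxationRecord(2, R1, R2 + 5.0, NOE))
    assert broadened.J0 > 1.5 * plain.J0
    assert broadened.JwN == pytest.approx(plain.JwN, rel=1e-9)


def test_order_parameter_curves_do_not_cross():
    tm = np.linspace(1.0, 20.0, 60)
    J0_a, JwN_a = order_parameter_curve(0.7, tm)
    J0_b, JwN_b = order_parameter_curve(0.8, tm)
    # at matched J0, the higher-S2 curve has strictly different JwN
    for j0, jn in zip(J0_a, JwN_a):
        jn_b = np.interp(j0, J0_b, JwN_b)
        if J0_b[0] <= j0 <= J0_b[-1]:
            assert abs(jn_b - jn) > 0


def test_generated_points_lie_on_their_order_parameter_curve():
    tm_grid = np.linspace(1.0, 20.0, 200)
    J0_curve, JwN_curve = order_parameter_curve(0.8, tm_grid, tau_e=50.0)
    for tm in (3.0, 7.0, 12.0):
        p = ModelFreeParams(0.8, tm, tau_e=50.0)
        j0 = float(model_free_J(p, 0.0))
        jn = float(model_free_J(p, abs(CONST.omega_n)))
        assert np.interp(j0, J0_curve, JwN_curve) == pytest.approx(jn, rel=1e-3)


def test_flat_profile_selects_no_components(rng):
    res = np.arange(1, 81)
    flat = 1.4 + rng.normal(0, 0.05, 80)
    prof = fit_t1t2_profile(res, flat)
    assert prof.n_components <= 1


def test_two_seeded_clusters_recovered_within_2_residues(rng):
    res = np.arange(1, 101)
    y = 1.5 + 3.0 * np.exp(-0.5 * ((res - 30) / 5) ** 2) \
        + 2.0 * np.exp(-0.5 * ((res - 70) / 6) ** 2) + rng.normal(0, 0.1, 100)
    prof = fit_t1t2_profile(res, y)
    assert prof.n_components == 2
    centers = np.sort(prof.centers)
    assert centers[0] == pytest.approx(30, abs=2)
    assert centers[1] == pytest.approx(70, abs=2)


def test_noiseless_single_gaussian_exact():
    res = np.arange(1, 101)
    y = 1.0 + 2.5 * np.exp(-0.5 * ((res - 50) / 8.0) ** 2)
    prof = fit_t1t2_profile(res, y, n_gaussians=1)
    assert prof.baseline == pytest.approx(1.0, abs=1e-6)
    assert prof.centers[0] == pytest.approx(50.0, abs=1e-6)
    assert prof.widths[0] == pytest.approx(8.0, abs=1e-5)
    assert prof.amplitudes[0] == pytest.approx(2.5, abs=1e-6)


def _linear_like(seed):
    params = [ModelFreeParams(0.55, 3.0, tau_e=80.0) for _ in range(80)]
    return synthdata.gen_relaxation_table(params, noise_sd=0.02, seed=seed)


def _cyclized_like(seed):
    # clusters of exchange-broadened residues raise R2 locally
    params = []
    for i in range(80):
        in_cluster = (20 <= i < 30) or (55 <= i < 65)
        params.append(
            ModelFreeParams(0.55, 3.0, tau_e=80.0, R_ex=4.0 if in_cluster else 0.0)
        )
    return synthdata.gen_relaxation_table(params, noise_sd=0.02, seed=seed)


def test_cyclized_like_dataset_has_lower_mean_t2_and_clustered_profile():
    lin = _linear_like(1)
    cyc = _cyclized_like(1)
    assert mean_T2(cyc) < mean_T2(lin)
    res = np.array([r.residue for r in cyc])
    t1t2_cyc = np.array([r.T1 / r.T2 for r in cyc])
    t1t2_lin = np.array([r.T1 / r.T2 for r in lin])
    prof_cyc = fit_t1t2_profile(res, t1t2_cyc)
    prof_lin = fit_t1t2_profile(res, t1t2_lin)
    assert prof_cyc.n_components >= 2
    assert prof_lin.n_components <= 1
    assert t1t2_cyc.std() > 2.0 * t1t2_lin.std()


def test_nonphysical_model_free_params_rejected():
    with pytest.raises(ValueError):
        ModelFreeParams(1.2, 5.0)
    with pytest.raises(ValueError):
        ModelFreeParams(0.5, -1.0)
    with pytest.raises(ValueError):
        RelaxationRecord(1, -0.5, 5.0, 0.7)
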