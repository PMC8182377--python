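"""Three-state equilibrium analysis: populations, SVD rank, model fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from knotfold import equilibrium, synthdata
from knotfold.constants import R_KCAL, T_DEFAULT
from knotfold.equilibrium import (
    SignalLoss,
    ThreeStateModel,
    fit_equilibrium,
    populations,
    svd_rank,
    transition_midpoints,
)


def brute_force_populations(model, D):
    """Oracle: Boltzmann weights over the three state free energies."""
    RT = R_KCAL * model.T
    G = np.array(
        [0.0, model.dG1 - model.m1 * D, model.dG1 + model.dG2 - (model.m1 + model.m2) * D]
    )
    w = np.exp(-(G - G.min()) / RT)
    return w / w.sum()


@given(
    dG1=st.floats(0.5, 12.0),
    m1=st.floats(0.3, 4.0),
    dG2=st.floats(0.5, 12.0),
    m2=st.floats(0.3, 4.0),
    D=st.floats(0.0, 9.0),
)
@settings(max_examples=100, deadline=None)
def test_populations_match_partition_function_oracle(dG1, m1, dG2, m2, D):
    model = ThreeStateModel(dG1, m1, dG2, m2)
    got = np.array([p.item() for p in populations(model, D)])
    np.testing.assert_allclose(got, brute_force_populations(model, D), atol=1e-10)
    assert got.sum() == pytest.approx(1.0, abs=1e-12)


def test_first_midpoint_splits_native_and_intermediate():
    model = ThreeStateModel(3.0, 1.5, 25.0, 1.0)
    fN, fI, fD = populations(model, 3.0 / 1.5)
    assert fN == pytest.approx(0.5, abs=1e-9)
    assert fI == pytest.approx(0.5, abs=1e-9)


def test_native_dominates_in_water():
    model = ThreeStateModel(8.0, 2.0, 8.0, 2.0)
    fN, _, _ = populations(model, 0.0)
    assert fN > 0.999


def test_fraction_denatured_monotone_in_denaturant(three_state_model):
    D = np.linspace(0, 9, 200)
    _, _, fD = populations(three_state_model, D)
    assert np.all(np.diff(fD) >= -1e-12)


def test_transition_midpoints_quotient():
    model = ThreeStateModel(3.0, 1.5, 8.95, 3.06)
    d1, d2 = transition_midpoints(model)
    assert d1 == pytest.approx(2.0)
    assert d2 == pytest.approx(2.9248, abs=5e-4)


def test_second_midpoint_matches_steepest_denatured_growth(three_state_model):
    # well-separated transitions: argmax d f_D / dD sits at dG2/m2
    D = np.linspace(0, 9, 2001)
    _, _, fD = populations(three_state_model, D)
    d_mid = D[np.argmax(np.gradient(fD, D))]
    assert d_mid == pytest.approx(three_state_model.dG2 / three_state_model.m2, abs=0.05)


def test_svd_rank_three_state_noiseless(three_state_model):
    s = synthdata.gen_denaturation_series(three_state_model, noise_sd=0.0)
    assert svd_rank(s).rank == 3


def test_svd_rank_single_state():
    model = ThreeStateModel(25.0, 0.5, 25.0, 0.5)
    s = synthdata.gen_denaturation_series(model, noise_sd=0.0)
    assert svd_rank(s).rank == 1


def test_svd_rank_robust_to_one_percent_noise(three_state_model):
    s0 = synthdata.gen_denaturation_series(three_state_model, noise_sd=0.0)
    noise = 0.01 * s0.matrix.max()
    s = synthdata.gen_denaturation_series(three_state_model, noise_sd=noise, seed=3)
    assert svd_rank(s).rank == 3


def test_svd_rejects_all_zero_matrix():
    s = equilibrium.SpectralSeries(
        np.arange(5.0), np.arange(4.0), np.zeros((5, 4))
    )
    with pytest.raises(ValueError):
        svd_rank(s)


def test_svd_truncation_residual_below_noise_floor(three_state_model):
    noise = 0.01
    s = synthdata.gen_denaturation_series(three_state_model, noise_sd=noise, seed=9)
    res = svd_rank(s)
    U, sv, Vt = np.linalg.svd(s.matrix, full_matrices=False)
    approx = (U[:, :3] * sv[:3]) @ Vt[:3]
    rms = np.sqrt(np.mean((s.matrix - approx) ** 2))
    assert rms <= 1.5 * noise


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_parameter_recovery_within_10pct_at_1pct_noise(three_state_model, seed):
    s = synthdata.gen_denaturation_series(three_state_model, noise_sd=0.01, seed=seed)
    fit = fit_equilibrium(s, n_states=3)
    truth = s.meta["truth"].params
    for name in ("dG1", "m1", "dG2", "m2"):
        assert getattr(fit.model, name) == pytest.approx(truth[name], rel=0.10)


def test_clean_series_fits_loss_amplitude_near_zero(denaturation_series):
    fit = fit_equilibrium(denaturation_series, n_states=3, loss="auto")
    assert fit.loss is not None and fit.loss.amplitude < 0.05


def test_signal_loss_window_detected_when_present(three_state_model):
    loss = SignalLoss(0.5, 2.5, 0.4)
    s = synthdata.gen_denaturation_series(
        three_state_model, loss=loss, noise_sd=0.01, seed=2
    )
    fit = fit_equilibrium(s, n_states=3, loss="auto")
    assert fit.loss.amplitude == pytest.approx(0.5, abs=0.15)
    assert fit.loss.center == pytest.approx(2.5, abs=0.5)
    assert np.any(fit.aggregated > 0.2)


def test_two_state_fit_equals_degenerate_three_state():
    # genuinely two-state data: second transition unreachable
    model = ThreeStateModel(4.0, 2.0, 28.0, 0.5)
    wl = np.arange(300.0, 451.0, 2.0)
    basis = synthdata.default_basis_spectra(wl, 2)
    s = synthdata.gen_denaturation_series(
        model, basis_spectra=basis, wavelengths=wl, noise_sd=0.005, seed=4
    )
    f2 = fit_equilibrium(s, n_states=2)
    # warm-start the richer model from the nested solution: with a truly
    # two-state series the intermediate must stay unpopulated
    f3 = fit_equilibrium(
        s, n_states=3,
        init={"dG1": f2.model.dG1, "m1": f2.model.m1, "dG2": 25.0, "m2": 0.5},
    )
    assert f2.model.dG1 == pytest.approx(f3.model.dG1, rel=0.05)
    assert f2.model.m1 == pytest.approx(f3.model.m1, rel=0.05)
    # the third state never becomes populated in the 3-state fit
    assert f3.populations[2].max() < 1e-3


def test_population_rows_of_fit_sum_to_one(denaturation_series):
    fit = fit_equilibrium(denaturation_series, n_states=3)
    np.testing.assert_allclose(fit.populations.sum(axis=0), 1.0, atol=1e-12)


def test_invalid_model_rejected():
    with pytest.raises(ValueError):
        ThreeStateModel(3.0, -1.0, 8.0, 2.0)
    with pytest.raises(ValueError):
        SignalLoss(1.5, 2.0, 0.5)
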