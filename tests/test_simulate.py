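"""Synthetic-data generator: reproducibility and distributional fidelity."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from msocc import (
    MISSING,
    SimulationConfig,
    default_coefficients,
    recovery_study,
    simulate,
    transition_row,
)
from msocc.fit import OptimizerOptions


def test_same_seed_bit_identical():
    a = simulate(SimulationConfig(n_sites=30, n_seasons=3, seed=9))
    b = simulate(SimulationConfig(n_sites=30, n_seasons=3, seed=9))
    np.testing.assert_array_equal(a.data.observations, b.data.observations)
    np.testing.assert_array_equal(a.latent_states, b.latent_states)
    assert a.data.covariates.equals(b.data.covariates)


def test_different_seed_differs():
    a = simulate(SimulationConfig(n_sites=30, n_seasons=3, seed=9))
    c = simulate(SimulationConfig(n_sites=30, n_seasons=3, seed=10))
    assert not np.array_equal(a.data.observations, c.data.observations)


def test_zero_occupancy_coefficients_yield_all_zero():
    coefs = {"psi1:(intercept)": -50.0, "psi:(intercept)": -50.0,
             "psi:state[1]": 0.0, "psi:state[2]": 0.0}
    sim = simulate(
        SimulationConfig(n_sites=25, n_seasons=4, coefficients=coefs,
                         missing_rate=0.0, seed=1)
    )
    assert (sim.latent_states == 0).all()
    assert (sim.data.observations == 0).all()


def test_certain_occupancy_and_detection_forced_pattern():
    """ψ = R = p = δ = 1 (δ1 = 0 kept): survey 1 reads 1, surveys 2+ read 2."""
    coefs = {
        "psi1:(intercept)": 50.0, "r1:(intercept)": 50.0,
        "psi:(intercept)": 50.0, "psi:state[1]": 0.0, "psi:state[2]": 0.0,
        "r:(intercept)": 50.0, "r:state[1]": 0.0, "r:state[2]": 0.0,
    }
    for j in range(1, 5):
        coefs[f"p1[{j}]"] = coefs[f"p2[{j}]"] = 50.0
    for j in range(2, 5):
        coefs[f"delta[{j}]"] = 50.0
    sim = simulate(
        SimulationConfig(n_sites=20, n_seasons=3, coefficients=coefs,
                         missing_rate=0.0, seed=2)
    )
    assert (sim.latent_states == 2).all()
    assert (sim.data.observations[:, :, 0] == 1).all()
    assert (sim.data.observations[:, :, 1:] == 2).all()


def test_first_season_occupancy_binomial_concentration():
    """At 10,000 sites the occupied fraction concentrates on ψ1 = 0.53."""
    coefs = default_coefficients(SimulationConfig().spec)
    coefs["psi1:(intercept)"] = float(np.log(0.53 / 0.47))
    sim = simulate(
        SimulationConfig(n_sites=10_000, n_seasons=1, coefficients=coefs, seed=3)
    )
    frac = float((sim.latent_states[:, 0] > 0).mean())
    assert abs(frac - 0.53) < 3 * np.sqrt(0.53 * 0.47 / 10_000)


def test_latent_transitions_match_transition_rows():
    """Empirical transition frequencies agree with the generating rows
    (chi-square test per previous state at n = 10,000)."""
    sim = simulate(SimulationConfig(n_sites=10_000, n_seasons=2, missing_rate=0.0, seed=4))
    from msocc.likelihood import site_parameters

    pars = site_parameters(sim.truth, sim.design)
    prev, nxt = sim.latent_states[:, 0], sim.latent_states[:, 1]
    for m in (0, 1, 2):
        sel = prev == m
        if sel.sum() < 50:
            continue
        counts = np.bincount(nxt[sel], minlength=3)
        # covariate-free ψ model: every site shares the same row
        expected_row = np.stack(
            [1 - pars["psi"][sel, 0, m],
             pars["psi"][sel, 0, m] * (1 - pars["r"][sel, 0, m]),
             pars["psi"][sel, 0, m] * pars["r"][sel, 0, m]], axis=-1
        ).mean(axis=0)
        p = stats.chisquare(counts, expected_row * sel.sum()).pvalue
        assert p > 1e-4


def test_observation_frequencies_match_observation_model():
    """Conditional observation frequencies converge to the two-level
    detection probabilities."""
    sim = simulate(SimulationConfig(n_sites=10_000, n_seasons=1, missing_rate=0.0, seed=6))
    from msocc.likelihood import site_parameters

    pars = site_parameters(sim.truth, sim.design)
    obs, states = sim.data.observations[:, 0, :], sim.latent_states[:, 0]
    s2 = states == 2
    for j in range(4):
        o = obs[s2, j]
        p2, d = pars["p2"][j], pars["delta"][j]
        n = len(o)
        se = np.sqrt(p2 * (1 - p2) / n)
        assert abs((o > 0).mean() - p2) < 4 * se + 1e-9
        assert abs((o == 2).mean() - p2 * d) < 4 * np.sqrt(p2 * d * (1 - p2 * d) / n) + 1e-9
    s1 = states == 1
    for j in range(4):
        p1 = pars["p1"][j]
        assert abs((obs[s1, j] == 1).mean() - p1) < 4 * np.sqrt(p1 * (1 - p1) / s1.sum())


def test_missingness_respects_rate_and_contract():
    sim = simulate(SimulationConfig(n_sites=500, n_seasons=3, missing_rate=0.2, seed=7))
    frac = float((sim.data.observations == MISSING).mean())
    assert abs(frac - 0.2) < 0.02
    # every site keeps at least one non-missing survey (data contract)
    assert not (sim.data.observations == MISSING).all(axis=(1, 2)).any()


def test_observations_consistent_with_latent_states():
    """No-false-positive rule: codes never exceed what the state permits."""
    sim = simulate(SimulationConfig(n_sites=200, n_seasons=4, seed=8))
    obs, states = sim.data.observations, sim.latent_states
    assert (obs[states == 0] <= 0).all()  # only 0 or MISSING
    assert (obs[states == 1] <= 1).all()


def test_recovery_study_report_shape():
    cfg = SimulationConfig(n_sites=40, n_seasons=3, seed=13)
    rep = recovery_study(cfg, n_replicates=2, options=OptimizerOptions(n_random_starts=0))
    k = rep.estimates["coefficient"].nunique()
    assert len(rep.estimates) == 2 * k
    assert set(rep.summary.columns) >= {"coefficient", "bias", "rmse", "coverage"}
    assert rep.n_replicates == 2


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_sites=0)
    with pytest.raises(ValueError):
        SimulationConfig(missing_rate=1.0)
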