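"""Hidden-Markov likelihood: observation model, transitions, forward pass."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from msocc import (
    MISSING,
    DomainError,
    SeasonParameters,
    observation_prob,
    site_loglik,
    total_negloglik,
    transition_row,
)
from msocc import SimulationConfig, build_design, simulate, truth_vector
from msocc.data import DetectionHistorySet


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "state, obs, p1, p2, delta, expected",
    [
        (0, 0, 0.3, 0.4, 0.5, 1.0),
        (0, 1, 0.3, 0.4, 0.5, 0.0),
        (1, 2, 0.3, 0.4, 0.5, 0.0),  # no false-positive evidence
        (1, 1, 0.3, 0.4, 0.5, 0.3),
        (2, 2, 0.5, 0.96, 0.93, 0.8928),
        (2, 1, 0.5, 0.70, 0.0, 0.70),  # detected without evidence when δ=0
        (1, MISSING, 0.3, 0.4, 0.5, 1.0),
    ],
)
def test_observation_prob_cases(state, obs, p1, p2, delta, expected):
    assert observation_prob(state, obs, p1, p2, delta) == pytest.approx(expected)


def test_observation_prob_rejects_bad_probability():
    with pytest.raises(DomainError):
        observation_prob(1, 1, 1.3, 0.5, 0.5)


@given(
    state=st.integers(0, 2),
    p1=st.floats(0, 1),
    p2=st.floats(0, 1),
    delta=st.floats(0, 1),
)
@settings(deadline=None, derandomize=True)
def test_observation_prob_sums_to_one(state, p1, p2, delta):
    total = sum(observation_prob(state, o, p1, p2, delta) for o in (0, 1, 2))
    assert total == pytest.approx(1.0, abs=1e-12)


@given(psi=st.floats(0, 1), r=st.floats(0, 1), m=st.integers(0, 2))
@settings(deadline=None, derandomize=True)
def test_transition_row_is_a_distribution(psi, r, m):
    row = transition_row(m, psi, r)
    assert row.min() >= 0.0
    assert row.sum() == pytest.approx(1.0, abs=1e-12)


def test_transition_row_cases():
    np.testing.assert_allclose(transition_row(0, 0.0, 0.7), [1, 0, 0])
    np.testing.assert_allclose(transition_row(1, 1.0, 1.0), [0, 0, 1])
    np.testing.assert_allclose(transition_row(2, 0.98, 0.9), [0.02, 0.098, 0.882])


# ---------------------------------------------------------------------------
# forward algorithm vs independent enumeration
# ---------------------------------------------------------------------------

def brute_force_loglik(params: SeasonParameters, history: np.ndarray) -> float:
    """Independent oracle: sum the likelihood over all latent state paths."""
    history = np.atleast_2d(history)
    T, J = history.shape
    init = {
        0: 1 - params.psi1,
        1: params.psi1 * (1 - params.r1),
        2: params.psi1 * params.r1,
    }
    total = 0.0
    for seq in itertools.product(range(3), repeat=T):
        pr = init[seq[0]]
        for t in range(1, T):
            m = seq[t - 1]
            pr *= transition_row(m, params.psi[t - 1, m], params.r[t - 1, m])[seq[t]]
        for t in range(T):
            for j in range(J):
                pr *= observation_prob(
                    seq[t], history[t, j], params.p1[j], params.p2[j], params.delta[j]
                )
        total += pr
    return float(np.log(total)) if total > 0 else float("-inf")


def random_case(rng: np.random.Generator, max_seasons: int = 5):
    T = int(rng.integers(1, max_seasons + 1))
    J = int(rng.integers(1, 5))
    params = SeasonParameters(
        psi1=rng.random(),
        r1=rng.random(),
        psi=rng.random((max(T - 1, 1), 3)),
        r=rng.random((max(T - 1, 1), 3)),
        p1=rng.random(J),
        p2=rng.random(J),
        delta=np.concatenate([[0.0], rng.random(J - 1)]),
    )
    history = rng.integers(-1, 3, size=(T, J))
    return params, history


def test_site_loglik_hand_enumeration():
    """1 season, 1 survey, obs 0: 0.5 + 0.25*0.25 + 0.25*0.25 = 0.625."""
    p = SeasonParameters(
        psi1=0.5, r1=0.5, psi=np.zeros((0, 3)), r=np.zeros((0, 3)),
        p1=[0.75], p2=[0.75], delta=[0.0],
    )
    assert np.exp(site_loglik(p, np.array([[0]]))) == pytest.approx(0.625)


def test_all_missing_history_is_uninformative():
    p = SeasonParameters(
        psi1=0.3, r1=0.6, psi=np.full((2, 3), 0.5), r=np.full((2, 3), 0.5),
        p1=[0.5, 0.5], p2=[0.5, 0.5], delta=[0.0, 0.5],
    )
    hist = np.full((3, 2), MISSING)
    assert site_loglik(p, hist) == pytest.approx(0.0, abs=1e-14)


def test_forward_equals_enumeration_random_cases():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        params, history = random_case(rng)
        a = site_loglik(params, history)
        b = brute_force_loglik(params, history)
        if np.isinf(b):
            assert np.isinf(a)
        else:
            assert a == pytest.approx(b, abs=1e-10)


def test_impossible_history_is_minus_infinity():
    """Evidence code at the first survey is impossible since δ1 = 0."""
    p = SeasonParameters(
        psi1=0.9, r1=0.9, psi=np.zeros((0, 3)), r=np.zeros((0, 3)),
        p1=[0.5], p2=[0.5], delta=[0.0],
    )
    assert site_loglik(p, np.array([[2]])) == float("-inf")


def test_perfect_detection_reduces_to_transition_product():
    """With p = 1 and δ2..J = 1, a consistent fully observed history has
    exactly the probability of its latent path."""
    psi = np.array([[0.4, 0.7, 0.9], [0.5, 0.8, 0.95]])
    r = np.array([[0.2, 0.5, 0.8], [0.3, 0.6, 0.85]])
    p = SeasonParameters(
        psi1=0.6, r1=0.5, psi=psi, r=r,
        p1=np.ones(3), p2=np.ones(3), delta=np.array([0.0, 1.0, 1.0]),
    )
    # latent path 2 -> 1 -> 2 ; state-2 seasons read (1, 2, 2), state-1 (1, 1, 1)
    hist = np.array([[1, 2, 2], [1, 1, 1], [1, 2, 2]])
    expected = (
        0.6 * 0.5                       # start in state 2
        * psi[0, 2] * (1 - r[0, 2])     # to state 1
        * psi[1, 1] * r[1, 1]           # to state 2
    )
    assert site_loglik(p, hist) == pytest.approx(np.log(expected), abs=1e-12)


def test_survey_order_invariance_within_season():
    """Permuting surveys 2..J together with their detection parameters
    leaves the likelihood unchanged (survey 1 is pinned by δ1 = 0)."""
    rng = np.random.default_rng(77)
    params, history = random_case(rng)
    J = history.shape[1]
    if J < 3:
        params, history = random_case(np.random.default_rng(78))
        J = history.shape[1]
    perm = np.concatenate([[0], 1 + np.random.default_rng(1).permutation(J - 1)])
    permuted = SeasonParameters(
        psi1=params.psi1, r1=params.r1, psi=params.psi, r=params.r,
        p1=params.p1[perm], p2=params.p2[perm], delta=params.delta[perm],
    )
    a = site_loglik(params, history)
    b = site_loglik(permuted, history[:, perm])
    if np.isinf(a):
        assert np.isinf(b)
    else:
        assert a == pytest.approx(b, abs=1e-12)


def test_doubling_dataset_doubles_negloglik(small_sim):
    data = small_sim.data
    design = build_design(small_sim.design.spec, data)
    theta = truth_vector(design, None)
    single = total_negloglik(theta, design, data)
    cov = data.covariates.loc[data.site_ids]
    doubled = DetectionHistorySet(
        site_ids=data.site_ids + [s + "_b" for s in data.site_ids],
        observations=np.concatenate([data.observations] * 2),
        covariates=pd.concat(
            [cov, cov.set_axis([s + "_b" for s in data.site_ids], axis=0)]
        ),
    )
    d2 = build_design(design.spec, doubled)
    assert total_negloglik(theta, d2, doubled) == pytest.approx(2 * single, rel=1e-12)


def test_non_finite_theta_rejected(small_sim):
    theta = truth_vector(small_sim.design, None)
    theta[0] = np.nan
    with pytest.raises(DomainError):
        total_negloglik(theta, small_sim.design, small_sim.data)
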