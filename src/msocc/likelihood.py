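"""Multi-season multi-state occupancy likelihood (forward algorithm).

The latent state of a territory in season t is one of

* 0 — unoccupied,
* 1 — occupied without successful reproduction,
* 2 — occupied with successful reproduction,

and is assumed constant within a season (closure).  Between seasons the
state follows a Markov chain whose row for previous state m is

    (1 - psi[m],  psi[m] * (1 - R[m]),  psi[m] * R[m])

with psi[m] the occupancy probability given previous state m and R[m]
the success probability given occupancy.  Within a season each survey j
yields an observation with no false positives:

    true 0:  obs 0 with prob 1
    true 1:  obs 1 w.p. p1[j], obs 0 otherwise
    true 2:  obs 2 w.p. p2[j]*delta[j], obs 1 w.p. p2[j]*(1-delta[j]),
             obs 0 w.p. 1-p2[j]

delta[0] (first survey) is structurally zero: evidence of reproduction
cannot be assessed that early in the breeding cycle.  A missing survey
contributes a factor of 1 for every state.  The site likelihood is
computed by the forward algorithm with per-season rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MISSING, DetectionHistorySet
from .design import DesignSet

try:  # scipy.special.expit is the numerically safe inverse logit
    from scipy.special import expit
except ImportError:  # pragma: no cover
    def expit(x):
        return 1.0 / (1.0 + np.exp(-x))


class DomainError(ValueError):
    """Raised when a probability argument falls outside [0, 1]."""


def _check_prob(*vals: float) -> None:
    for v in vals:
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"probability {v} outside [0, 1]")


def observation_prob(
    true_state: int, observed: int, p1_j: float, p2_j: float, delta_j: float
) -> float:
    """P(observed code | latent state) for a single survey.

    ``observed == MISSING`` returns 1 for every state (no information).
    """
    _check_prob(p1_j, p2_j, delta_j)
    if observed == MISSING:
        return 1.0
    if true_state == 0:
        return 1.0 if observed == 0 else 0.0
    if true_state == 1:
        return {0: 1.0 - p1_j, 1: p1_j, 2: 0.0}[observed]
    if true_state == 2:
        return {
            0: 1.0 - p2_j,
            1: p2_j * (1.0 - delta_j),
            2: p2_j * delta_j,
        }[observed]
    raise DomainError(f"unknown latent state {true_state}")


def transition_row(prev_state: int, psi_m: float, r_m: float) -> np.ndarray:
    """State distribution next season given previous state m."""
    del prev_state  # row depends on m only through psi_m / r_m
    _check_prob(psi_m, r_m)
    return np.array([1.0 - psi_m, psi_m * (1.0 - r_m), psi_m * r_m])


@dataclass
class SeasonParameters:
    """Real-scale parameters for one site across all seasons.

    ``psi`` and ``r`` have shape (n_transitions, 3): row t-1 gives the
    season t values conditional on each previous state m = 0, 1, 2.
    ``delta`` has its first entry structurally zero.
    """

    psi1: float
    r1: float
    psi: np.ndarray
    r: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        self.r = np.atleast_2d(np.asarray(self.r, dtype=float))
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        for arr in (self.psi, self.r, self.p1, self.p2, self.delta):
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise DomainError("parameter outside [0, 1]")
        _check_prob(self.psi1, self.r1)
        if self.delta[0] != 0.0:
            raise DomainError("delta for the first survey is structurally 0")


def _seasonal_state_likelihoods(
    obs: np.ndarray, p1: np.ndarray, p2: np.ndarray, delta: np.ndarray
) -> np.ndarray:
    """P(season's surveys | state) for every (site, season, state).

    obs: (n_sites, n_seasons, n_surveys) codes; returns (n, T, 3).
    """
    p1 = p1.reshape(1, 1, -1)
    p2 = p2.reshape(1, 1, -1)
    delta = delta.reshape(1, 1, -1)
    miss = obs == MISSING
    f0 = np.where(miss | (obs == 0), 1.0, 0.0)
    f1 = np.where(
        miss, 1.0, np.where(obs == 0, 1.0 - p1, np.where(obs == 1, p1, 0.0))
    )
    f2 = np.where(
        miss,
        1.0,
        np.where(obs == 0, 1.0 - p2, np.where(obs == 1, p2 * (1.0 - delta), p2 * delta)),
    )
    return np.stack([f0.prod(axis=2), f1.prod(axis=2), f2.prod(axis=2)], axis=-1)


def _forward_logliks(
    obs: np.ndarray,
    psi1: np.ndarray,
    r1: np.ndarray,
    psi: np.ndarray,
    r: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    delta: np.ndarray,
) -> np.ndarray:
    """Per-site log-likelihoods, vectorized over sites.

    psi1, r1: (n,); psi, r: (n, T-1, 3); p1, p2, delta: (J,).
    """
    n, T, _ = obs.shape
    O = _seasonal_state_likelihoods(obs, p1, p2, delta)
    alpha = np.stack([1.0 - psi1, psi1 * (1.0 - r1), psi1 * r1], axis=-1) * O[:, 0, :]
    loglik = np.zeros(n)
    dead = np.zeros(n, dtype=bool)
    for t in range(T):
        if t > 0:
            # transition tensor rows: prev state m -> next state distribution
            ps, rr = psi[:, t - 1, :], r[:, t - 1, :]
            trans = np.stack(
                [1.0 - ps, ps * (1.0 - rr), ps * rr], axis=-1
            )  # (n, m, next)
            alpha = np.einsum("nm,nms->ns", alpha, trans) * O[:, t, :]
        c = alpha.sum(axis=1)
        zero = c <= 0.0
        dead |= zero
        c_safe = np.where(zero, 1.0, c)
        loglik += np.log(c_safe)
        alpha = alpha / c_safe[:, None]
    loglik[dead] = -np.inf
    return loglik


def site_loglik(params: SeasonParameters, history: np.ndarray) -> float:
    """Log-likelihood of one site's observation history.

    ``history`` is a (n_seasons, n_surveys) array of codes 0/1/2 or
    :data:`MISSING`.  A history impossible under the no-false-positive
    structure returns ``-inf``; an all-missing history returns 0.
    """
    history = np.atleast_2d(np.asarray(history, dtype=np.int64))
    T = history.shape[0]
    psi = np.broadcast_to(params.psi, (T - 1, 3)) if T > 1 else np.zeros((0, 3))
    r = np.broadcast_to(params.r, (T - 1, 3)) if T > 1 else np.zeros((0, 3))
    return float(
        _forward_logliks(
            history[None],
            np.array([params.psi1]),
            np.array([params.r1]),
            np.asarray(psi)[None],
            np.asarray(r)[None],
            params.p1,
            params.p2,
            params.delta,
        )[0]
    )


def site_parameters(theta: np.ndarray, design: DesignSet) -> dict[str, np.ndarray]:
    """Map logit-scale coefficients to real-scale parameter arrays.

    Returns psi1, r1 of shape (n_sites,); psi, r of shape
    (n_sites, n_transitions, 3); p1, p2, delta of shape (n_surveys,)
    with delta[0] = 0.
    """
    parts = design.split(theta)
    n, n_tr = design.n_sites, design.n_transitions
    psi = expit(design.X_psi @ parts["psi"]).reshape(n, n_tr, 3)
    r = expit(design.X_r @ parts["r"]).reshape(n, n_tr, 3)
    return {
        "psi1": expit(design.X_psi1 @ parts["psi1"]),
        "r1": expit(design.X_r1 @ parts["r1"]),
        "psi": psi,
        "r": r,
        "p1": expit(parts["p1"]),
        "p2": expit(parts["p2"]),
        "delta": np.concatenate([[0.0], expit(parts["delta"])]),
    }


def total_loglik(
    theta: np.ndarray, design: DesignSet, data: DetectionHistorySet
) -> float:
    """Total log-likelihood of the dataset at coefficient vector theta."""
    theta = np.asarray(theta, dtype=float)
    if not np.isfinite(theta).all():
        raise DomainError("non-finite coefficient vector")
    p = site_parameters(theta, design)
    ll = _forward_logliks(
        data.observations,
        p["psi1"],
        p["r1"],
        p["psi"],
        p["r"],
        p["p1"],
        p["p2"],
        p["delta"],
    )
    return float(ll.sum())


def total_negloglik(
    theta: np.ndarray, design: DesignSet, data: DetectionHistorySet
) -> float:
    """Negative total log-likelihood (the optimizer objective)."""
    return -total_loglik(theta, design, data)
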