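"""Maximum-likelihood estimation and real-scale derived estimates.

Coefficients live on the logit scale, so the optimization is
unconstrained.  The likelihood surface of multi-state occupancy models
can be multimodal, so fitting runs from several starting points (a zero
start plus random draws) and keeps the best optimum.  Standard errors
come from the inverse of a central-finite-difference Hessian at the MLE;
real-scale probabilities and their confidence intervals use the delta
method on the logit scale with a Wald interval back-transformed through
the inverse logit, which keeps intervals inside [0, 1] and reproduces
the asymmetry expected near the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .data import DetectionHistorySet
from .design import DesignSet, ModelSpec, SpecError, build_design
from .likelihood import site_parameters, total_negloglik

Z95 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass(frozen=True)
class OptimizerOptions:
    """Settings for the multi-start quasi-Newton maximization."""

    n_random_starts: int = 10
    start_scale: float = 2.0  # random starts ~ U(-scale, scale)
    seed: int = 20170411
    ftol: float = 1e-10
    maxiter: int = 2000
    hessian_step: float = 1e-5


@dataclass
class FitResult:
    """A fitted model: MLE, information-criterion quantities, curvature."""

    spec: ModelSpec
    design: DesignSet
    mle: np.ndarray
    neg_loglik: float
    vcov: np.ndarray | None
    converged: bool
    n_starts_used: int
    boundary: bool = False

    @property
    def K(self) -> int:
        return self.design.K

    @property
    def deviance(self) -> float:
        return 2.0 * self.neg_loglik

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.K

    @property
    def label(self) -> str:
        return self.spec.label

    def coefficients(self) -> pd.DataFrame:
        se = (
            np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))
            if self.vcov is not None
            else np.full(self.K, np.nan)
        )
        return pd.DataFrame(
            {"coefficient": self.design.names, "estimate": self.mle, "se": se}
        )

    def coef(self, name: str) -> float:
        return float(self.mle[self.design.names.index(name)])

    def coef_se(self, name: str) -> float:
        if self.vcov is None:
            return float("nan")
        i = self.design.names.index(name)
        return float(np.sqrt(max(self.vcov[i, i], 0.0)))

    def to_report(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# model: {self.label}\n")
            fh.write(
                f"# K={self.K} AIC={self.aic:.4f} deviance={self.deviance:.4f} "
                f"converged={self.converged}\n"
            )
            self.coefficients().to_csv(fh, index=False)


@dataclass(frozen=True)
class RealEstimate:
    """A probability on the real scale with delta-method uncertainty."""

    label: str
    point: float
    se: float
    ci_low: float
    ci_high: float
    boundary: bool = False

    @staticmethod
    def from_logit(label: str, eta: float, se_eta: float) -> "RealEstimate":
        p = float(expit(eta))
        se_p = se_eta * p * (1.0 - p)  # delta method
        lo = float(expit(eta - Z95 * se_eta))
        hi = float(expit(eta + Z95 * se_eta))
        boundary = p < 1e-6 or p > 1.0 - 1e-6
        return RealEstimate(label, p, se_p, lo, hi, boundary)


def _numeric_hessian(
    f: Callable[[np.ndarray], float], x: np.ndarray, step: float
) -> np.ndarray:
    """Central-finite-difference Hessian (O(step^2) accurate)."""
    k = x.size
    H = np.empty((k, k))
    ei = np.eye(k)
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                fp = f(x + 2 * step * ei[i])
                fm = f(x - 2 * step * ei[i])
                H[i, i] = (fp - 2 * f0 + fm) / (4.0 * step**2)
            else:
                fpp = f(x + step * (ei[i] + ei[j]))
                fpm = f(x + step * (ei[i] - ei[j]))
                fmp = f(x - step * (ei[i] - ei[j]))
                fmm = f(x - step * (ei[i] + ei[j]))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step**2)
    return H


def _vcov_from_hessian(H: np.ndarray) -> np.ndarray | None:
    if not np.isfinite(H).all():
        return None
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if not np.isfinite(vcov).all() or (np.diag(vcov) < -1e-8).any():
        return None
    return 0.5 * (vcov + vcov.T)


def fit(
    spec: ModelSpec,
    data: DetectionHistorySet,
    options: OptimizerOptions | None = None,
    design: DesignSet | None = None,
    start: np.ndarray | None = None,
) -> FitResult:
    """Fit a multi-season multi-state occupancy model by ML.

    Runs L-BFGS-B from a zero start, ``options.n_random_starts`` random
    starts, and any user-supplied ``start``; retains the best optimum.
    Non-convergence is flagged on the result, never raised.
    """
    options = options or OptimizerOptions()
    design = design or build_design(spec, data)
    rng = np.random.default_rng(options.seed)
    starts = [np.zeros(design.K)]
    if start is not None:
        starts.append(np.asarray(start, dtype=float))
    for _ in range(options.n_random_starts):
        starts.append(rng.uniform(-options.start_scale, options.start_scale, design.K))

    def objective(theta: np.ndarray) -> float:
        val = total_negloglik(theta, design, data)
        return val if np.isfinite(val) else 1e12

    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            options={"ftol": options.ftol, "gtol": 1e-8, "maxiter": options.maxiter},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    assert best is not None
    mle = np.asarray(best.x, dtype=float)
    H = _numeric_hessian(objective, mle, options.hessian_step)
    vcov = _vcov_from_hessian(H)
    # boundary flag: any fitted probability numerically at 0 or 1
    pars = site_parameters(mle, design)
    flat = np.concatenate(
        [np.ravel(pars[k]) for k in ("psi1", "r1", "psi", "r", "p1", "p2")]
        + [pars["delta"][1:]]
    )
    boundary = bool((flat < 1e-6).any() or (flat > 1.0 - 1e-6).any())
    return FitResult(
        spec=spec,
        design=design,
        mle=mle,
        neg_loglik=float(best.fun),
        vcov=vcov,
        converged=bool(best.success),
        n_starts_used=len(starts),
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# real-scale derived estimates
# ---------------------------------------------------------------------------

def _condition_row(
    design: DesignSet,
    family: str,
    prev_state: int | None,
    transition: int | None,
    covariates: dict[str, float] | None,
) -> np.ndarray:
    """Design row for one ψ/R family at a given condition.

    Unspecified covariates sit at 0 (their standardized mean); the year
    defaults to the reference (first) transition.
    """
    spec = design.spec
    terms = {
        "psi1": spec.psi1_terms,
        "r1": spec.r1_terms,
        "psi": spec.psi_terms,
        "r": spec.r_terms,
    }[family]
    covariates = covariates or {}
    unknown = set(covariates) - set(terms)
    if unknown:
        raise SpecError(f"condition covariate(s) {sorted(unknown)} not in the {family} model")
    row = [1.0]
    for term in terms:
        if term == "state":
            m = 0 if prev_state is None else int(prev_state)
            row += [1.0 if m == 1 else 0.0, 1.0 if m == 2 else 0.0]
        elif term == "year":
            k = 0 if transition is None else int(transition)
            row += [1.0 if k == j else 0.0 for j in range(1, design.n_seasons - 1)]
        else:
            row.append(float(covariates.get(term, 0.0)))
    return np.asarray(row)


def real_estimate(
    fit_result: FitResult,
    family: str,
    prev_state: int | None = None,
    transition: int | None = None,
    covariates: dict[str, float] | None = None,
    label: str | None = None,
) -> RealEstimate:
    """Real-scale probability for one parameter family at a condition.

    ``family`` is one of ``psi1, r1, psi, r`` (with optional previous
    state, transition-year index and covariate values) or a detection
    family ``p1, p2, delta`` with ``transition`` giving the 0-based
    survey index.
    """
    design = fit_result.design
    sl = design.slices[family]
    if family in ("p1", "p2", "delta"):
        j = 0 if transition is None else int(transition)
        if family == "delta":
            if j == 0:
                return RealEstimate(label or "delta[1]", 0.0, 0.0, 0.0, 0.0)
            j -= 1  # free deltas start at survey 2
        idx = sl.start + j
        eta = float(fit_result.mle[idx])
        se = (
            float(np.sqrt(max(fit_result.vcov[idx, idx], 0.0)))
            if fit_result.vcov is not None
            else float("nan")
        )
        lab = label or design.names[idx]
        return RealEstimate.from_logit(lab, eta, se)
    x = _condition_row(design, family, prev_state, transition, covariates)
    beta = fit_result.mle[sl]
    eta = float(x @ beta)
    if fit_result.vcov is not None:
        var = float(x @ fit_result.vcov[sl, sl] @ x)
        se = float(np.sqrt(max(var, 0.0)))
    else:
        se = float("nan")
    lab = label or (f"{family}[{prev_state}]" if prev_state is not None else family)
    return RealEstimate.from_logit(lab, eta, se)


def real_estimates(
    fit_result: FitResult, conditions: list[dict] | None = None
) -> list[RealEstimate]:
    """Standard report: ψ/R by previous state plus all detection parameters."""
    if conditions is not None:
        return [real_estimate(fit_result, **c) for c in conditions]
    out = []
    for m in (0, 1, 2):
        out.append(real_estimate(fit_result, "psi", prev_state=m, label=f"psi[{m}]"))
    for m in (0, 1, 2):
        out.append(real_estimate(fit_result, "r", prev_state=m, label=f"R[{m}]"))
    for fam in ("p1", "p2"):
        for j in range(fit_result.design.n_surveys):
            out.append(
                real_estimate(fit_result, fam, transition=j, label=f"{fam}[{j + 1}]")
            )
    for j in range(fit_result.design.n_surveys):
        out.append(real_estimate(fit_result, "delta", transition=j, label=f"delta[{j + 1}]"))
    return out


def _marginal_state_distributions(
    theta: np.ndarray, design: DesignSet
) -> np.ndarray:
    """Unconditional P(state) per (site, season): shape (n, T, 3)."""
    p = site_parameters(theta, design)
    n, T = design.n_sites, design.n_seasons
    pi = np.empty((n, T, 3))
    pi[:, 0, 0] = 1.0 - p["psi1"]
    pi[:, 0, 1] = p["psi1"] * (1.0 - p["r1"])
    pi[:, 0, 2] = p["psi1"] * p["r1"]
    for t in range(1, T):
        ps, rr = p["psi"][:, t - 1, :], p["r"][:, t - 1, :]
        trans = np.stack([1.0 - ps, ps * (1.0 - rr), ps * rr], axis=-1)
        pi[:, t, :] = np.einsum("nm,nms->ns", pi[:, t - 1, :], trans)
    return pi


def average_probability(
    fit_result: FitResult,
    family: str,
    data: DetectionHistorySet | None = None,
) -> RealEstimate:
    """Average occupancy (or success-given-occupancy) over sites and seasons.

    ``family='psi'`` averages the model-implied marginal probability of
    occupancy P(state > 0) over every site-season cell; ``family='r'``
    averages P(state = 2 | state > 0).  Uncertainty is propagated from
    the coefficient covariance by the delta method (numeric gradient),
    with the interval built on the logit scale.
    """
    del data  # the design already fixes the site set
    design = fit_result.design

    def stat(theta: np.ndarray) -> float:
        pi = _marginal_state_distributions(theta, design)
        occ = pi[:, :, 1] + pi[:, :, 2]
        if family == "psi":
            return float(occ.mean())
        if family == "r":
            with np.errstate(invalid="ignore", divide="ignore"):
                cond = np.where(occ > 0, pi[:, :, 2] / occ, 0.0)
            return float(cond.mean())
        raise SpecError(f"family must be 'psi' or 'r', got {family!r}")

    point = stat(fit_result.mle)
    if fit_result.vcov is None:
        return RealEstimate(f"avg_{family}", point, float("nan"), float("nan"), float("nan"))
    step = 1e-6
    grad = np.empty(design.K)
    for i in range(design.K):
        e = np.zeros(design.K)
        e[i] = step
        grad[i] = (stat(fit_result.mle + e) - stat(fit_result.mle - e)) / (2 * step)
    var = float(grad @ fit_result.vcov @ grad)
    se = float(np.sqrt(max(var, 0.0)))
    p = min(max(point, 1e-12), 1.0 - 1e-12)
    eta, se_eta = float(logit(p)), se / (p * (1.0 - p))
    est = RealEstimate.from_logit(f"avg_{family}", eta, se_eta)
    return RealEstimate(est.label, point, se, est.ci_low, est.ci_high, est.boundary)
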