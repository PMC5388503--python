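"""AIC-based model selection, Akaike weights, and model averaging.

Ranking follows the standard information-theoretic workflow: for each
candidate model, ΔAIC_i = AIC_i − min(AIC) and the Akaike weight
w_i = exp(−ΔAIC_i/2) / Σ_j exp(−ΔAIC_j/2).  Model-averaged estimates
combine per-model points with these weights; their unconditional
standard error adds the between-model spread to the within-model
variance (Burnham–Anderson):

    SE_uncond = Σ_i w_i * sqrt(var_i + (θ_i − θ̄)²)

Because fitting every combination of occupancy and success structures is
combinatorially expensive, selection can run in two phases: optimize the
structure of one parameter family while the other is held at an anchor
structure, then fix the winner and optimize the other family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import DetectionHistorySet
from .design import ModelSpec
from .fit import FitResult, OptimizerOptions, RealEstimate, Z95, fit

logger = logging.getLogger(__name__)


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights over a candidate set (sum to 1)."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


@dataclass
class ModelTable:
    """Ranked candidate models: label, K, AIC, ΔAIC, weight, deviance."""

    table: pd.DataFrame
    fits: list[FitResult]

    @property
    def best(self) -> FitResult:
        for i in self.table.index:
            if self.table.loc[i, "converged"]:
                return self.fits[int(self.table.loc[i, "fit_index"])]
        return self.fits[int(self.table.loc[self.table.index[0], "fit_index"])]

    def to_csv(self, path: str | Path) -> None:
        cols = ["Model", "K", "AIC", "dAIC", "w", "Deviance"]
        self.table[cols].to_csv(path, index=False, float_format="%.4f")

    def alternatives(self) -> pd.DataFrame:
        """Models within 2 AIC of the best, with a deviance-reduction flag.

        A model whose deviance does not improve on the best model's has
        bought its ΔAIC < 2 entirely with an extra parameter — an
        uninformative-parameter signature — and is flagged
        non-competitive.
        """
        best_dev = float(self.table["Deviance"].iloc[0])
        alt = self.table[self.table["dAIC"] < 2.0].copy()
        alt["competitive"] = alt["Deviance"] < best_dev - 1e-9
        alt.loc[alt.index[0], "competitive"] = True
        return alt


def rank_models(fits: Sequence[FitResult]) -> ModelTable:
    """Rank fitted models by AIC; ties broken by smaller K then label.

    Non-converged fits are retained (flagged) so the table is complete,
    but :attr:`ModelTable.best` skips them.
    """
    if not fits:
        raise ValueError("rank_models needs at least one fit")
    rows = [
        {
            "Model": f.label,
            "K": f.K,
            "AIC": f.aic,
            "Deviance": f.deviance,
            "converged": f.converged,
            "fit_index": i,
        }
        for i, f in enumerate(fits)
    ]
    df = pd.DataFrame(rows).sort_values(["AIC", "K", "Model"]).reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    df["w"] = akaike_weights(df["AIC"].to_numpy())
    return ModelTable(df[["Model", "K", "AIC", "dAIC", "w", "Deviance", "converged", "fit_index"]], list(fits))


@dataclass(frozen=True)
class AveragedEstimate:
    """A model-averaged probability with its unconditional SE."""

    label: str
    point: float
    unconditional_se: float
    ci_low: float
    ci_high: float


def model_average(
    fits: Sequence[FitResult],
    weights: Sequence[float],
    target: Callable[[FitResult], RealEstimate],
    label: str | None = None,
) -> AveragedEstimate:
    """Average a derived estimate across models with Akaike weights.

    The point is the weighted mean of per-model points; the
    unconditional SE mixes within-model variance and between-model
    spread.  The confidence interval is built on the logit scale from
    the averaged point and unconditional SE, keeping it inside [0, 1].
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(fits):
        raise ValueError("one weight per fit required")
    if abs(w.sum() - 1.0) > 1e-9:
        logger.warning("weights sum to %.6f; renormalizing", w.sum())
        w = w / w.sum()
    ests = [target(f) for f in fits]
    points = np.array([e.point for e in ests])
    ses = np.array([e.se for e in ests])
    point = float(w @ points)
    terms = np.sqrt(ses**2 + (points - point) ** 2)
    se = float(np.sum(np.where(w == 0.0, 0.0, w * terms)))  # zero weight drops out
    p = min(max(point, 1e-12), 1.0 - 1e-12)
    if se > 0 and 0.0 < point < 1.0:
        eta, se_eta = float(logit(p)), se / (p * (1.0 - p))
        lo = float(expit(eta - Z95 * se_eta))
        hi = float(expit(eta + Z95 * se_eta))
    else:
        lo = hi = point
    return AveragedEstimate(label or ests[0].label, point, se, lo, hi)


def average_from_table(
    table: ModelTable,
    target: Callable[[FitResult], RealEstimate],
    top_only: bool = False,
    label: str | None = None,
) -> AveragedEstimate:
    """Model-average over a ranked table (optionally ΔAIC < 2 models only,
    with weights renormalized over that subset)."""
    df = table.table[table.table["converged"]]
    if top_only:
        df = df[df["dAIC"] < 2.0]
    fits = [table.fits[int(i)] for i in df["fit_index"]]
    w = df["w"].to_numpy(float)
    return model_average(fits, w / w.sum(), target, label=label)


@dataclass
class TwoPhaseResult:
    phase1: ModelTable
    phase2: ModelTable

    @property
    def best(self) -> FitResult:
        return self.phase2.best


def two_phase_selection(
    psi_candidates: Sequence[Sequence[str]],
    r_candidates: Sequence[Sequence[str]],
    data: DetectionHistorySet,
    anchor_r: Sequence[str],
    options: OptimizerOptions | None = None,
    psi1_terms: Sequence[str] = (),
    r1_terms: Sequence[str] = (),
) -> TwoPhaseResult:
    """Two-phase structure selection.

    Phase 1 fits every occupancy (ψ) candidate with the success (R)
    structure held at ``anchor_r`` and picks the AIC-best; phase 2 fixes
    that ψ structure and fits every R candidate.
    """
    if not psi_candidates or not r_candidates:
        raise ValueError("candidate lists must be non-empty")
    fits1 = []
    for terms in psi_candidates:
        spec = ModelSpec(
            psi_terms=tuple(terms),
            r_terms=tuple(anchor_r),
            psi1_terms=tuple(psi1_terms),
            r1_terms=tuple(r1_terms),
            n_surveys=data.n_surveys,
        )
        f = fit(spec, data, options)
        logger.info(
            "phase1 %s K=%d AIC=%.2f converged=%s", f.label, f.K, f.aic, f.converged
        )
        fits1.append(f)
    table1 = rank_models(fits1)
    best_psi = table1.best.spec.psi_terms
    fits2 = []
    for terms in r_candidates:
        spec = ModelSpec(
            psi_terms=best_psi,
            r_terms=tuple(terms),
            psi1_terms=tuple(psi1_terms),
            r1_terms=tuple(r1_terms),
            n_surveys=data.n_surveys,
        )
        f = fit(spec, data, options)
        logger.info(
            "phase2 %s K=%d AIC=%.2f converged=%s", f.label, f.K, f.aic, f.converged
        )
        fits2.append(f)
    return TwoPhaseResult(table1, rank_models(fits2))


def default_candidates(
    covariates: Sequence[str] = ("state", "year", "zone", "ruggedness", "crops", "scrub", "distance"),
    max_terms: int = 3,
) -> list[tuple[str, ...]]:
    """Intercept-only plus all additive combinations of ≤ max_terms terms."""
    out: list[tuple[str, ...]] = [()]
    for k in range(1, max_terms + 1):
        out.extend(itertools.combinations(covariates, k))
    return out
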