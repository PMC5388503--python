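"""Model specification and design-matrix construction.

A model is specified by the covariate terms acting on each parameter
family on the logit scale:

* ``psi1`` / ``r1`` — first-season occupancy and success (no previous
  state exists, so ``state`` is not allowed here);
* ``psi`` / ``r`` — transition probabilities for seasons 2..T, which may
  depend on the previous latent state (``state``, coded as two dummies
  for states 1 and 2 against reference 0), on the transition year
  (``year``, categorical with the first transition as reference) and on
  site covariates;
* detection — survey-specific detection probabilities ``p[1]`` (state-1
  territories) and ``p[2]`` (state-2 territories), four free parameters
  each, and reproduction-evidence probabilities ``delta`` with the
  first-survey value structurally fixed at zero and surveys 2..J free;
  all constant across years.

``build_design`` turns a spec plus data into per-family design matrices
whose total column count is the model's free-parameter count K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .data import DetectionHistorySet, DataError

STATE_TERM = "state"
YEAR_TERM = "year"
#: covariates standardized to zero mean / unit sd before analysis
QUANTITATIVE = ("ruggedness", "crops", "scrub", "distance")


class SpecError(ValueError):
    """Raised for an inconsistent or unresolvable model specification."""


def _canon(terms: Iterable[str]) -> tuple[str, ...]:
    seen: list[str] = []
    for t in terms:
        c = t.strip().lower()
        if c in ("intercept", "1", "."):
            continue
        if c == "crop":
            c = "crops"
        if c not in seen:
            seen.append(c)
    # deterministic ordering: state, year, then alphabetical site covariates
    front = [t for t in (STATE_TERM, YEAR_TERM) if t in seen]
    rest = sorted(t for t in seen if t not in (STATE_TERM, YEAR_TERM))
    return tuple(front + rest)


@dataclass(frozen=True)
class ModelSpec:
    """Covariate structure per parameter family (all logit links).

    Terms are drawn from ``state``, ``year`` and the site covariate
    names; an intercept is always included and need not be listed.
    """

    psi_terms: tuple[str, ...] = ()
    r_terms: tuple[str, ...] = ()
    psi1_terms: tuple[str, ...] = ()
    r1_terms: tuple[str, ...] = ()
    n_surveys: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "psi_terms", _canon(self.psi_terms))
        object.__setattr__(self, "r_terms", _canon(self.r_terms))
        object.__setattr__(self, "psi1_terms", _canon(self.psi1_terms))
        object.__setattr__(self, "r1_terms", _canon(self.r1_terms))
        for fam, terms in (("psi1", self.psi1_terms), ("r1", self.r1_terms)):
            if STATE_TERM in terms or YEAR_TERM in terms:
                raise SpecError(f"{fam} cannot depend on state or year")

    @staticmethod
    def _fmt(terms: tuple[str, ...]) -> str:
        return "+".join(t.capitalize() for t in terms) if terms else "."

    @property
    def label(self) -> str:
        return f"psi({self._fmt(self.psi_terms)}) R({self._fmt(self.r_terms)})"

    def to_config(self) -> str:
        """One line per family, round-trippable via :meth:`from_config`."""
        return "\n".join(
            f"{fam}: {' '.join(terms) if terms else 'intercept'}"
            for fam, terms in [
                ("psi1", self.psi1_terms),
                ("r1", self.r1_terms),
                ("psi", self.psi_terms),
                ("r", self.r_terms),
            ]
        )

    @classmethod
    def from_config(cls, text: str) -> "ModelSpec":
        kw: dict[str, tuple[str, ...]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fam, _, rhs = line.partition(":")
            fam = fam.strip().lower()
            if fam not in ("psi1", "r1", "psi", "r"):
                raise SpecError(f"unknown parameter family {fam!r}")
            kw[f"{fam}_terms"] = tuple(rhs.replace("+", " ").split())
        return cls(**kw)


@dataclass
class DesignSet:
    """Design matrices and coefficient layout for one ModelSpec.

    Transition-family matrices have one row per (site, transition,
    previous-state) cell in site-major order; first-season matrices one
    row per site.  ``K`` counts every free coefficient including the
    survey-specific detection parameters.
    """

    spec: ModelSpec
    X_psi1: np.ndarray
    X_r1: np.ndarray
    X_psi: np.ndarray
    X_r: np.ndarray
    names: list[str]
    slices: dict[str, slice]
    n_sites: int
    n_seasons: int
    n_surveys: int

    @property
    def K(self) -> int:
        return len(self.names)

    @property
    def n_transitions(self) -> int:
        return self.n_seasons - 1

    def split(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.K,):
            raise SpecError(f"coefficient vector has length {theta.size}, expected {self.K}")
        return {fam: theta[sl] for fam, sl in self.slices.items()}


def standardize_covariates(data: DetectionHistorySet) -> DetectionHistorySet:
    """Center and scale quantitative covariates to mean 0, sd 1.

    Binary covariates (``zone``) are left untouched.  The (mean, sd)
    pairs are retained on the returned data for back-transformation of
    reported effects.  Uses the sample standard deviation (ddof=1).
    """
    cov = data.covariates.copy()
    constants = dict(data.standardization)
    for name in cov.columns:
        if name not in QUANTITATIVE:
            continue
        x = cov[name].to_numpy(float)
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if sd == 0.0 or not np.isfinite(sd):
            raise DataError(f"covariate {name!r} has no spread; cannot standardize")
        mean = float(np.mean(x))
        cov[name] = (x - mean) / sd
        constants[name] = (mean, sd)
    return DetectionHistorySet(
        site_ids=list(data.site_ids),
        observations=data.observations.copy(),
        covariates=cov,
        standardization=constants,
    )


def _family_matrix(
    terms: tuple[str, ...],
    data: DetectionHistorySet,
    transition: bool,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for one ψ/R family.

    First-season families: one row per site.  Transition families: rows
    ordered (site, transition t=2..T, previous state m=0,1,2).
    """
    n, T = data.n_sites, data.n_seasons
    cov = data.covariates.loc[data.site_ids]
    if transition:
        n_tr = T - 1
        site_ix = np.repeat(np.arange(n), n_tr * 3)
        tr_ix = np.tile(np.repeat(np.arange(n_tr), 3), n)
        st_ix = np.tile(np.arange(3), n * n_tr)
        rows = n * n_tr * 3
    else:
        site_ix = np.arange(n)
        rows = n
    cols: list[np.ndarray] = [np.ones(rows)]
    names: list[str] = ["(intercept)"]
    for term in terms:
        if term == STATE_TERM:
            if not transition:
                raise SpecError("state term is only defined for transition families")
            cols += [(st_ix == 1).astype(float), (st_ix == 2).astype(float)]
            names += ["state[1]", "state[2]"]
        elif term == YEAR_TERM:
            if not transition:
                raise SpecError("year term is only defined for transition families")
            for k in range(1, T - 1):  # reference = first transition
                cols.append((tr_ix == k).astype(float))
                names.append(f"year[{k + 1}]")
        else:
            if term not in cov.columns:
                raise SpecError(f"unknown covariate {term!r}")
            cols.append(cov[term].to_numpy(float)[site_ix])
            names.append(term)
    return np.column_stack(cols), names


def build_design(spec: ModelSpec, data: DetectionHistorySet) -> DesignSet:
    """Construct design matrices and the coefficient layout for a model."""
    if spec.n_surveys != data.n_surveys:
        raise SpecError(
            f"spec expects {spec.n_surveys} surveys but data has {data.n_surveys}"
        )
    X1, n1 = _family_matrix(spec.psi1_terms, data, transition=False)
    Xr1, nr1 = _family_matrix(spec.r1_terms, data, transition=False)
    Xp, np_ = _family_matrix(spec.psi_terms, data, transition=True)
    Xr, nr = _family_matrix(spec.r_terms, data, transition=True)
    J = data.n_surveys
    names: list[str] = []
    slices: dict[str, slice] = {}
    blocks = [
        ("psi1", [f"psi1:{s}" for s in n1]),
        ("r1", [f"r1:{s}" for s in nr1]),
        ("psi", [f"psi:{s}" for s in np_]),
        ("r", [f"r:{s}" for s in nr]),
        ("p1", [f"p1[{j + 1}]" for j in range(J)]),
        ("p2", [f"p2[{j + 1}]" for j in range(J)]),
        ("delta", [f"delta[{j + 1}]" for j in range(1, J)]),  # survey 1 fixed at 0
    ]
    for fam, blk in blocks:
        slices[fam] = slice(len(names), len(names) + len(blk))
        names.extend(blk)
    if len(set(names)) != len(names):
        raise SpecError("duplicate coefficient names")
    return DesignSet(
        spec=spec,
        X_psi1=X1,
        X_r1=Xr1,
        X_psi=Xp,
        X_r=Xr,
        names=names,
        slices=slices,
        n_sites=data.n_sites,
        n_seasons=data.n_seasons,
        n_surveys=J,
    )
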