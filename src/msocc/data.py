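"""Detection-history data model and I/O.

A *detection history* records, for each territory (site), the outcome of
repeated surveys within each breeding season over several seasons.  Each
survey is coded with one of three observable states

* ``0`` — no sign of occupancy,
* ``1`` — occupancy detected, no evidence of successful reproduction,
* ``2`` — occupancy detected with evidence of successful reproduction,

or marked missing when the survey was not carried out.  Alongside the
histories each site carries habitat covariates (zone, ruggedness, crops,
scrub, distance to the nearest track) used downstream to model occupancy
and breeding-success probabilities.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a survey that was not carried out.  Stored as -1 in the
#: integer observation array; never compares equal to a legal state code.
MISSING: int = -1

LEGAL_CODES = frozenset({0, 1, 2})

DEFAULT_COVARIATES = ("zone", "ruggedness", "crops", "scrub", "distance")


class DataError(ValueError):
    """Raised for malformed or inconsistent detection-history input."""


@dataclass(frozen=True)
class Dialect:
    """Layout of a plain-text detection-history table.

    One row per site: a site identifier, then ``n_seasons * n_surveys``
    observation columns (season-major), then the covariate columns.
    Observation codes may be given one token per survey or packed into
    strings (e.g. ``010.`` for one season of four surveys).
    """

    n_seasons: int = 7
    n_surveys: int = 4
    delimiter: str | None = None  # None = any whitespace
    missing_tokens: tuple[str, ...] = (".", "-", "NA")
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES
    comment_char: str = "#"

    @property
    def n_obs(self) -> int:
        return self.n_seasons * self.n_surveys


@dataclass
class DetectionHistorySet:
    """Observation codes and site covariates for an occupancy study.

    Attributes
    ----------
    site_ids
        One identifier per site, unique.
    observations
        Integer array of shape ``(n_sites, n_seasons, n_surveys)`` holding
        codes 0/1/2 or :data:`MISSING`.
    covariates
        DataFrame indexed like ``site_ids`` with one numeric column per
        covariate.
    """

    site_ids: list[str]
    observations: np.ndarray
    covariates: pd.DataFrame
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=np.int64)
        self.validate()

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_seasons(self) -> int:
        return self.observations.shape[1]

    @property
    def n_surveys(self) -> int:
        return self.observations.shape[2]

    def validate(self) -> None:
        if self.observations.ndim != 3:
            raise DataError("observations must be a sites x seasons x surveys array")
        if self.observations.shape[0] != len(self.site_ids):
            raise DataError(
                f"{len(self.site_ids)} site ids but "
                f"{self.observations.shape[0]} observation rows"
            )
        if len(set(self.site_ids)) != len(self.site_ids):
            dupes = sorted({s for s in self.site_ids if self.site_ids.count(s) > 1})
            raise DataError(f"duplicate site id(s): {dupes}")
        legal = np.isin(self.observations, [MISSING, 0, 1, 2])
        if not legal.all():
            bad = np.unique(self.observations[~legal])
            raise DataError(f"illegal observation code(s): {bad.tolist()}")
        if (self.observations == MISSING).all(axis=(1, 2)).any():
            idx = int(np.argmax((self.observations == MISSING).all(axis=(1, 2))))
            raise DataError(f"site {self.site_ids[idx]!r} has no non-missing survey")
        missing_cov = [s for s in self.site_ids if s not in self.covariates.index]
        if missing_cov:
            raise DataError(f"covariates missing for site(s): {missing_cov}")
        if not np.isfinite(self.covariates.loc[self.site_ids].to_numpy(float)).all():
            raise DataError("non-finite covariate values")

    def subset(self, indices: Sequence[int]) -> "DetectionHistorySet":
        ids = [self.site_ids[i] for i in indices]
        return DetectionHistorySet(
            site_ids=ids,
            observations=self.observations[list(indices)],
            covariates=self.covariates.loc[ids],
            standardization=dict(self.standardization),
        )


@dataclass(frozen=True)
class NaiveSummary:
    """Detection-ignorant occupancy and breeding-success summaries.

    ``naive_occupancy`` is the fraction of surveyed site-years with at
    least one detection (code 1 or 2); ``naive_success`` the fraction of
    *those* site-years with at least one code-2 observation.  Both ignore
    imperfect detection and therefore underestimate the corresponding
    model-based probabilities whenever detection is imperfect.
    """

    naive_occupancy: float
    naive_success: float
    per_season: pd.DataFrame  # columns: season, n_surveyed, n_occupied, n_success, ...


def _season_flags(obs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per site-year: any non-missing survey, any detection, any code 2."""
    surveyed = (obs != MISSING).any(axis=2)
    detected = ((obs == 1) | (obs == 2)).any(axis=2)
    success = (obs == 2).any(axis=2)
    return surveyed, detected, success


def naive_estimates(data: DetectionHistorySet) -> NaiveSummary:
    """Compute naïve (detection-ignorant) occupancy and success proportions.

    Site-years with every survey missing are excluded from the occupancy
    denominator; the success denominator is the set of site-years with at
    least one detection.
    """
    surveyed, detected, success = _season_flags(data.observations)
    n_surveyed = int(surveyed.sum())
    if n_surveyed == 0:
        raise DataError("no non-missing observations; naive summary undefined")
    n_detected = int(detected.sum())
    occ = n_detected / n_surveyed
    succ = float("nan") if n_detected == 0 else int(success.sum()) / n_detected
    rows = []
    for t in range(data.n_seasons):
        ns, nd, nc = int(surveyed[:, t].sum()), int(detected[:, t].sum()), int(success[:, t].sum())
        rows.append(
            {
                "season": t + 1,
                "n_surveyed": ns,
                "n_occupied": nd,
                "n_success": nc,
                "naive_occupancy": nd / ns if ns else float("nan"),
                "naive_success": nc / nd if nd else float("nan"),
            }
        )
    return NaiveSummary(occ, succ, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# plain-text reader / writer
# ---------------------------------------------------------------------------

def _tokenize(line: str, dialect: Dialect) -> list[str]:
    if dialect.delimiter is None:
        return line.split()
    return [t.strip() for t in line.split(dialect.delimiter)]


def _parse_obs_tokens(tokens: list[str], dialect: Dialect, lineno: int) -> np.ndarray:
    """Accept one token per survey or packed strings covering all surveys."""
    chars: list[str] = []
    for tok in tokens:
        if tok in dialect.missing_tokens:
            chars.append(".")
        elif len(tok) == 1:
            chars.append(tok)
        else:  # packed string: per-character codes, '.'/'-' as missing
            chars.extend(tok)
    if len(chars) != dialect.n_obs:
        raise DataError(
            f"line {lineno}: expected {dialect.n_obs} observation codes, got {len(chars)}"
        )
    out = np.empty(dialect.n_obs, dtype=np.int64)
    for k, ch in enumerate(chars):
        if ch in dialect.missing_tokens or ch in (".", "-"):
            out[k] = MISSING
        elif ch in ("0", "1", "2"):
            out[k] = int(ch)
        else:
            season, survey = divmod(k, dialect.n_surveys)
            raise DataError(
                f"line {lineno}: unknown observation token {ch!r} "
                f"(season {season + 1}, survey {survey + 1})"
            )
    return out.reshape(dialect.n_seasons, dialect.n_surveys)


def read_detection_histories(
    path: str | Path | io.TextIOBase, dialect: Dialect | None = None
) -> DetectionHistorySet:
    """Read a plain-text detection-history table.

    Each row: site id, ``n_seasons * n_surveys`` observation codes
    (season-major), then one column per covariate named in the dialect.
    """
    dialect = dialect or Dialect()
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    site_ids: list[str] = []
    obs_rows: list[np.ndarray] = []
    cov_rows: list[list[float]] = []
    n_cov = len(dialect.covariate_names)
    header_skipped = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(dialect.comment_char):
            continue
        tokens = _tokenize(line, dialect)
        tokens = [t for t in tokens if t]
        if not header_skipped and tokens and tokens[0].lower() in ("site", "site_id", "id"):
            header_skipped = True
            continue
        if len(tokens) < 1 + n_cov:
            raise DataError(f"line {lineno}: too few columns ({len(tokens)})")
        site_ids.append(tokens[0])
        obs_tokens = tokens[1 : len(tokens) - n_cov]
        obs_rows.append(_parse_obs_tokens(obs_tokens, dialect, lineno))
        try:
            cov_rows.append([float(v) for v in tokens[len(tokens) - n_cov :]])
        except ValueError as exc:
            raise DataError(f"line {lineno}: non-numeric covariate value ({exc})") from None
    if not site_ids:
        raise DataError("no data rows found")
    covariates = pd.DataFrame(
        cov_rows, index=site_ids, columns=list(dialect.covariate_names)
    )
    data = DetectionHistorySet(site_ids, np.stack(obs_rows), covariates)
    _warn_inconsistent_seasons(data)
    return data


def _warn_inconsistent_seasons(data: DetectionHistorySet) -> None:
    # Under the no-false-positive coding every within-season code mix is
    # legal (a successful territory may be seen without evidence early and
    # with evidence later), so this is a hook that currently never fires;
    # kept so stricter codings can plug in a check.
    del data


def write_detection_histories(
    data: DetectionHistorySet, path: str | Path, dialect: Dialect | None = None
) -> None:
    """Write a DetectionHistorySet in the same one-row-per-site text format."""
    dialect = dialect or Dialect(
        n_seasons=data.n_seasons,
        n_surveys=data.n_surveys,
        covariate_names=tuple(data.covariates.columns),
    )
    miss = dialect.missing_tokens[0]
    with open(path, "w") as fh:
        header = (
            ["site"]
            + [
                f"s{t + 1}v{j + 1}"
                for t in range(data.n_seasons)
                for j in range(data.n_surveys)
            ]
            + list(data.covariates.columns)
        )
        fh.write("# " + " ".join(header) + "\n")
        for i, sid in enumerate(data.site_ids):
            codes = [
                miss if c == MISSING else str(int(c))
                for c in data.observations[i].ravel()
            ]
            covs = [repr(float(v)) for v in data.covariates.loc[sid]]
            fh.write(" ".join([sid] + codes + covs) + "\n")


def naive_summary_to_csv(summary: NaiveSummary, path: str | Path) -> None:
    df = summary.per_season.copy()
    df.attrs["overall"] = (summary.naive_occupancy, summary.naive_success)
    with open(path, "w") as fh:
        fh.write(f"# overall naive_occupancy={summary.naive_occupancy:.6f} ")
        fh.write(f"naive_success={summary.naive_success:.6f}\n")
        df.to_csv(fh, index=False)
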