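"""Core network scale-up estimators.

The known-population method estimates a respondent's personal network
size from counts of alters in subpopulations of known size: with ``m``
the mean total count of known-subpopulation alters per respondent,

    c = m * t / e0

Scaling the unmasked mean hidden-alter count ``m1`` by the same logic
gives the basic hidden-population size estimate

    e1 = (m1 / c) * t

Both are ratio-of-means estimators: one pooled ``m`` over all names, a
single ``c`` — never per-name or per-respondent ratios averaged.  A
per-respondent variant is exposed for diagnostics only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .study_frame import StudyFrame

logger = logging.getLogger("nsum")

NAME_PREFIX = "name_"


@dataclass(frozen=True)
class ScaleUpEstimate:
    """A point estimate with an optional percentile confidence interval."""

    point: float
    n: int
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValidationError("ci_low and ci_high must be given together")
        if self.ci_low is not None and not self.ci_low <= self.point <= self.ci_high:
            raise ValidationError(
                f"CI [{self.ci_low}, {self.ci_high}] must bracket the point {self.point}"
            )


class GeneralSurveyTable:
    """General-population survey: one row per respondent.

    Expected columns: ``id``, optional cluster labels (``industry``,
    ``unit``, ``department``), one ``name_<label>`` count column per known
    subpopulation, ``rrt_group`` (1/2), ``rrt_answer`` (masked numeric
    answer) and ``answered`` (False for blank sheets).  Rows with
    ``answered=False`` carry no counts and are excluded from every mean.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.name_columns = [c for c in self.df.columns if c.startswith(NAME_PREFIX)]
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.df
        if not self.name_columns:
            raise ValidationError(f"general survey has no '{NAME_PREFIX}<label>' count columns")
        if "id" not in df.columns:
            raise ValidationError("general survey missing 'id' column")
        if "answered" not in df.columns:
            # infer: a row with any missing count is unanswered
            counts = df[self.name_columns]
            df["answered"] = ~counts.isna().any(axis=1)
        df["answered"] = df["answered"].astype(bool)
        ans = df["answered"]
        # missing counts on nominally answered rows demote them to unanswered
        incomplete = ans & df[self.name_columns].isna().any(axis=1)
        if incomplete.any():
            logger.info("demoting %d rows with missing counts to answered=False", incomplete.sum())
            df.loc[incomplete, "answered"] = False
            ans = df["answered"]
        counts = df.loc[ans, self.name_columns].to_numpy(dtype=float)
        if (counts < 0).any():
            raise ValidationError("known-subpopulation counts must be non-negative")
        if "rrt_group" in df.columns:
            groups = df.loc[ans, "rrt_group"].to_numpy()
            if not np.isin(groups, (1, 2)).all():
                raise ValidationError("rrt_group must be 1 or 2 on answered rows")
        if "rrt_answer" in df.columns:
            answers = df.loc[ans, "rrt_answer"].to_numpy(dtype=float)
            if np.isnan(answers).any():
                raise ValidationError("rrt_answer missing on answered rows")
            if (answers < 0).any():
                raise ValidationError("rrt_answer must be non-negative")

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def answered_mask(self) -> np.ndarray:
        return self.df["answered"].to_numpy(dtype=bool)

    @property
    def n_answered(self) -> int:
        return int(self.answered_mask.sum())

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c[len(NAME_PREFIX):] for c in self.name_columns)

    def known_matrix(self) -> np.ndarray:
        """Counts of answered rows, shape (n_answered, n_names)."""
        return self.df.loc[self.answered_mask, self.name_columns].to_numpy(dtype=float)

    def known_row_sums(self) -> np.ndarray:
        return self.known_matrix().sum(axis=1)

    def name_totals(self) -> np.ndarray:
        """Total reported alters per name over answered rows."""
        return self.known_matrix().sum(axis=0)

    def rrt_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(group, answer) arrays over answered rows."""
        ans = self.answered_mask
        return (
            self.df.loc[ans, "rrt_group"].to_numpy(dtype=int),
            self.df.loc[ans, "rrt_answer"].to_numpy(dtype=float),
        )

    def take(self, idx) -> "GeneralSurveyTable":
        """Row-resampled copy (no re-validation); used by the bootstrap."""
        return GeneralSurveyTable(self.df.iloc[np.asarray(idx)], validate=False)

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "GeneralSurveyTable":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"general survey CSV not found: {path}")
        df = pd.read_csv(path, dtype={"id": str})
        return cls(df)

    def to_csv(self, path) -> None:
        df = self.df.copy()
        for col in self.name_columns + (["rrt_answer"] if "rrt_answer" in df.columns else []):
            df[col] = df[col].astype("Int64")
        df.to_csv(path, index=False)


# -- operations ----------------------------------------------------------

def mean_known_count(table: GeneralSurveyTable) -> float:
    """Mean over answered rows of the total known-subpopulation alter count (m).

    Unanswered rows are excluded listwise; the exclusion count is logged.
    """
    excluded = table.n - table.n_answered
    if table.n_answered == 0:
        raise ValidationError("no answered rows: cannot compute mean known count")
    if excluded:
        logger.info("mean_known_count: excluded %d unanswered rows of %d", excluded, table.n)
    return float(table.known_row_sums().mean())


def network_size_from_known(m: float, frame: StudyFrame) -> float:
    """Personal network size from the known-population ledger: c = m * t / e0."""
    if m < 0:
        raise ValidationError(f"mean known count must be >= 0, got {m}")
    return m * frame.t / frame.e0


def basic_nsum_estimate(m1: float, c: float, t: int) -> float:
    """Basic scale-up estimate of the hidden-population size: e1 = (m1 / c) * t."""
    if c <= 0:
        raise ValidationError(f"network size c must be > 0, got {c}")
    if m1 < 0:
        logger.warning("basic_nsum_estimate: negative m1 (%.4g) yields a negative estimate", m1)
    return (m1 / c) * t


def per_respondent_network_sizes(table: GeneralSurveyTable, frame: StudyFrame) -> np.ndarray:
    """Diagnostic-only mean-of-ratios variant: c_i = rowsum_i * t / e0 per respondent."""
    return table.known_row_sums() * frame.t / frame.e0


def name_proportion_diagnostic(table, frame: StudyFrame) -> tuple[float, float]:
    """Pearson correlation between reported and actual per-name population shares.

    Compares each name's share of the total reported alters against its
    share of the ledger, N_j / e0.  Works for any table exposing
    ``name_totals()`` and ``labels`` (general survey or RDS table).

    Returns
    -------
    (r, p) : float, float
        Pearson correlation and two-sided p-value.
    """
    if tuple(table.labels) != frame.labels:
        raise ValidationError("table name columns do not match the frame's known subpopulations")
    totals = np.asarray(table.name_totals(), dtype=float)
    if totals.size < 3:
        raise ValidationError("need >= 3 known subpopulations for the correlation diagnostic")
    grand = totals.sum()
    if grand <= 0:
        raise ValidationError("no reported alters: correlation undefined")
    reported_share = totals / grand
    actual_share = np.asarray(frame.sizes, dtype=float) / frame.e0
    if np.ptp(reported_share) == 0 or np.ptp(actual_share) == 0:
        raise ValidationError("constant share vector: correlation undefined")
    r, p = stats.pearsonr(reported_share, actual_share)
    return float(r), float(p)
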