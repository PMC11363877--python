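"""Barrier-effect and transmission-error adjustment of the basic estimate.

Two correction factors come from a survey of the hidden population
itself (sampled by chain referral):

* popularity ratio ``delta`` — mean personal network size of hidden
  members divided by that of the general population; values below 1 mean
  hidden members are under-represented in general-population networks.
* information transmission rate ``tau`` — fraction of a hidden member's
  network that is aware of their membership.

The adjusted size is ``e1 / (delta * tau)`` and the prevalence expresses
it against the adult population.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .scale_up import NAME_PREFIX
from .study_frame import StudyFrame

logger = logging.getLogger("nsum")

AWARE_PREFIX = "aware_"


@dataclass(frozen=True)
class AdjustmentFactors:
    """Popularity ratio and information transmission rate."""

    delta: float
    tau: float

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValidationError(f"popularity ratio delta must be > 0, got {self.delta}")
        if not 0 < self.tau <= 1 + 1e-9:
            raise ValidationError(f"transmission rate tau must be in (0, 1], got {self.tau}")
        if self.delta > 1:
            logger.warning(
                "popularity ratio delta=%.3f exceeds 1 (estimation noise?); proceeding", self.delta
            )


class RDSTable:
    """Hidden-population survey sampled by chain referral, one row per respondent.

    Expected columns: ``id``, ``recruiter_id`` (empty for seeds), ``wave``,
    one ``name_<label>`` and one ``aware_<label>`` column per known
    subpopulation.  The recruitment links must form a forest rooted at the
    wave-0 seeds, and awareness counts can never exceed the alter counts.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.name_columns = [c for c in self.df.columns if c.startswith(NAME_PREFIX)]
        self.aware_columns = [AWARE_PREFIX + c[len(NAME_PREFIX):] for c in self.name_columns]
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.df
        for col in ("id", "recruiter_id", "wave"):
            if col not in df.columns:
                raise ValidationError(f"RDS table missing '{col}' column")
        if not self.name_columns:
            raise ValidationError(f"RDS table has no '{NAME_PREFIX}<label>' columns")
        missing = [c for c in self.aware_columns if c not in df.columns]
        if missing:
            raise ValidationError(f"RDS table missing awareness columns: {missing}")
        if df["id"].isna().any() or df["id"].duplicated().any():
            raise ValidationError("RDS ids must be unique and non-missing")
        waves = df["wave"].to_numpy()
        if (waves < 0).any() or (waves != waves.astype(int)).any():
            raise ValidationError("wave must be a non-negative integer")
        known = df[self.name_columns].to_numpy(dtype=float)
        aware = df[self.aware_columns].to_numpy(dtype=float)
        if np.isnan(known).any() or np.isnan(aware).any():
            raise ValidationError("RDS counts must not be missing")
        if (known < 0).any() or (aware < 0).any():
            raise ValidationError("RDS counts must be non-negative")
        if (aware > known).any():
            bad = int((aware > known).sum())
            raise ValidationError(
                f"aware_counts exceed known_counts in {bad} cells (awareness of an alter "
                "implies the alter is counted)"
            )
        is_seed = df["recruiter_id"].isna()
        if (df.loc[is_seed, "wave"] != 0).any():
            raise ValidationError("seed rows (no recruiter) must have wave 0")
        if (df.loc[~is_seed, "wave"] == 0).any():
            raise ValidationError("wave-0 rows must be seeds (empty recruiter_id)")
        wave_of = dict(zip(df["id"], df["wave"]))
        for rid, recruiter, wave in df.loc[~is_seed, ["id", "recruiter_id", "wave"]].itertuples(
            index=False
        ):
            if recruiter not in wave_of:
                raise ValidationError(f"respondent {rid!r} has dangling recruiter_id {recruiter!r}")
            if wave_of[recruiter] >= wave:
                raise ValidationError(
                    f"respondent {rid!r} (wave {wave}) recruited by {recruiter!r} "
                    f"of wave {wave_of[recruiter]}; recruiter must be from an earlier wave"
                )

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c[len(NAME_PREFIX):] for c in self.name_columns)

    def known_matrix(self) -> np.ndarray:
        return self.df[self.name_columns].to_numpy(dtype=float)

    def aware_matrix(self) -> np.ndarray:
        return self.df[self.aware_columns].to_numpy(dtype=float)

    def known_row_sums(self) -> np.ndarray:
        return self.known_matrix().sum(axis=1)

    def aware_row_sums(self) -> np.ndarray:
        return self.aware_matrix().sum(axis=1)

    def name_totals(self) -> np.ndarray:
        return self.known_matrix().sum(axis=0)

    def recruitment_forest(self) -> tuple[list[int], dict[int, list[int]]]:
        """(seed row positions, children map row position -> recruited row positions)."""
        df = self.df
        pos_of = {rid: i for i, rid in enumerate(df["id"])}
        seeds = [i for i, r in enumerate(df["recruiter_id"]) if pd.isna(r)]
        children: dict[int, list[int]] = {}
        for i, r in enumerate(df["recruiter_id"]):
            if not pd.isna(r):
                children.setdefault(pos_of[r], []).append(i)
        return seeds, children

    def take(self, idx) -> "RDSTable":
        """Row-resampled copy (no re-validation); used by the bootstrap."""
        return RDSTable(self.df.iloc[np.asarray(idx)], validate=False)

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "RDSTable":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"RDS survey CSV not found: {path}")
        df = pd.read_csv(path, dtype={"id": str, "recruiter_id": str})
        return cls(df)

    def to_csv(self, path) -> None:
        df = self.df.copy()
        for col in self.name_columns + self.aware_columns + ["wave"]:
            df[col] = df[col].astype("Int64")
        df.to_csv(path, index=False)


# -- operations ----------------------------------------------------------

def mean_known_rowsum(rds: RDSTable) -> float:
    """Mean per-respondent total known-subpopulation alter count."""
    if rds.n == 0:
        raise ValidationError("empty RDS table")
    return float(rds.known_row_sums().mean())


def mean_aware_rowsum(rds: RDSTable) -> float:
    """Mean per-respondent total aware-alter count."""
    if rds.n == 0:
        raise ValidationError("empty RDS table")
    return float(rds.aware_row_sums().mean())


def hidden_network_size(rds: RDSTable, frame: StudyFrame, weighted: bool = False) -> float:
    """Scale-up estimate of the hidden population's mean network size (c_H).

    Unweighted mean by default; ``weighted=True`` applies an inverse
    degree weight (RDS-II style) using each respondent's known row sum as
    a degree proxy, exposed for sensitivity analysis only.
    """
    rs = rds.known_row_sums()
    if rs.size == 0:
        raise ValidationError("empty RDS table")
    m = _maybe_weighted_mean(rs, rs, weighted)
    return m * frame.t / frame.e0


def aware_network_size(rds: RDSTable, frame: StudyFrame, weighted: bool = False) -> float:
    """Scale-up estimate of the mean number of network members aware of membership."""
    rs = rds.aware_row_sums()
    if rs.size == 0:
        raise ValidationError("empty RDS table")
    m = _maybe_weighted_mean(rs, rds.known_row_sums(), weighted)
    return m * frame.t / frame.e0


def _maybe_weighted_mean(values: np.ndarray, degrees: np.ndarray, weighted: bool) -> float:
    if not weighted:
        return float(values.mean())
    pos = degrees > 0
    if not pos.any():
        return float(values.mean())
    w = 1.0 / degrees[pos]
    return float(np.average(values[pos], weights=w))


def popularity_ratio(c_H: float, c_G: float) -> float:
    """delta = c_H / c_G."""
    if c_G <= 0:
        raise ValidationError(f"general-population network size must be > 0, got {c_G}")
    return c_H / c_G


def transmission_rate(aware: float, c_H: float) -> float:
    """tau = aware / c_H."""
    if c_H <= 0:
        raise ValidationError(f"hidden-population network size must be > 0, got {c_H}")
    return aware / c_H


def adjusted_estimate(e1: float, factors: AdjustmentFactors) -> float:
    """Adjusted hidden-population size: e1 / (delta * tau)."""
    prod = factors.delta * factors.tau
    if prod <= 0:
        raise ValidationError(f"delta * tau must be > 0, got {prod}")
    return e1 / prod


def prevalence(adjusted: float, frame: StudyFrame) -> float:
    """Prevalence among the adult population, in percent."""
    if frame.adult_pop <= 0:
        raise ValidationError("adult_pop must be > 0")
    return 100.0 * adjusted / frame.adult_pop
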