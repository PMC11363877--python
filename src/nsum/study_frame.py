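"""Study frame: population totals and the ledger of known subpopulations.

Every scale-up estimator divides by quantities held here: the total
population ``t``, the adult (15-64) population, and ``e0``, the exact
integer sum of the known-subpopulation sizes.  Known-subpopulation
fractions outside the recommended 0.1-0.2% band are flagged (and logged
as warnings) but never rejected: the band is a recall-bias guideline,
not a hard constraint.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import FrameValidationError

logger = logging.getLogger("nsum")

#: Recommended fraction band for a known subpopulation (size / t).
FRACTION_BAND = (0.001, 0.002)


@dataclass(frozen=True)
class KnownSubpopulation:
    """A subpopulation of known size used to estimate personal network size.

    Parameters
    ----------
    label : str
        Short identifier, e.g. a last name.
    size : int
        Number of people in the subpopulation. Must be positive.
    """

    label: str
    size: int

    def __post_init__(self) -> None:
        if not self.label:
            raise FrameValidationError("known subpopulation label must be non-empty")
        if int(self.size) != self.size or self.size <= 0:
            raise FrameValidationError(
                f"known[{self.label!r}].size must be a positive integer, got {self.size!r}"
            )
        object.__setattr__(self, "size", int(self.size))

    def fraction_of(self, t: int) -> float:
        """Fraction of the total population this subpopulation represents."""
        return self.size / t

    def in_band(self, t: int) -> bool:
        """Whether size/t lies inside the recommended band."""
        lo, hi = FRACTION_BAND
        return lo <= self.size / t <= hi


@dataclass(frozen=True)
class StudyFrame:
    """Demographic frame of the study region.

    Attributes
    ----------
    t : int
        Total (annual average) population of the region.
    adult_pop : int
        Population aged 15-64, the denominator for prevalence.
    known : tuple of KnownSubpopulation
        The known-subpopulation ledger; ``e0`` is the sum of its sizes.
    """

    t: int
    adult_pop: int
    known: tuple[KnownSubpopulation, ...]

    def __post_init__(self) -> None:
        if int(self.t) != self.t or self.t <= 0:
            raise FrameValidationError(f"t must be a positive integer, got {self.t!r}")
        object.__setattr__(self, "t", int(self.t))
        if int(self.adult_pop) != self.adult_pop or not 0 < self.adult_pop <= self.t:
            raise FrameValidationError(
                f"adult_pop must be an integer in (0, t], got {self.adult_pop!r}"
            )
        object.__setattr__(self, "adult_pop", int(self.adult_pop))
        known = tuple(self.known)
        if not known:
            raise FrameValidationError("known subpopulation list must be non-empty")
        object.__setattr__(self, "known", known)
        labels = [k.label for k in known]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise FrameValidationError(f"duplicate known-subpopulation labels: {sorted(dupes)}")
        if not 0 < self.e0 < self.t:
            raise FrameValidationError(
                f"e0 must satisfy 0 < e0 < t; got e0={self.e0}, t={self.t}"
            )
        for viol in self.band_violations():
            logger.warning("study frame: %s", viol)

    @property
    def e0(self) -> int:
        """Exact integer sum of the known-subpopulation sizes."""
        return sum(k.size for k in self.known)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(k.label for k in self.known)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(k.size for k in self.known)

    def band_violations(self) -> list[str]:
        """Human-readable descriptions of subpopulations outside the fraction band."""
        lo, hi = FRACTION_BAND
        out = []
        for k in self.known:
            if not k.in_band(self.t):
                out.append(
                    f"subpopulation {k.label!r} fraction {k.fraction_of(self.t):.5f} "
                    f"outside recommended band [{lo}, {hi}]"
                )
        return out

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "adult_pop": self.adult_pop,
            "known": [{"label": k.label, "size": k.size} for k in self.known],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyFrame":
        for key in ("t", "adult_pop", "known"):
            if key not in d:
                raise FrameValidationError(f"frame config missing required key {key!r}")
        known = []
        for i, entry in enumerate(d["known"]):
            if "label" not in entry or "size" not in entry:
                raise FrameValidationError(f"known[{i}] must have 'label' and 'size' keys")
            known.append(KnownSubpopulation(label=str(entry["label"]), size=entry["size"]))
        return cls(t=d["t"], adult_pop=d["adult_pop"], known=tuple(known))


def load_frame(path) -> StudyFrame:
    """Load and validate a StudyFrame from a YAML or JSON config file.

    The file must provide keys ``t``, ``adult_pop`` and
    ``known: [{label, size}, ...]``.  Extra top-level keys (e.g. ``rrt``,
    ``bootstrap``) are ignored here so one config file can drive the whole
    pipeline.
    """
    path = Path(path)
    if not path.exists():
        raise FrameValidationError(f"frame config not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FrameValidationError(f"frame config must be a mapping, got {type(data).__name__}")
    return StudyFrame.from_dict(data)


def save_frame(frame: StudyFrame, path) -> None:
    """Write a frame to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(frame.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(frame.to_dict(), sort_keys=False))
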