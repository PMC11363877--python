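"""Two-group unrelated-question randomized response technique (quantitative).

Each respondent is assigned to one of two groups.  A respondent in group
``g`` answers the sensitive question with probability ``p_g`` and an
unrelated innocuous question otherwise; only the group label and the
numeric answer are recorded.  With distinct design probabilities the
sensitive mean is recoverable from the two group means::

    mu_s = [(1 - p2) * mean(g1) - (1 - p1) * mean(g2)] / (p1 - p2)

The variance of ``mu_s`` follows from the independence of the two group
means:

    var(mu_s) = [(1 - p2)^2 var(mean g1) + (1 - p1)^2 var(mean g2)] / (p1 - p2)^2

``unmask_mean`` estimates the sensitive mean; ``mask_responses`` applies
the masking for simulation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._util import as_rng
from .exceptions import DesignError, ValidationError

logger = logging.getLogger("nsum")


@dataclass(frozen=True)
class RRTDesign:
    """Design probabilities of the two-group randomized response scheme.

    Parameters
    ----------
    p1, p2 : float
        Probability that a respondent in group 1 (resp. group 2) is asked
        the sensitive question.  Both in [0, 1] and p1 != p2, otherwise the
        unmasking denominator vanishes.
    """

    p1: float
    p2: float

    def __post_init__(self) -> None:
        for name, p in (("p1", self.p1), ("p2", self.p2)):
            if not 0.0 <= p <= 1.0:
                raise DesignError(f"{name} must lie in [0, 1], got {p!r}")
        if self.p1 == self.p2:
            raise DesignError(
                f"degenerate design: p1 == p2 == {self.p1} makes the sensitive mean unidentifiable"
            )


@dataclass(frozen=True)
class RRTResult:
    """Unmasked sensitive mean with its estimated variance.

    ``mu_s`` may be negative in small samples; ``mu_s_floored`` is the
    zero-floored convenience value.  The raw value is never silently
    truncated.
    """

    mu_s: float
    var_mu_s: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.var_mu_s < 0:
            raise ValidationError(f"var_mu_s must be >= 0, got {self.var_mu_s}")
        if self.n1 < 2 or self.n2 < 2:
            raise ValidationError(
                f"each group needs >= 2 respondents for a variance estimate (n1={self.n1}, n2={self.n2})"
            )

    @property
    def mu_s_floored(self) -> float:
        return max(self.mu_s, 0.0)

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_mu_s))


def unmask_mean(answers_g1, answers_g2, design: RRTDesign) -> RRTResult:
    """Estimate the sensitive mean from the two groups' masked answers.

    Parameters
    ----------
    answers_g1, answers_g2 : array-like of float
        Recorded numeric answers of group 1 and group 2 (each >= 2 values).
    design : RRTDesign
        The sensitive-question probabilities of the two groups.

    Returns
    -------
    RRTResult
        Point estimate, variance of the estimate, and group sizes.
    """
    g1 = np.asarray(answers_g1, dtype=float)
    g2 = np.asarray(answers_g2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValidationError(
            f"variance unavailable: each group needs >= 2 answers (got {g1.size}, {g2.size})"
        )
    p1, p2 = design.p1, design.p2
    denom = p1 - p2
    mu1, mu2 = g1.mean(), g2.mean()
    mu_s = ((1 - p2) * mu1 - (1 - p1) * mu2) / denom
    # variance of each group *mean*: sample variance / n
    v1 = g1.var(ddof=1) / g1.size
    v2 = g2.var(ddof=1) / g2.size
    var_mu_s = ((1 - p2) ** 2 * v1 + (1 - p1) ** 2 * v2) / denom**2
    if mu_s < 0:
        logger.warning("RRT unmasked mean is negative (%.4g); reporting raw value", mu_s)
    return RRTResult(mu_s=float(mu_s), var_mu_s=float(var_mu_s), n1=int(g1.size), n2=int(g2.size))


def mask_responses(sensitive, unrelated, group_assignment, design: RRTDesign, seed) -> np.ndarray:
    """Apply randomized-response masking to per-respondent answers.

    Each respondent reports their sensitive value with the probability of
    their group (``design.p1`` for group 1, ``design.p2`` for group 2) and
    their unrelated value otherwise.  Which question was answered is not
    recorded.

    Parameters
    ----------
    sensitive, unrelated : array-like of float
        Aligned per-respondent true answers to the two questions.
    group_assignment : array-like of {1, 2}
        Group label per respondent.
    design : RRTDesign
    seed : int or numpy.random.Generator
        Source of randomness; a fixed int seed gives identical output on
        every run.

    Returns
    -------
    numpy.ndarray of float
        The recorded (masked) answer per respondent.
    """
    s = np.asarray(sensitive, dtype=float)
    u = np.asarray(unrelated, dtype=float)
    g = np.asarray(group_assignment)
    if not (s.shape == u.shape == g.shape):
        raise ValidationError(
            f"length mismatch: sensitive {s.shape}, unrelated {u.shape}, groups {g.shape}"
        )
    bad = ~np.isin(g, (1, 2))
    if bad.any():
        raise ValidationError(f"group_assignment must be 1 or 2; found {np.unique(g[bad])}")
    rng = as_rng(seed)
    p = np.where(g == 1, design.p1, design.p2)
    ask_sensitive = rng.random(s.shape) < p
    return np.where(ask_sensitive, s, u)
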