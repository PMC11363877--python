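"""Bootstrap confidence intervals for the scale-up pipeline.

Three resampling schemes:

* ``bootstrap_general`` — respondent (or whole-cluster) resampling of the
  general-population survey;
* ``rds_chain_bootstrap`` — recruitment-chain bootstrap of the hidden
  population survey: seeds are resampled with replacement, then each
  selected respondent's recruits are resampled with replacement,
  recursively, truncating at the observed maximum wave and sample size.
  This respects the dependence induced by chain referral.  A plain
  respondent bootstrap is available via ``flavor="respondent"``;
* ``joint_pipeline_ci`` — per resample, both surveys are independently
  resampled and the entire estimation chain (including re-unmasking the
  randomized-response answers) is recomputed, so every noise source
  propagates into the composite CIs.

All intervals are percentile intervals.  One master seed spawns an
independent substream per resample, so results are reproducible and
order-independent.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .adjustment import (
    RDSTable,
    popularity_ratio,
    transmission_rate,
)
from .exceptions import BootstrapError, ValidationError
from .rrt import RRTDesign, RRTResult, unmask_mean
from .scale_up import (
    GeneralSurveyTable,
    ScaleUpEstimate,
    basic_nsum_estimate,
    network_size_from_known,
)
from .study_frame import StudyFrame

CHAIN_KEYS = ("m0", "c", "m1", "e1", "c_H", "aware", "delta", "tau", "adjusted", "prevalence")


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap settings: resample count, coverage level, master seed."""

    B: int = 10_000
    level: float = 0.95
    seed: int = 0
    method: str = "percentile"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValidationError(f"B must be >= 1, got {self.B}")
        if not 0 < self.level < 1:
            raise ValidationError(f"level must be in (0, 1), got {self.level}")
        if self.method != "percentile":
            raise ValidationError(f"unsupported CI method {self.method!r}")


def _percentile_ci(samples: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1 - level) / 2
    lo, hi = np.quantile(samples, [alpha, 1 - alpha])
    return float(lo), float(hi)


def _spawn_rngs(seed: int, B: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(B)]


# -- chain arithmetic shared by point estimation and resampling ----------

def estimate_chain(
    m0: float,
    rrt_result: RRTResult,
    rds_known_mean: float,
    rds_aware_mean: float,
    frame: StudyFrame,
) -> dict[str, float]:
    """Full estimation chain from the four survey-level means.

    Returns every intermediate keyed as in ``CHAIN_KEYS``.  Uses the raw
    (possibly negative) unmasked mean; flooring is a reporting concern.
    """
    c = network_size_from_known(m0, frame)
    m1 = rrt_result.mu_s
    e1 = basic_nsum_estimate(m1, c, frame.t)
    scale = frame.t / frame.e0
    c_H = rds_known_mean * scale
    aware = rds_aware_mean * scale
    delta = popularity_ratio(c_H, c)
    tau = transmission_rate(aware, c_H)
    if delta * tau <= 0:
        raise ValidationError(f"delta*tau must be > 0 (delta={delta}, tau={tau})")
    adjusted = e1 / (delta * tau)
    return {
        "m0": m0,
        "c": c,
        "m1": m1,
        "e1": e1,
        "c_H": c_H,
        "aware": aware,
        "delta": delta,
        "tau": tau,
        "adjusted": adjusted,
        "prevalence": 100.0 * adjusted / frame.adult_pop,
    }


# -- general-survey bootstrap --------------------------------------------

def bootstrap_general(
    table: GeneralSurveyTable,
    statistic: Callable[[GeneralSurveyTable], float],
    spec: BootstrapSpec,
    cluster_level: str | None = None,
) -> ScaleUpEstimate:
    """Percentile bootstrap CI of ``statistic`` over the general survey.

    ``cluster_level`` of ``"department"`` or ``"unit"`` resamples whole
    clusters with replacement instead of individual respondents,
    reflecting the clustered sampling design.
    """
    point = float(statistic(table))
    n = table.n
    if cluster_level not in (None, "none"):
        if cluster_level not in table.df.columns:
            raise ValidationError(f"cluster column {cluster_level!r} not in table")
        cluster_ids = table.df[cluster_level].to_numpy()
        clusters = [np.flatnonzero(cluster_ids == c) for c in np.unique(cluster_ids)]
    else:
        clusters = None

    stats = np.empty(spec.B)
    failures = 0
    for b, rng in enumerate(_spawn_rngs(spec.seed, spec.B)):
        if clusters is None:
            idx = rng.integers(0, n, n)
        else:
            picks = rng.integers(0, len(clusters), len(clusters))
            idx = np.concatenate([clusters[k] for k in picks])
        try:
            stats[b] = statistic(table.take(idx))
        except Exception:
            stats[b] = np.nan
            failures += 1
            if failures > max(1, 0.01 * spec.B):
                raise BootstrapError(
                    f"statistic failed on {failures}/{b + 1} resamples (>1%); aborting"
                ) from None
    stats = stats[~np.isnan(stats)]
    lo, hi = _percentile_ci(stats, spec.level)
    return ScaleUpEstimate(point=point, n=n, ci_low=min(lo, point), ci_high=max(hi, point))


# -- recruitment-chain bootstrap -----------------------------------------

def _regrow_forest(
    rng: np.random.Generator,
    seeds: list[int],
    children: dict[int, list[int]],
    max_wave: int,
    n_max: int,
) -> np.ndarray:
    """One chain-bootstrap replicate: row positions with multiplicity."""
    out: list[int] = []
    queue: deque[tuple[int, int]] = deque()
    picked_seeds = rng.integers(0, len(seeds), len(seeds))
    for k in picked_seeds:
        queue.append((seeds[k], 0))
    while queue and len(out) < n_max:
        node, wave = queue.popleft()
        out.append(node)
        kids = children.get(node)
        if kids and wave < max_wave:
            picks = rng.integers(0, len(kids), len(kids))
            for k in picks:
                queue.append((kids[k], wave + 1))
    return np.asarray(out, dtype=int)


def rds_chain_bootstrap(
    rds: RDSTable,
    statistic: Callable[[RDSTable], float],
    spec: BootstrapSpec,
    flavor: str = "chain",
) -> ScaleUpEstimate:
    """Percentile bootstrap CI of ``statistic`` over the hidden-population survey.

    ``flavor="chain"`` regrows the recruitment forest per resample (see
    module docstring); ``flavor="respondent"`` is a plain iid row
    bootstrap fallback.
    """
    if flavor not in ("chain", "respondent"):
        raise ValidationError(f"unknown RDS bootstrap flavor {flavor!r}")
    point = float(statistic(rds))
    n = rds.n
    seeds, children = rds.recruitment_forest()
    max_wave = int(rds.df["wave"].max())

    stats = np.empty(spec.B)
    failures = 0
    for b, rng in enumerate(_spawn_rngs(spec.seed, spec.B)):
        if flavor == "chain":
            idx = _regrow_forest(rng, seeds, children, max_wave, n)
        else:
            idx = rng.integers(0, n, n)
        try:
            stats[b] = statistic(rds.take(idx))
        except Exception:
            stats[b] = np.nan
            failures += 1
            if failures > max(1, 0.01 * spec.B):
                raise BootstrapError(
                    f"statistic failed on {failures}/{b + 1} resamples (>1%); aborting"
                ) from None
    stats = stats[~np.isnan(stats)]
    lo, hi = _percentile_ci(stats, spec.level)
    return ScaleUpEstimate(point=point, n=n, ci_low=min(lo, point), ci_high=max(hi, point))


# -- joint pipeline bootstrap --------------------------------------------

def joint_pipeline_ci(
    general: GeneralSurveyTable,
    rds: RDSTable,
    frame: StudyFrame,
    design: RRTDesign,
    spec: BootstrapSpec,
    rds_flavor: str = "chain",
) -> dict[str, ScaleUpEstimate]:
    """Bootstrap the entire estimation chain, resampling both surveys.

    Per resample the general survey is resampled at respondent level, the
    hidden-population survey by the recruitment-chain bootstrap, and every
    quantity in ``CHAIN_KEYS`` recomputed — including re-unmasking the
    randomized-response answers, so masking noise reaches all downstream
    CIs.  Returns one ``ScaleUpEstimate`` per chain quantity.
    """
    # point estimates
    g_group, g_answer = general.rrt_arrays()
    rrt_point = unmask_mean(g_answer[g_group == 1], g_answer[g_group == 2], design)
    point = estimate_chain(
        float(general.known_row_sums().mean()),
        rrt_point,
        float(rds.known_row_sums().mean()),
        float(rds.aware_row_sums().mean()),
        frame,
    )

    # precomputed arrays for fast resampling
    g_rowsums = general.known_row_sums()
    n_g = g_rowsums.size
    r_known = rds.known_row_sums()
    r_aware = rds.aware_row_sums()
    n_r = r_known.size
    seeds, children = rds.recruitment_forest()
    max_wave = int(rds.df["wave"].max())
    scale = frame.t / frame.e0
    p1, p2 = design.p1, design.p2
    denom = p1 - p2

    draws = {k: np.empty(spec.B) for k in CHAIN_KEYS}
    failures = 0
    for b, rng in enumerate(_spawn_rngs(spec.seed, spec.B)):
        gi = rng.integers(0, n_g, n_g)
        if rds_flavor == "chain":
            ri = _regrow_forest(rng, seeds, children, max_wave, n_r)
        else:
            ri = rng.integers(0, n_r, n_r)
        grp = g_group[gi]
        ans = g_answer[gi]
        a1, a2 = ans[grp == 1], ans[grp == 2]
        if a1.size < 2 or a2.size < 2 or ri.size == 0:
            for k in CHAIN_KEYS:
                draws[k][b] = np.nan
            failures += 1
            if failures > max(1, 0.01 * spec.B):
                raise BootstrapError(f"chain failed on {failures}/{b + 1} resamples; aborting")
            continue
        m0 = g_rowsums[gi].mean()
        m1 = ((1 - p2) * a1.mean() - (1 - p1) * a2.mean()) / denom
        c = m0 * scale
        e1 = (m1 / c) * frame.t
        c_H = r_known[ri].mean() * scale
        aware = r_aware[ri].mean() * scale
        delta = c_H / c
        tau = aware / c_H if c_H > 0 else np.nan
        adjusted = e1 / (delta * tau) if delta * tau else np.nan
        vals = (m0, c, m1, e1, c_H, aware, delta, tau, adjusted,
                100.0 * adjusted / frame.adult_pop)
        for k, v in zip(CHAIN_KEYS, vals):
            draws[k][b] = v

    out: dict[str, ScaleUpEstimate] = {}
    n_total = general.n_answered + rds.n
    for k in CHAIN_KEYS:
        samples = draws[k][~np.isnan(draws[k])]
        lo, hi = _percentile_ci(samples, spec.level)
        pt = point[k]
        out[k] = ScaleUpEstimate(point=pt, n=n_total, ci_low=min(lo, pt), ci_high=max(hi, pt))
    return out
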