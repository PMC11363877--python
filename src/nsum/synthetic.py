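"""Synthetic survey generator with fully specified ground truth.

Generates both survey tables from the implied marginal count
distributions (no explicit social graph over the whole population):

* general survey — respondent degrees are overdispersed counts
  (negative-binomial with mean ``c_true`` and dispersion
  ``degree_dispersion``; infinite dispersion degenerates to Poisson);
  known-subpopulation counts are Binomial(d_i, N_j/t); the *visible*
  hidden-alter count is Binomial(d_i, (N_H/t) * delta_true * tau_true) —
  barrier and transmission effects are applied at the tie level, the
  model under which the multiplicative adjustment is exactly unbiased;
  answers are then masked by the randomized-response design and a
  ``nonresponse_rate`` fraction of sheets is blanked.
* hidden-population survey — members have degrees of mean
  ``c_true * delta_true``; a recruitment forest is grown from seeds with
  a fixed coupon count; awareness counts thin the known counts by
  ``tau_true``.

Everything is deterministic given the seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import as_rng
from .adjustment import RDSTable
from .exceptions import ValidationError
from .rrt import RRTDesign, mask_responses
from .scale_up import NAME_PREFIX, GeneralSurveyTable
from .study_frame import KnownSubpopulation, StudyFrame, save_frame

#: Region totals mirroring the study setting, used by default_frame().
DEFAULT_T = 4_531_429
DEFAULT_ADULT_POP = 2_820_541


def default_frame(n_names: int = 48, seed: int = 0, t: int = DEFAULT_T,
                  adult_pop: int = DEFAULT_ADULT_POP) -> StudyFrame:
    """A frame with ``n_names`` known subpopulations inside the 0.1-0.2% band."""
    rng = as_rng(seed)
    sizes = rng.integers(int(0.001 * t), int(0.002 * t) + 1, n_names)
    known = tuple(
        KnownSubpopulation(label=f"N{i + 1:02d}", size=int(s)) for i, s in enumerate(sizes)
    )
    return StudyFrame(t=t, adult_pop=adult_pop, known=known)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of a synthetic world."""

    frame: StudyFrame
    N_H: int
    c_true: float = 120.0
    delta_true: float = 1.0
    tau_true: float = 1.0
    degree_dispersion: float = 3.0
    mu_unrelated: float = 20.0
    nonresponse_rate: float = 0.063

    def __post_init__(self) -> None:
        if not 0 <= self.N_H < self.frame.t:
            raise ValidationError(f"N_H must lie in [0, t), got {self.N_H}")
        if self.c_true <= 0:
            raise ValidationError(f"c_true must be > 0, got {self.c_true}")
        if not 0 < self.delta_true <= 1:
            raise ValidationError(f"delta_true must be in (0, 1], got {self.delta_true}")
        if not 0 < self.tau_true <= 1:
            raise ValidationError(f"tau_true must be in (0, 1], got {self.tau_true}")
        if self.degree_dispersion <= 0:
            raise ValidationError("degree_dispersion must be > 0 (use numpy.inf for Poisson)")
        if self.mu_unrelated < 0:
            raise ValidationError("mu_unrelated must be >= 0")
        if not 0 <= self.nonresponse_rate < 1:
            raise ValidationError("nonresponse_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "N_H": self.N_H,
            "c_true": self.c_true,
            "delta_true": self.delta_true,
            "tau_true": self.tau_true,
            "degree_dispersion": self.degree_dispersion,
            "mu_unrelated": self.mu_unrelated,
            "nonresponse_rate": self.nonresponse_rate,
        }


def _draw_degrees(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    if not np.isfinite(dispersion):
        return rng.poisson(mean, n)
    # negative binomial with mean `mean` and variance mean + mean^2/dispersion
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, n)


def truth_report(truth: SyntheticTruth) -> dict[str, float]:
    """Implied target values for every pipeline quantity, for recovery tests."""
    f = truth.frame
    dt = truth.delta_true * truth.tau_true
    return {
        "N_H": float(truth.N_H),
        "c_true": truth.c_true,
        "c_hidden": truth.c_true * truth.delta_true,
        "delta_true": truth.delta_true,
        "tau_true": truth.tau_true,
        "m0_expected": truth.c_true * f.e0 / f.t,
        "m1_expected": truth.c_true * (truth.N_H / f.t) * dt,
        "basic_target": float(truth.N_H) * dt,
        "adjusted_target": float(truth.N_H),
        "prevalence": 100.0 * truth.N_H / f.adult_pop,
    }


def generate_general_survey(
    truth: SyntheticTruth,
    n: int,
    design: RRTDesign,
    seed,
    n_industries: int = 20,
    n_units: int = 36,
    n_departments: int = 83,
) -> GeneralSurveyTable:
    """Simulate the general-population survey at respondent level.

    Cluster labels (industry > unit > department) are exchangeable by
    default — they carry no between-cluster effect but let the cluster
    bootstrap be exercised.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = as_rng(seed)
    f = truth.frame
    p_names = np.asarray(f.sizes, dtype=float) / f.t
    p_hidden = (truth.N_H / f.t) * truth.delta_true * truth.tau_true

    degrees = _draw_degrees(rng, n, truth.c_true, truth.degree_dispersion)
    known = rng.binomial(degrees[:, None], p_names[None, :])
    hidden_visible = rng.binomial(degrees, p_hidden)
    unrelated = rng.poisson(truth.mu_unrelated, n)
    group = rng.integers(1, 3, n)
    masked = mask_responses(hidden_visible, unrelated, group, design, rng)
    blank = rng.random(n) < truth.nonresponse_rate

    dept = rng.integers(0, n_departments, n)
    unit = dept % n_units
    industry = unit % n_industries

    df = pd.DataFrame({
        "id": [f"g{i + 1:05d}" for i in range(n)],
        "industry": [f"I{k + 1:02d}" for k in industry],
        "unit": [f"U{k + 1:02d}" for k in unit],
        "department": [f"D{k + 1:02d}" for k in dept],
    })
    known = known.astype(float)
    masked = masked.astype(float)
    known[blank] = np.nan
    masked[blank] = np.nan
    for j, label in enumerate(f.labels):
        df[NAME_PREFIX + label] = known[:, j]
    df["rrt_group"] = group
    df["rrt_answer"] = masked
    df["answered"] = ~blank
    return GeneralSurveyTable(df)


def generate_rds_survey(
    truth: SyntheticTruth,
    n_target: int = 302,
    n_seeds: int = 2,
    coupons: int = 3,
    max_wave: int = 8,
    seed=0,
    recruit_prob: float = 0.7,
    degree_proportional: bool = False,
    max_attempts: int = 20,
) -> RDSTable:
    """Simulate the hidden-population survey with a recruitment forest.

    Each respondent redeems Binomial(coupons, recruit_prob) coupons on
    distinct not-yet-recruited members; growth stops when ``n_target``
    respondents are enrolled or every chain passes ``max_wave``.  If the
    forest dies out short of ``n_target``, growth restarts with a fresh
    substream (deterministically, up to ``max_attempts``) — mirroring the
    field practice of seeding new chains when referral stalls.
    """
    if not 1 <= n_seeds <= n_target:
        raise ValidationError(f"need n_target >= n_seeds >= 1, got {n_target}, {n_seeds}")
    if truth.N_H < n_target:
        raise ValidationError(
            f"hidden population N_H={truth.N_H} smaller than target sample {n_target}"
        )
    if isinstance(seed, np.random.Generator):
        streams = [seed] * max_attempts  # reuse the caller's stream across attempts
    else:
        streams = np.random.SeedSequence(seed).spawn(max_attempts)
    last = None
    for stream in streams:
        rng = as_rng(stream)
        table = _grow_rds(truth, n_target, n_seeds, coupons, max_wave, rng,
                          recruit_prob, degree_proportional)
        last = table
        if table.n == n_target:
            return table
    raise ValidationError(
        f"recruitment stalled at {last.n}/{n_target} respondents after "
        f"{max_attempts} attempts; raise recruit_prob or max_wave"
    )


def _grow_rds(truth, n_target, n_seeds, coupons, max_wave, rng,
              recruit_prob, degree_proportional) -> RDSTable:
    f = truth.frame
    N_H = truth.N_H
    # degrees drawn lazily for sampled members only, unless recruitment is
    # degree-proportional (then the whole hidden population needs them)
    all_degrees = (
        _draw_degrees(rng, N_H, truth.c_true * truth.delta_true, truth.degree_dispersion)
        if degree_proportional else None
    )

    pool = rng.permutation(N_H)
    pool_pos = n_seeds  # next unrecruited index into `pool`
    members: list[int] = list(pool[:n_seeds])
    recruiter: list[int] = [-1] * n_seeds
    wave: list[int] = [0] * n_seeds
    frontier = list(range(n_seeds))
    w = 0
    while frontier and w < max_wave and len(members) < n_target:
        w += 1
        next_frontier: list[int] = []
        for parent in frontier:
            if len(members) >= n_target:
                break
            n_rec = rng.binomial(coupons, recruit_prob)
            for _ in range(n_rec):
                if len(members) >= n_target or pool_pos >= N_H:
                    break
                if degree_proportional:
                    remaining = pool[pool_pos:]
                    wts = all_degrees[remaining].astype(float) + 1e-9
                    k = rng.choice(remaining.size, p=wts / wts.sum())
                    pool[[pool_pos, pool_pos + k]] = pool[[pool_pos + k, pool_pos]]
                new = pool[pool_pos]
                pool_pos += 1
                members.append(new)
                recruiter.append(parent)
                wave.append(w)
                next_frontier.append(len(members) - 1)
        frontier = next_frontier

    n = len(members)
    if degree_proportional:
        degrees = all_degrees[np.asarray(members)]
    else:
        degrees = _draw_degrees(rng, n, truth.c_true * truth.delta_true,
                                truth.degree_dispersion)
    p_names = np.asarray(f.sizes, dtype=float) / f.t
    known = rng.binomial(degrees[:, None], p_names[None, :])
    aware = rng.binomial(known, truth.tau_true)

    ids = [f"r{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame({
        "id": ids,
        "recruiter_id": [ids[r] if r >= 0 else None for r in recruiter],
        "wave": wave,
    })
    for j, label in enumerate(f.labels):
        df[NAME_PREFIX + label] = known[:, j]
    for j, label in enumerate(f.labels):
        df["aware_" + label] = aware[:, j]
    return RDSTable(df)


def write_world(
    truth: SyntheticTruth,
    out_dir,
    design: RRTDesign,
    n_general: int = 1747,
    seed: int = 0,
    rds_kwargs: dict | None = None,
) -> dict[str, Path]:
    """Generate one synthetic world and write it as plain-text artifacts.

    Writes ``general_survey.csv``, ``rds_survey.csv``, ``frame.yaml`` and
    ``truth.json`` into ``out_dir``; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_gen, s_rds = ss.spawn(2)
    general = generate_general_survey(truth, n_general, design, np.random.default_rng(s_gen))
    rds = generate_rds_survey(truth, seed=int(s_rds.generate_state(1)[0]),
                              **(rds_kwargs or {}))
    paths = {
        "general": out / "general_survey.csv",
        "rds": out / "rds_survey.csv",
        "frame": out / "frame.yaml",
        "truth": out / "truth.json",
    }
    general.to_csv(paths["general"])
    rds.to_csv(paths["rds"])
    frame_dict = truth.frame.to_dict()
    frame_dict["rrt"] = {"p1": design.p1, "p2": design.p2}
    import yaml as _yaml
    paths["frame"].write_text(_yaml.safe_dump(frame_dict, sort_keys=False))
    report = {"truth": truth.to_dict(), "targets": truth_report(truth), "seed": seed}
    paths["truth"].write_text(json.dumps(report, indent=2) + "\n")
    return paths
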