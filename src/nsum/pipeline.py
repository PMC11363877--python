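"""End-to-end orchestration and the printed-value replication mode."""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .adjustment import RDSTable
from .exceptions import ValidationError
from .rrt import RRTDesign, unmask_mean
from .scale_up import GeneralSurveyTable, name_proportion_diagnostic
from .study_frame import StudyFrame, load_frame
from .uncertainty import CHAIN_KEYS, BootstrapSpec, joint_pipeline_ci

logger = logging.getLogger("nsum")


@dataclass
class RunReport:
    """Complete machine-readable result of one estimation run."""

    version: str
    seed: int
    config: dict
    digest: dict
    estimates: dict  # key -> {point, ci_low, ci_high}
    diagnostics: dict
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "digest": self.digest,
            "estimates": self.estimates,
            "diagnostics": self.diagnostics,
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2) + "\n"

    def to_text(self) -> str:
        lines = [f"nsum estimation report (v{self.version}, seed={self.seed})", ""]
        d = self.digest
        lines.append(
            f"general survey: {d['n_general']} rows, {d['n_general_excluded']} blank sheets excluded"
        )
        lines.append(f"hidden-population survey: {d['n_rds']} rows")
        lines.append("")
        lines.append(f"{'quantity':<12}{'estimate':>14}{'95% CI':>28}")
        for key, est in self.estimates.items():
            if est["ci_low"] is None:
                ci = "-"
            else:
                ci = f"[{est['ci_low']:.4g}, {est['ci_high']:.4g}]"
            lines.append(f"{key:<12}{est['point']:>14.4g}{ci:>28}")
        lines.append("")
        r = self.diagnostics.get("name_proportion_r")
        p = self.diagnostics.get("name_proportion_p")
        if r is not None:
            lines.append(f"name-proportion diagnostic (hidden survey): r={r:.3f}, p={p:.3g}")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines) + "\n"

    def write(self, out_dir) -> tuple[Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        jpath, tpath = out / "report.json", out / "report.txt"
        jpath.write_text(self.to_json())
        tpath.write_text(self.to_text())
        return jpath, tpath


def _load_config(frame_config) -> tuple[StudyFrame, dict]:
    """Load the frame plus the raw config dict (for rrt/bootstrap keys)."""
    frame = load_frame(frame_config)
    text = Path(frame_config).read_text()
    raw = json.loads(text) if str(frame_config).endswith(".json") else yaml.safe_load(text)
    return frame, raw if isinstance(raw, dict) else {}


def run_estimate(
    general_csv,
    rds_csv,
    frame_config,
    seed: int = 0,
    B: int = 10_000,
    level: float = 0.95,
    design: RRTDesign | None = None,
    rds_flavor: str = "chain",
) -> RunReport:
    """Run the full estimation chain with joint-bootstrap CIs.

    The RRT design is taken from ``design`` if given, else from the
    config's ``rrt.p1``/``rrt.p2`` keys.  Any stage failure aborts with a
    stage-labeled error; a returned report is always complete.
    """
    warnings: list[str] = []
    try:
        frame, raw = _load_config(frame_config)
    except ValidationError as e:
        raise ValidationError(f"[frame] {e}") from e
    warnings.extend(frame.band_violations())

    if design is None:
        rrt_cfg = raw.get("rrt", {})
        if "p1" not in rrt_cfg or "p2" not in rrt_cfg:
            raise ValidationError(
                "[frame] config lacks rrt.p1/rrt.p2 and no design was supplied"
            )
        design = RRTDesign(p1=float(rrt_cfg["p1"]), p2=float(rrt_cfg["p2"]))

    try:
        general = GeneralSurveyTable.from_csv(general_csv)
    except ValidationError as e:
        raise ValidationError(f"[general] {e}") from e
    try:
        rds = RDSTable.from_csv(rds_csv)
    except ValidationError as e:
        raise ValidationError(f"[rds] {e}") from e
    if tuple(general.labels) != frame.labels or tuple(rds.labels) != frame.labels:
        raise ValidationError("[estimate] survey name columns do not match the frame's ledger")

    try:
        spec = BootstrapSpec(B=B, level=level, seed=seed)
        estimates = joint_pipeline_ci(general, rds, frame, design, spec, rds_flavor=rds_flavor)
        grp, ans = general.rrt_arrays()
        rrt_res = unmask_mean(ans[grp == 1], ans[grp == 2], design)
        r, p = name_proportion_diagnostic(rds, frame)
        r_gen, p_gen = name_proportion_diagnostic(general, frame)
    except ValidationError as e:
        raise ValidationError(f"[estimate] {e}") from e

    if rrt_res.mu_s < 0:
        warnings.append(
            f"RRT-unmasked mean is negative ({rrt_res.mu_s:.4g}); floored value "
            f"{rrt_res.mu_s_floored} reported alongside"
        )
    if estimates["delta"].point > 1:
        warnings.append(f"popularity ratio exceeds 1 ({estimates['delta'].point:.3f})")

    est_dict = {
        k: {"point": v.point, "ci_low": v.ci_low, "ci_high": v.ci_high}
        for k, v in estimates.items()
    }
    est_dict["m1_floored"] = {
        "point": rrt_res.mu_s_floored, "ci_low": None, "ci_high": None,
    }
    return RunReport(
        version=__version__,
        seed=seed,
        config={
            "frame": str(frame_config),
            "t": frame.t,
            "adult_pop": frame.adult_pop,
            "e0": frame.e0,
            "n_known": len(frame.known),
            "rrt": {"p1": design.p1, "p2": design.p2},
            "bootstrap": {"B": B, "level": level, "rds_flavor": rds_flavor},
        },
        digest={
            "n_general": general.n,
            "n_general_excluded": general.n - general.n_answered,
            "n_rds": rds.n,
        },
        estimates=est_dict,
        diagnostics={
            "name_proportion_r": r,
            "name_proportion_p": p,
            "name_proportion_r_general": r_gen,
            "name_proportion_p_general": p_gen,
            "rrt_var_mu_s": rrt_res.var_mu_s,
        },
        warnings=warnings,
    )


# -- replication of the published arithmetic chain -----------------------

#: Values as printed in the source study's results.
PRINTED = {
    "t": 4_531_429,
    "e0": 302_251,
    "adult_pop": 2_820_541,
    "m0": 8.3,
    "m1": 1.6e-2,
    "c": 123.9,
    "rds_known_mean": 4.4,
    "rds_aware_mean": 3.9,
    "c_H": 66.3,
    "aware": 58.5,
    "e1": 585.1,
    "delta": 0.536,
    "tau": 0.879,
    "adjusted": 1241.9,
    "prevalence": 4.4e-2,
}


@dataclass(frozen=True)
class ReplicationRow:
    quantity: str
    printed: float
    recomputed: float
    formula: str
    digits: int
    matches_printed: bool


def replicate_paper() -> list[ReplicationRow]:
    """Recompute each downstream printed value from printed upstream values.

    Some printed inputs are too coarsely rounded to reproduce their
    printed outputs exactly (the source mixes rounded and unrounded
    intermediates); those rows carry ``matches_printed=False`` and both
    values, by design.
    """
    P = PRINTED
    rows: list[ReplicationRow] = []

    def add(quantity, recomputed, formula, digits=1):
        rec = round(recomputed, digits)
        rows.append(ReplicationRow(
            quantity=quantity,
            printed=P[quantity],
            recomputed=rec,
            formula=formula,
            digits=digits,
            matches_printed=abs(rec - round(P[quantity], digits)) < 10.0 ** (-digits) / 2,
        ))

    add("c", P["m0"] * P["t"] / P["e0"], "m0*t/e0")
    add("e1", (P["m1"] / P["c"]) * P["t"], "(m1/c)*t")
    add("c_H", P["rds_known_mean"] * P["t"] / P["e0"], "mean_known*t/e0")
    add("aware", P["rds_aware_mean"] * P["t"] / P["e0"], "mean_aware*t/e0")
    add("delta", P["c_H"] / P["c"], "c_H/c", digits=3)
    add("tau", P["aware"] / P["c_H"], "aware/c_H", digits=3)
    add("adjusted", P["e1"] / (P["delta"] * P["tau"]), "e1/(delta*tau)")
    add("prevalence", 100.0 * P["adjusted"] / P["adult_pop"], "100*adjusted/adult_pop", digits=3)
    return rows


def replication_text(rows: list[ReplicationRow] | None = None) -> str:
    rows = replicate_paper() if rows is None else rows
    lines = [
        "replication of the published arithmetic chain",
        "(recomputed from printed upstream values; mismatches reflect the",
        " source's own rounding of intermediates, both values shown)",
        "",
        f"{'quantity':<12}{'printed':>12}{'recomputed':>12}  {'formula':<24}{'match'}",
    ]
    for r in rows:
        lines.append(
            f"{r.quantity:<12}{r.printed:>12g}{r.recomputed:>12g}  {r.formula:<24}"
            f"{'yes' if r.matches_printed else 'NO (input rounding)'}"
        )
    return "\n".join(lines) + "\n"
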