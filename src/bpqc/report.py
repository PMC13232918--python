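"""End-to-end audit pipeline producing the JSON audit report.

Runs every data-quality check over a validated visit table, stratified the
way auditors read such data: per cohort and pooled, on raw readings and on
protocol-averaged visit values, for each measure (systolic, diastolic).
"""

from __future__ import annotations

import importlib.metadata
from dataclasses import dataclass, field

import pandas as pd

from . import averaging, digits, segmented, spike
from .io_model import ALPHA, ValidationReport, validate_visits


def _version() -> str:
    try:
        return importlib.metadata.version("bpqc")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


@dataclass
class AuditConfig:
    """Knobs of the audit pipeline, recorded verbatim in the provenance block."""

    sbp_threshold: int = 140
    dbp_threshold: int = 90
    spike_targets: tuple[int, ...] = (62,)
    alpha: float = ALPHA
    expected_digit: float = 0.10
    window_halfwidth: int = segmented.DEFAULT_WINDOW
    discordance_rule: str = "either"
    rounding: str = "none"
    half_policy: str = "denominator"
    ci_level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "sbp_threshold": self.sbp_threshold,
            "dbp_threshold": self.dbp_threshold,
            "spike_targets": list(self.spike_targets),
            "alpha": self.alpha,
            "expected_digit": self.expected_digit,
            "window_halfwidth": self.window_halfwidth,
            "discordance_rule": self.discordance_rule,
            "rounding": self.rounding,
            "half_policy": self.half_policy,
            "ci_level": self.ci_level,
        }


def _digit_section(vt_raw: pd.DataFrame, averaged: pd.DataFrame, cfg: AuditConfig) -> dict:
    out = {}
    cohorts = sorted(vt_raw["cohort_id"].unique()) if len(vt_raw) else []
    for stage, frame, cols in (
        ("raw", vt_raw, {"sbp": "sbp", "dbp": "dbp"}),
        ("averaged", averaged, {"sbp": "sbp_avg", "dbp": "dbp_avg"}),
    ):
        for measure in ("sbp", "dbp"):
            for cohort in [*cohorts, "pooled"]:
                vals = (
                    frame[cols[measure]]
                    if cohort == "pooled"
                    else frame.loc[frame["cohort_id"] == cohort, cols[measure]]
                )
                res = digits.digit_preference_audit(
                    vals,
                    alpha=cfg.alpha,
                    expected=cfg.expected_digit,
                    half_policy=cfg.half_policy,
                )
                out[f"{stage}/{measure}/{cohort}"] = res.to_dict()
    return out


def _spike_section(vt_raw: pd.DataFrame, averaged: pd.DataFrame, cfg: AuditConfig) -> dict:
    out = {}
    cohorts = sorted(vt_raw["cohort_id"].unique()) if len(vt_raw) else []
    for target in cfg.spike_targets:
        for cohort in [*cohorts, "pooled"]:
            raw_v = (
                vt_raw["dbp"] if cohort == "pooled"
                else vt_raw.loc[vt_raw["cohort_id"] == cohort, "dbp"]
            )
            avg_v = (
                averaged["dbp_avg"] if cohort == "pooled"
                else averaged.loc[averaged["cohort_id"] == cohort, "dbp_avg"]
            )
            if len(raw_v) == 0 or len(avg_v) == 0:
                out[f"dbp={target}/{cohort}"] = {"error": "empty stratum"}
                continue
            res = spike.spike_audit(raw_v, avg_v, target=target, level=cfg.ci_level)
            out[f"dbp={target}/{cohort}"] = res.to_dict()
    return out


def run_audit(
    vt: pd.DataFrame,
    config: AuditConfig | None = None,
    input_path: str | None = None,
    seed: int | None = None,
    validation: ValidationReport | None = None,
) -> dict:
    """Run the complete audit over a visit table and return the report dict.

    ``vt`` may be raw (it is validated here) or already validated (pass the
    earlier :class:`ValidationReport` through ``validation`` to keep its
    tallies in the provenance).  The returned dict serialises with
    :func:`bpqc.io_model.write_audit_report`.
    """
    cfg = config or AuditConfig()
    if validation is None:
        vt, validation = validate_visits(vt)
    averaged = averaging.apply_protocol(vt, rule=cfg.discordance_rule, rounding=cfg.rounding)
    report = {
        "provenance": {
            "package": "bpqc",
            "version": _version(),
            "input_path": input_path,
            "seed": seed,
            "config": cfg.to_dict(),
        },
        "validation": validation.to_dict(),
        "averaging": {
            "n_visits": int(len(averaged)),
            "triplicate_fraction": averaging.triplicate_fraction(averaged),
            "protocol_violations": int(averaged["protocol_violation"].sum()) if len(averaged) else 0,
        },
        "differences": averaging.pairwise_difference_summary(vt).to_dict(),
        "digit_preference": _digit_section(vt, averaged, cfg),
        "spike_artifact": _spike_section(vt, averaged, cfg),
        "threshold_behavior": segmented.classify_all(
            vt,
            averaged,
            thresholds={"sbp": cfg.sbp_threshold, "dbp": cfg.dbp_threshold},
            alpha=cfg.alpha,
            window_halfwidth=cfg.window_halfwidth,
        ),
    }
    return report
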