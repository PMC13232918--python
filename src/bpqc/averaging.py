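"""Repeat-reading triage and the visit averaging protocol.

The measurement protocol behind the audits: each visit records two readings;
if they differ by more than 10 mm Hg a third reading is requested, and the
visit value is the mean of readings 2 and 3, otherwise the mean of readings
1 and 2.  Averages of two integers are exact multiples of 0.5 mm Hg and are
not rounded by default, because the terminal-digit audits downstream depend
on whether half-integers are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import VISIT_KEY

#: Discordance threshold (mm Hg) that triggers a third reading; strict
#: inequality — a difference of exactly 10 does not trigger.
DISCORDANCE_MM_HG = 10

#: Difference pairs summarised by :func:`pairwise_difference_summary`.
DIFF_PAIRS = ((1, 2), (1, 3), (2, 3))


def requires_third_reading(
    r1: tuple[int, int],
    r2: tuple[int, int],
    rule: str = "either",
    limit: int = DISCORDANCE_MM_HG,
) -> bool:
    """Whether readings 1 and 2 are discordant enough to demand a third.

    ``r1``/``r2`` are ``(sbp, dbp)`` pairs.  ``rule`` selects which
    component(s) the >10 mm Hg criterion applies to: ``"either"`` (default,
    most conservative — triggers most often), ``"sbp_only"``, or ``"both"``.
    """
    ds = abs(r1[0] - r2[0])
    dd = abs(r1[1] - r2[1])
    if rule == "either":
        return ds > limit or dd > limit
    if rule == "sbp_only":
        return ds > limit
    if rule == "both":
        return ds > limit and dd > limit
    raise ValueError(f"unknown discordance rule {rule!r}")


def _round_avg(x: np.ndarray, rounding: str) -> np.ndarray:
    if rounding == "none":
        return x
    if rounding == "half_up":
        return np.floor(x + 0.5)
    if rounding == "half_even":
        return np.round(x)
    raise ValueError(f"unknown rounding mode {rounding!r}")


def visit_average(readings: pd.DataFrame, rule: str = "either", rounding: str = "none") -> dict:
    """Average one validated visit (2 or 3 rows, sorted by reading index).

    Two readings: mean of 1 and 2.  Three readings: mean of 2 and 3.
    Returns a dict with ``sbp_avg``, ``dbp_avg``, ``used`` (pair of reading
    indices), ``triplicate`` and ``protocol_violation`` (two discordant
    readings with no third).
    """
    n = len(readings)
    if n not in (2, 3):
        raise ValueError(f"visit must have 2 or 3 readings, got {n}")
    readings = readings.sort_values("reading_index")
    sbp = readings["sbp"].to_numpy(dtype=float)
    dbp = readings["dbp"].to_numpy(dtype=float)
    if n == 3:
        used = (2, 3)
        sa, da = (sbp[1] + sbp[2]) / 2.0, (dbp[1] + dbp[2]) / 2.0
        violation = False
    else:
        used = (1, 2)
        sa, da = (sbp[0] + sbp[1]) / 2.0, (dbp[0] + dbp[1]) / 2.0
        violation = requires_third_reading((sbp[0], dbp[0]), (sbp[1], dbp[1]), rule=rule)
    sa = float(_round_avg(np.asarray(sa), rounding))
    da = float(_round_avg(np.asarray(da), rounding))
    return {
        "sbp_avg": sa,
        "dbp_avg": da,
        "used": used,
        "triplicate": n == 3,
        "protocol_violation": violation,
    }


def apply_protocol(vt: pd.DataFrame, rule: str = "either", rounding: str = "none") -> pd.DataFrame:
    """Average every visit of a validated visit table.

    Vectorised equivalent of mapping :func:`visit_average` over visits.
    Returns one row per visit with columns ``cohort_id``, ``participant_id``,
    ``visit_id``, ``sbp_avg``, ``dbp_avg``, ``triplicate``,
    ``protocol_violation``.  Row order of the input never changes the result:
    grouping is by visit key and reading index.
    """
    if vt.empty:
        return pd.DataFrame(
            columns=VISIT_KEY + ["sbp_avg", "dbp_avg", "triplicate", "protocol_violation"]
        )
    wide = (
        vt.pivot_table(
            index=VISIT_KEY, columns="reading_index", values=["sbp", "dbp"], aggfunc="first"
        )
    )
    s1 = wide[("sbp", 1)].to_numpy(dtype=float)
    s2 = wide[("sbp", 2)].to_numpy(dtype=float)
    d1 = wide[("dbp", 1)].to_numpy(dtype=float)
    d2 = wide[("dbp", 2)].to_numpy(dtype=float)
    if ("sbp", 3) in wide.columns:
        s3 = wide[("sbp", 3)].to_numpy(dtype=float)
        d3 = wide[("dbp", 3)].to_numpy(dtype=float)
    else:
        s3 = np.full_like(s1, np.nan)
        d3 = np.full_like(d1, np.nan)
    trip = ~np.isnan(s3)
    sbp_avg = np.where(trip, (s2 + s3) / 2.0, (s1 + s2) / 2.0)
    dbp_avg = np.where(trip, (d2 + d3) / 2.0, (d1 + d2) / 2.0)
    ds = np.abs(s1 - s2)
    dd = np.abs(d1 - d2)
    if rule == "either":
        discord = (ds > DISCORDANCE_MM_HG) | (dd > DISCORDANCE_MM_HG)
    elif rule == "sbp_only":
        discord = ds > DISCORDANCE_MM_HG
    elif rule == "both":
        discord = (ds > DISCORDANCE_MM_HG) & (dd > DISCORDANCE_MM_HG)
    else:
        raise ValueError(f"unknown discordance rule {rule!r}")
    out = wide.index.to_frame(index=False)
    out["sbp_avg"] = _round_avg(sbp_avg, rounding)
    out["dbp_avg"] = _round_avg(dbp_avg, rounding)
    out["triplicate"] = trip
    out["protocol_violation"] = discord & ~trip
    return out.sort_values(VISIT_KEY, kind="stable").reset_index(drop=True)


def triplicate_fraction(averaged: pd.DataFrame) -> float:
    """Fraction of visits averaged over readings (2, 3)."""
    if len(averaged) == 0:
        return float("nan")
    return float(averaged["triplicate"].mean())


@dataclass
class DiffSummary:
    """Median and IQR of reading-to-reading differences, mm Hg.

    ``entries`` maps e.g. ``"sbp1-sbp2"`` to ``{"median", "q25", "q75",
    "n"}`` or to ``None`` when no visit contributes (e.g. no triplicates).
    Quantiles use linear interpolation between order statistics (the numpy
    default); the same convention is used by the test oracles.
    """

    entries: dict[str, dict | None]

    def to_dict(self) -> dict:
        return {"entries": self.entries}


def pairwise_difference_summary(vt: pd.DataFrame) -> DiffSummary:
    """Summarise reading1−reading2, reading1−reading3 and reading2−reading3
    differences for both measures over a validated visit table.

    Differences involving reading 3 are computed only over triplicate
    visits; with no triplicates those entries are ``None`` (undefined),
    never zero.
    """
    entries: dict[str, dict | None] = {}
    if vt.empty:
        for a, b in DIFF_PAIRS:
            entries[f"sbp{a}-sbp{b}"] = None
            entries[f"dbp{a}-dbp{b}"] = None
        return DiffSummary(entries)
    wide = vt.pivot_table(
        index=VISIT_KEY, columns="reading_index", values=["sbp", "dbp"], aggfunc="first"
    )
    for measure in ("sbp", "dbp"):
        for a, b in DIFF_PAIRS:
            name = f"{measure}{a}-{measure}{b}"
            if (measure, a) not in wide.columns or (measure, b) not in wide.columns:
                entries[name] = None
                continue
            diff = (wide[(measure, a)] - wide[(measure, b)]).dropna().to_numpy(dtype=float)
            if diff.size == 0:
                entries[name] = None
                continue
            q25, med, q75 = np.percentile(diff, [25, 50, 75])
            entries[name] = {
                "median": float(med),
                "q25": float(q25),
                "q75": float(q75),
                "n": int(diff.size),
            }
    return DiffSummary(entries)
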