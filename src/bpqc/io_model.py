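"""Reading ingestion, validation and audit-report serialization.

A *visit table* is the canonical in-memory container for raw blood-pressure
data: a :class:`pandas.DataFrame` in long format with one row per reading and
columns ``cohort_id``, ``participant_id``, ``visit_id``, ``reading_index``
(1, 2 or 3), ``sbp`` and ``dbp`` (integer mm Hg).  All downstream audit
stages (averaging, digit preference, spike, threshold tests) consume this
layout.  A wide layout (``sbp1``/``dbp1`` ... ``sbp3``/``dbp3``, one row per
visit) is common in field exports and is converted on ingest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical long-format columns, in order.
VISIT_COLUMNS = ["cohort_id", "participant_id", "visit_id", "reading_index", "sbp", "dbp"]

#: Grouping key identifying one visit.
VISIT_KEY = ["cohort_id", "participant_id", "visit_id"]

#: Physiological plausibility gates (mm Hg).  Values outside are treated as
#: transcription errors, not measurements; the bounds are deliberately wide
#: and configurable in :func:`validate_visits`.
SBP_RANGE = (40, 300)
DBP_RANGE = (20, 200)

#: Global two-sided significance level used by every audit stage.
ALPHA = 0.01


class FormatError(ValueError):
    """Input file does not match the expected tabular layout."""


@dataclass
class ValidationReport:
    """Tally of visits kept/dropped by :func:`validate_visits`.

    ``dropped`` maps a reason label to the number of visits excluded for that
    reason; a visit is counted once, under the first failing rule.
    ``protocol_violations`` counts *kept* visits whose two readings are
    discordant (>10 mm Hg apart) but that have no third reading.
    """

    n_visits_in: int = 0
    n_visits_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    protocol_violations: int = 0

    @property
    def n_visits_dropped(self) -> int:
        return sum(self.dropped.values())

    def to_dict(self) -> dict:
        return {
            "n_visits_in": self.n_visits_in,
            "n_visits_kept": self.n_visits_kept,
            "n_visits_dropped": self.n_visits_dropped,
            "dropped": dict(self.dropped),
            "protocol_violations": self.protocol_violations,
        }


def read_visits(path: str | Path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a long-format visit CSV into the canonical visit table.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Optional mapping from canonical column name to the column name used
        in the file, e.g. ``{"sbp": "SYS", "dbp": "DIA"}``.

    Raises
    ------
    FormatError
        If a required column is missing (the message names it) or a BP /
        reading-index cell is not an integer (the message cites the CSV row).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (dialect or {}).items()}
    df = df.rename(columns=rename)
    for col in VISIT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path.name}")
    df = df[VISIT_COLUMNS].copy()
    for col in ("reading_index", "sbp", "dbp"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() | (parsed != np.floor(parsed))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
            raise FormatError(
                f"non-integer value {df[col].iloc[row - 2]!r} for column {col!r} "
                f"at row {row} of {path.name}"
            )
        df[col] = parsed.astype(int)
    # stable order inside each visit by reading index
    df = df.sort_values(VISIT_KEY + ["reading_index"], kind="stable").reset_index(drop=True)
    return df


def read_visits_wide(path: str | Path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a wide-format file (one row per visit, ``sbp1..3``/``dbp1..3``
    columns; the third pair may be blank) and convert to the long layout."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (dialect or {}).items()}
    df = df.rename(columns=rename)
    for col in VISIT_KEY + ["sbp1", "dbp1", "sbp2", "dbp2"]:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path.name}")
    rows = []
    for _, r in df.iterrows():
        for idx in (1, 2, 3):
            s, d = r.get(f"sbp{idx}", ""), r.get(f"dbp{idx}", "")
            if s == "" and d == "":
                continue
            rows.append(
                (r["cohort_id"], r["participant_id"], r["visit_id"], idx, s, d)
            )
    long_df = pd.DataFrame(rows, columns=VISIT_COLUMNS)
    for col in ("reading_index", "sbp", "dbp"):
        parsed = pd.to_numeric(long_df[col], errors="coerce")
        bad = parsed.isna() | (parsed != np.floor(parsed))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"non-integer value {long_df[col].iloc[i]!r} for column {col!r} in {path.name}"
            )
        long_df[col] = parsed.astype(int)
    return long_df.sort_values(VISIT_KEY + ["reading_index"], kind="stable").reset_index(drop=True)


def validate_visits(
    vt: pd.DataFrame,
    sbp_range: tuple[int, int] = SBP_RANGE,
    dbp_range: tuple[int, int] = DBP_RANGE,
    discordance_mm_hg: int = 10,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Drop visits violating structural or physiological invariants.

    Rules, applied per visit in order (first failure determines the reason):

    1. ``insufficient readings`` — fewer than 2 readings;
    2. ``too many readings`` — more than 3;
    3. ``bad reading indices`` — indices not exactly {1,2} or {1,2,3};
    4. ``out of range`` — any sbp/dbp outside the plausibility gates;
    5. ``dbp >= sbp`` — any reading with diastolic at or above systolic.

    Visits whose first two readings are discordant (> ``discordance_mm_hg``
    in either component) but that lack a third reading are **kept** and
    counted as ``protocol_violations``: dropping them would silently bias
    the audits that this package exists to run.

    Returns the retained visit table and a :class:`ValidationReport`.
    """
    report = ValidationReport()
    if vt.empty:
        return vt.copy(), report
    keep_keys = []
    for key, g in vt.groupby(VISIT_KEY, sort=False):
        report.n_visits_in += 1
        idx = sorted(g["reading_index"].tolist())
        if len(g) < 2:
            reason = "insufficient readings"
        elif len(g) > 3:
            reason = "too many readings"
        elif idx not in ([1, 2], [1, 2, 3]):
            reason = "bad reading indices"
        elif (
            (g["sbp"] < sbp_range[0]).any()
            or (g["sbp"] > sbp_range[1]).any()
            or (g["dbp"] < dbp_range[0]).any()
            or (g["dbp"] > dbp_range[1]).any()
        ):
            reason = "out of range"
        elif (g["dbp"] >= g["sbp"]).any():
            reason = "dbp >= sbp"
        else:
            g = g.sort_values("reading_index")
            if len(g) == 2:
                ds = abs(int(g["sbp"].iloc[0]) - int(g["sbp"].iloc[1]))
                dd = abs(int(g["dbp"].iloc[0]) - int(g["dbp"].iloc[1]))
                if ds > discordance_mm_hg or dd > discordance_mm_hg:
                    report.protocol_violations += 1
            report.n_visits_kept += 1
            keep_keys.append(key)
            continue
        report.dropped[reason] = report.dropped.get(reason, 0) + 1
    if not keep_keys:
        return vt.iloc[0:0].copy(), report
    keyframe = pd.DataFrame(keep_keys, columns=VISIT_KEY)
    kept = vt.merge(keyframe, on=VISIT_KEY, how="inner")
    kept = kept.sort_values(VISIT_KEY + ["reading_index"], kind="stable").reset_index(drop=True)
    return kept, report


# --------------------------------------------------------------------------
# JSON audit report plumbing


def _jsonable(obj):
    """Convert numpy scalars and NaN/inf to JSON-safe python values.

    Non-finite floats become ``None`` so the report never contains literal
    NaN tokens; consumers read ``null`` as "undefined", which is what a
    non-finite statistic means here.
    """
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_audit_report(report: dict, path: str | Path) -> None:
    """Serialize an audit report (nested dict) to pretty-printed JSON.

    Writing then :func:`read_audit_report` yields an equal dict (non-finite
    numbers round-trip to ``None``).
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, allow_nan=False)
        fh.write("\n")


def read_audit_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
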