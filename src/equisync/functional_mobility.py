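"""Functional-mobility test records and session-trend summaries.

Two timed walking tests, administered immediately before ("pre") and
after ("post") the riding sessions on days 1, 4 and 8:

* **TUG** (Timed Up and Go): stand from a chair, walk 3 m, turn, walk
  back, sit down.
* **10mWT** (10 Meter Walk Test, ``TENMWT``): comfortable-speed walk timed
  between the 2 m and 8 m marks of a 10 m path.

The summaries mirror the study's reporting: per-group mean and sample
standard deviation, and percent change of later sessions against
session 1.  No hypothesis testing is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import errors

TESTS = ("TUG", "TENMWT")
PHASES = ("pre", "post")
TEST_SESSIONS = (1, 4, 8)


@dataclass(frozen=True)
class FunctionalTestRecord:
    """One timing observation: who, which test day, pre or post, seconds."""

    participant_id: str
    session_index: int
    phase: str
    test: str
    time_s: float

    def __post_init__(self) -> None:
        if self.session_index not in TEST_SESSIONS:
            raise errors.ParameterError(
                f"session_index must be one of {TEST_SESSIONS}, "
                f"got {self.session_index}")
        if self.phase not in PHASES:
            raise errors.ParameterError(f"phase must be in {PHASES}, got {self.phase!r}")
        if self.test not in TESTS:
            raise errors.ParameterError(f"test must be in {TESTS}, got {self.test!r}")
        if not (np.isfinite(self.time_s) and self.time_s > 0):
            raise errors.ParameterError(f"time_s must be finite and > 0, got {self.time_s}")


def records_to_frame(records: Iterable[FunctionalTestRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(r.participant_id, r.session_index, r.phase, r.test, r.time_s)
         for r in records],
        columns=["participant", "session", "phase", "test", "time_s"])
    dup = df.duplicated(["participant", "session", "phase", "test"])
    if dup.any():
        raise errors.FormatError(
            "duplicate (participant, session, phase, test) records: "
            f"{df[dup][['participant', 'session', 'phase']].to_dict('records')}")
    return df


def read_functional_csv(path: str | Path) -> list[FunctionalTestRecord]:
    """Read records from a CSV with columns participant, session, phase, test, time_s."""
    df = pd.read_csv(path)
    missing = {"participant", "session", "phase", "test", "time_s"} - set(df.columns)
    if missing:
        raise errors.FormatError(f"{Path(path).name}: missing columns {sorted(missing)}")
    records = [
        FunctionalTestRecord(str(r.participant), int(r.session), str(r.phase),
                             str(r.test), float(r.time_s))
        for r in df.itertuples()
    ]
    records_to_frame(records)  # duplicate check
    return records


def write_functional_csv(records: Iterable[FunctionalTestRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.9g")


def _as_frame(data, value_col: str = "time_s") -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data.rename(columns={value_col: "value"})
    else:
        df = records_to_frame(data).rename(columns={"time_s": "value"})
    if "session" not in df.columns or "value" not in df.columns:
        raise errors.FormatError(
            f"need 'session' and {value_col!r} columns for percent change")
    return df


def percent_change(
    data,
    baseline_session: int,
    target_session: int,
    *,
    direction: str = "decrease",
    phase: str | None = None,
    value_col: str = "time_s",
) -> float:
    """Percent change of the target-session mean against the baseline mean.

    ``data`` is a record set or any DataFrame with ``session`` and a value
    column (so correlation or RMSE series work the same way).  For
    decrease-phrased metrics (times, lag, RMSE) the value is
    ``100 * (mean_baseline - mean_target) / mean_baseline``; for
    increase-phrased metrics (correlation) the sign convention flips to
    ``100 * (mean_target - mean_baseline) / mean_baseline``.  Pre and post
    phases are pooled unless ``phase`` restricts them.
    """
    if direction not in ("decrease", "increase"):
        raise errors.ParameterError(
            f"direction must be 'decrease' or 'increase', got {direction!r}")
    df = _as_frame(data, value_col)
    if phase is not None:
        if "phase" not in df.columns:
            raise errors.FormatError("no 'phase' column to restrict on")
        df = df[df["phase"] == phase]
    for s in (baseline_session, target_session):
        if not (df["session"] == s).any():
            raise errors.CoverageError(f"no records for session {s}")
    if "participant" in df.columns:
        for pid, grp in df.groupby("participant"):
            have = set(grp["session"])
            if not {baseline_session, target_session} <= have:
                raise errors.CoverageError(
                    f"participant {pid!r} lacks session "
                    f"{baseline_session if baseline_session not in have else target_session}")
    mb = float(df.loc[df["session"] == baseline_session, "value"].mean())
    mt = float(df.loc[df["session"] == target_session, "value"].mean())
    if mb == 0:
        raise errors.UndefinedMetricError("baseline mean is zero; percent change undefined")
    if direction == "decrease":
        return 100.0 * (mb - mt) / mb
    return 100.0 * (mt - mb) / mb


def group_sd(
    records: Iterable[FunctionalTestRecord],
    session: int,
    phase: str,
    *,
    test: str | None = None,
) -> float:
    """Sample (n-1) standard deviation of times across participants."""
    df = records_to_frame(records)
    sel = (df["session"] == session) & (df["phase"] == phase)
    if test is not None:
        sel &= df["test"] == test
    times = df.loc[sel, "time_s"].to_numpy()
    if times.size < 2:
        raise errors.UndefinedMetricError(
            f"group (session={session}, phase={phase!r}) has {times.size} "
            "record(s); sd needs >= 2")
    return float(np.std(times, ddof=1))


class FunctionalSummary(NamedTuple):
    """Per-group means/sds plus percent-change rows vs session 1."""

    cells: pd.DataFrame
    percent_changes: pd.DataFrame


def functional_summary(records: Sequence[FunctionalTestRecord]) -> FunctionalSummary:
    """Summary table mirroring the study's bar-graph quantities.

    One row per (test, phase, session) with n, mean and sample sd — the sd
    is omitted (NaN) when the group has a single participant — plus one
    percent-change row per (test, phase, later session) against session 1.
    """
    df = records_to_frame(records)
    if df.empty:
        warnings.warn("no functional records; empty summary", stacklevel=2)
        return FunctionalSummary(
            pd.DataFrame(columns=["test", "phase", "session", "n", "mean_s", "sd_s"]),
            pd.DataFrame(columns=["test", "phase", "baseline_session",
                                  "target_session", "percent_change"]))
    cells = (
        df.groupby(["test", "phase", "session"])["time_s"]
        .agg(n="count", mean_s="mean", sd_s=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan)
        .reset_index()
    )
    pct_rows = []
    for (test, phase), grp in df.groupby(["test", "phase"]):
        sessions = sorted(grp["session"].unique())
        if 1 not in sessions:
            warnings.warn(
                f"({test}, {phase}): no session-1 baseline; percent changes "
                "skipped", stacklevel=2)
            continue
        for s in sessions:
            if s == 1:
                continue
            try:
                pct = percent_change(grp, 1, s, direction="decrease")
            except errors.CoverageError as e:
                warnings.warn(f"({test}, {phase}, session {s}): {e}", stacklevel=2)
                continue
            pct_rows.append({
                "test": test, "phase": phase,
                "baseline_session": 1, "target_session": s,
                "percent_change": pct,
            })
    pct = pd.DataFrame(
        pct_rows, columns=["test", "phase", "baseline_session",
                           "target_session", "percent_change"])
    return FunctionalSummary(cells, pct)
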