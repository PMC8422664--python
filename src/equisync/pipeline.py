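"""End-to-end orchestration: simulate a dataset, analyze a dataset.

``run_simulate`` writes a complete on-disk dataset (per-session IMU CSV
pairs, a YAML manifest, a functional-test CSV and a ground-truth JSON)
from the coupled-gait generator.  ``run_analyze`` consumes exactly that
layout — or real data arranged the same way — and writes per-session
interaction metrics, functional summaries and a percent-change report of
sessions 4 and 8 against session 1, mirroring the study's reporting
scheme.  All randomness flows from the single config seed and outputs are
byte-reproducible for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import errors, functional_mobility, imu_io, synthetic_data
from .interaction_metrics import (AnalysisParams, SessionResult,
                                  metrics_table, session_metrics)
from .synthetic_data import (HorseGaitConfig, ProgressionConfig,
                             RiderCouplingConfig)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.9g"


def _listify(obj):
    """Recursively turn tuples into lists so YAML stays plain."""
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


@dataclass
class SimulateConfig:
    """Simulation run: who rides, which sessions, horse model, seed."""

    participants: tuple[tuple[str, str], ...] = (
        ("P1", "TUG"), ("P2", "TUG"), ("P3", "TUG"), ("P4", "TENMWT"))
    progression: ProgressionConfig = field(default_factory=ProgressionConfig)
    seed: int = 0
    acc_units: str = "g"

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "SimulateConfig":
        known = {"participants", "sessions", "duration_s", "rate_hz",
                 "cadence_spm", "noise_sd", "seed", "coupling", "functional",
                 "acc_units"}
        unknown = set(raw) - known
        if unknown:
            raise errors.ConfigError(f"unknown config keys: {sorted(unknown)}")
        participants = []
        for p in raw.get("participants", [{"id": f"P{i}", "test": t}
                                          for i, t in ((1, "TUG"), (2, "TUG"),
                                                       (3, "TUG"), (4, "TENMWT"))]):
            if isinstance(p, str):
                participants.append((p, "TUG"))
            else:
                participants.append((str(p["id"]), str(p.get("test", "TUG"))))
        horse_kwargs = {}
        for key in ("duration_s", "rate_hz", "cadence_spm", "noise_sd"):
            if key in raw:
                horse_kwargs[key] = float(raw[key])
        horse = HorseGaitConfig(**horse_kwargs)
        sessions = tuple(int(s) for s in raw.get("sessions", range(1, 9)))
        coupling = None
        if "coupling" in raw:
            coupling = {}
            for s, cfg in raw["coupling"].items():
                bad = set(cfg) - {f.name for f in
                                  dataclasses.fields(RiderCouplingConfig)}
                if bad:
                    raise errors.ConfigError(
                        f"coupling[{s}]: unknown fields {sorted(bad)}")
                coupling[int(s)] = RiderCouplingConfig(
                    **{k: float(v) for k, v in cfg.items()})
        functional = None
        if "functional" in raw:
            functional = {
                str(test): {int(s): (float(ms[0]), float(ms[1]))
                            for s, ms in sched.items()}
                for test, sched in raw["functional"].items()}
        prog_kwargs = dict(sessions=sessions, horse=horse, coupling=coupling)
        if functional is not None:
            prog_kwargs["functional"] = functional
        prog = ProgressionConfig(**prog_kwargs)
        prog.validate()
        return cls(participants=tuple(participants), progression=prog,
                   seed=int(raw.get("seed", 0)),
                   acc_units=str(raw.get("acc_units", "g")))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulateConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, Mapping):
            raise errors.ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_mapping(raw)

    def to_dict(self) -> dict:
        prog = self.progression
        return _listify({
            "participants": [{"id": p, "test": t} for p, t in self.participants],
            "sessions": list(prog.sessions),
            "horse": dataclasses.asdict(prog.horse),
            "coupling": {int(s): dataclasses.asdict(c)
                         for s, c in prog.coupling.items()},
            "functional": {t: {int(s): list(ms) for s, ms in sched.items()}
                           for t, sched in prog.functional.items()},
            "seed": self.seed,
            "acc_units": self.acc_units,
        })


def run_simulate(cfg: SimulateConfig, out_dir: str | Path) -> Path:
    """Write a full synthetic dataset under ``out_dir``.

    Layout: ``data/<pid>_s<k>_{horse,rider}.csv``, ``manifest.yaml``,
    ``functional.csv``, ``ground_truth.json``, ``run.yaml``.
    """
    cfg.progression.validate()
    out = Path(out_dir)
    (out / "data").mkdir(parents=True, exist_ok=True)
    manifest = []
    truth: dict = {"seed": cfg.seed, "participants": {}}
    for p_i, (pid, _test) in enumerate(cfg.participants):
        pairs, ptruth = synthetic_data.generate_session_series(
            cfg.progression, pid,
            synthetic_data._session_seeds(cfg.seed, (p_i,)))
        truth["participants"][pid] = ptruth
        for pair in pairs:
            hname = f"data/{pid}_s{pair.session_index}_horse.csv"
            rname = f"data/{pid}_s{pair.session_index}_rider.csv"
            imu_io.write_razor_log(pair.horse, out / hname, acc_units=cfg.acc_units)
            imu_io.write_razor_log(pair.rider, out / rname, acc_units=cfg.acc_units)
            manifest.append({"participant": pid, "session": pair.session_index,
                             "horse_log": hname, "rider_log": rname})
    records = synthetic_data.generate_functional_times(
        cfg.progression, list(cfg.participants), cfg.seed)
    functional_mobility.write_functional_csv(records, out / "functional.csv")
    truth["functional_schedule"] = {
        t: {int(s): list(ms) for s, ms in sched.items()}
        for t, sched in cfg.progression.functional.items()}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    (out / "run.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return out


# metric name -> (column, phrased direction)
_METRIC_DIRECTIONS = {
    "max_corr": "increase",
    "lag_s": "decrease",
    "rmse_freq_hz": "decrease",
}


def _report_targets(sessions: Sequence[int]) -> list[int]:
    present = sorted(set(int(s) for s in sessions))
    if 1 not in present:
        return []
    preferred = [s for s in (4, 8) if s in present]
    return preferred or [s for s in present if s != 1]


def percent_change_report(
    metrics: pd.DataFrame,
    functional_records: Sequence[functional_mobility.FunctionalTestRecord],
) -> pd.DataFrame:
    """Percent change of every metric for sessions 4 and 8 versus session 1
    (falling back to whatever non-baseline sessions were run)."""
    rows = []
    if not metrics.empty:
        for col, direction in _METRIC_DIRECTIONS.items():
            sub = metrics[["participant", "session", col]].dropna()
            for s in _report_targets(sub["session"]):
                try:
                    pc = functional_mobility.percent_change(
                        sub, 1, s, direction=direction, value_col=col)
                except (errors.CoverageError, errors.UndefinedMetricError) as e:
                    warnings.warn(f"{col} session {s}: {e}", stacklevel=2)
                    continue
                rows.append({"metric": col, "direction": direction,
                             "baseline_session": 1, "target_session": s,
                             "percent_change": pc})
    if functional_records:
        df = functional_mobility.records_to_frame(functional_records)
        for test, grp in df.groupby("test"):
            for s in _report_targets(grp["session"]):
                try:
                    pc = functional_mobility.percent_change(
                        grp, 1, s, direction="decrease")
                except (errors.CoverageError, errors.UndefinedMetricError) as e:
                    warnings.warn(f"{test} session {s}: {e}", stacklevel=2)
                    continue
                rows.append({"metric": test, "direction": "decrease",
                             "baseline_session": 1, "target_session": s,
                             "percent_change": pc})
    return pd.DataFrame(
        rows, columns=["metric", "direction", "baseline_session",
                       "target_session", "percent_change"])


@dataclass
class AnalyzeResult:
    """Everything run_analyze computed, plus isolated per-session failures."""

    results: list[SessionResult]
    metrics: pd.DataFrame
    summary: functional_mobility.FunctionalSummary
    report: pd.DataFrame
    failures: list[tuple[imu_io.SessionDescriptor, str]]


def run_analyze(
    manifest_path: str | Path,
    functional_path: str | Path | None,
    out_dir: str | Path,
    params: AnalysisParams | None = None,
    *,
    acc_units: str = "g",
    seed: int = 0,
) -> AnalyzeResult:
    """Analyze every manifest entry and write the result bundle.

    Per-session failures are isolated (listed in the result and in
    ``run.yaml``) so one corrupt log does not void a whole dataset.
    """
    params = params or AnalysisParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    descriptors = imu_io.load_session_manifest(manifest_path)
    results: list[SessionResult] = []
    failures: list[tuple[imu_io.SessionDescriptor, str]] = []
    for desc in descriptors:
        try:
            pair = imu_io.load_pair(desc, acc_units=acc_units)
            results.append(session_metrics(pair, params))
        except errors.EquiSyncError as e:
            log.error("session failed: %s", e)
            failures.append((desc, str(e)))
    metrics = metrics_table(results)
    metrics.to_csv(out / "metrics.csv", index=False, float_format=_FLOAT_FMT)

    records: list[functional_mobility.FunctionalTestRecord] = []
    if functional_path is not None:
        records = functional_mobility.read_functional_csv(functional_path)
    summary = functional_mobility.functional_summary(records)
    summary.cells.to_csv(out / "functional_summary.csv", index=False,
                         float_format=_FLOAT_FMT)
    report = percent_change_report(metrics, records)
    if not summary.percent_changes.empty:
        per_phase = summary.percent_changes.assign(
            metric=lambda d: d["test"] + "_" + d["phase"],
            direction="decrease")[
            ["metric", "direction", "baseline_session", "target_session",
             "percent_change"]]
        report = pd.concat([report, per_phase], ignore_index=True)
    report.to_csv(out / "percent_change.csv", index=False, float_format=_FLOAT_FMT)

    run_meta = {
        "seed": seed,
        "params": _listify(dataclasses.asdict(params)),
        "acc_units": acc_units,
        "n_sessions": len(results),
        "failures": [
            {"participant": d.participant_id, "session": d.session_index,
             "error": msg} for d, msg in failures],
    }
    (out / "run.yaml").write_text(yaml.safe_dump(run_meta, sort_keys=True))
    return AnalyzeResult(results, metrics, summary, report, failures)
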