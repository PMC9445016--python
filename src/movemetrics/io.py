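"""Text-format I/O: trace CSVs with JSON sidecars, tidy test/score tables.

All artifacts are UTF-8 text (CSV / JSON) with "." decimal separators,
fixed column orders, and floats printed with 17 significant digits so that
every file round-trips bitwise through the readers. CSV files open with a
comment header carrying the tool version and a configuration hash; JSON
files carry the same under a ``_meta`` key.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activities import ACTIVITIES, REQUIRED_CHANNELS, MotionTrace, Phase
from .core import KinematicsError, PlanarSamples

log = logging.getLogger("movemetrics")

#: Longest sensor dropout (seconds) that ingestion will bridge by linear
#: interpolation; longer gaps reject the trace.
MAX_GAP_S = 0.5

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration, echoed verbatim into every report."""

    seed: int
    alpha: float = 0.05
    gate_mode: str = "both"          # Pearson gate: "both" | "either"
    equal_var: bool = True           # Student vs Welch t-test
    bh_correction: bool = False
    hysteresis_m: float = 0.005

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _csv_header(config: dict | None) -> str:
    h = config_hash(config or {})
    return f"# movemetrics {__version__} config_hash={h}\n"


def write_csv(df: pd.DataFrame, path, config: dict | None = None,
              index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_csv_header(config))
        df.to_csv(fh, index=index, float_format=_FLOAT_FMT, lineterminator="\n")


def read_csv(path, **kwargs) -> pd.DataFrame:
    # round_trip float parsing: the default parser can be one ulp off,
    # which would break the bitwise write -> read -> extract guarantee
    return pd.read_csv(path, comment="#", float_precision="round_trip", **kwargs)


def write_json(obj: dict, path, config: dict | None = None) -> None:
    payload = {"_meta": {"tool": f"movemetrics {__version__}",
                         "config_hash": config_hash(config or {})}}
    payload.update(obj)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# motion traces

def write_trace(trace: MotionTrace, csv_path, sidecar_path) -> None:
    """Write a trace as CSV (column ``t`` first) plus a JSON sidecar."""
    n = trace.n_samples
    cols = {"t": np.arange(n) / trace.fs}
    for name in sorted(trace.channels):
        cols[name] = trace.channels[name]
    write_csv(pd.DataFrame(cols), csv_path)
    sidecar = {
        "activity": trace.activity,
        "fs": trace.fs,
        "participant_id": trace.participant_id,
        "phases": [{"label": p.label, "start": p.start, "end": p.end}
                   for p in trace.phases],
    }
    write_json(sidecar, sidecar_path)


def _bridge_gaps(name: str, values: np.ndarray, fs: float,
                 source: str) -> np.ndarray:
    isnan = np.isnan(values)
    if not isnan.any():
        return values
    # longest run of consecutive missing samples
    padded = np.concatenate([[0], isnan.astype(int), [0]])
    edges = np.diff(padded)
    run_lengths = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
    longest = int(run_lengths.max())
    if longest > MAX_GAP_S * fs:
        raise KinematicsError(
            f"{source}: channel {name!r} has a {longest / fs:.2f} s dropout "
            f"(> {MAX_GAP_S} s); trace rejected"
        )
    idx = np.arange(values.size)
    filled = np.interp(idx, idx[~isnan], values[~isnan])
    log.info("%s: interpolated %d missing samples in channel %r",
             source, int(isnan.sum()), name)
    return filled


def read_trace(csv_path, sidecar_path) -> MotionTrace:
    """Read and validate a trace CSV + sidecar into a MotionTrace.

    Schema checks name the offending column or phase; short sensor
    dropouts (<= 0.5 s) are linearly interpolated and logged, longer ones
    reject the trace.
    """
    sidecar = read_json(sidecar_path)
    for key in ("activity", "fs"):
        if key not in sidecar:
            raise KinematicsError(f"{sidecar_path}: sidecar missing {key!r}")
    activity = sidecar["activity"]
    if activity not in ACTIVITIES:
        raise KinematicsError(f"{sidecar_path}: unknown activity {activity!r}")
    fs = float(sidecar["fs"])

    df = read_csv(csv_path)
    if "t" not in df.columns:
        raise KinematicsError(f"{csv_path}: missing time column 't'")
    missing = REQUIRED_CHANNELS[activity] - set(df.columns)
    if missing:
        raise KinematicsError(f"{csv_path}: missing channels {sorted(missing)}")
    channels = {
        name: _bridge_gaps(name, df[name].to_numpy(dtype=float), fs, str(csv_path))
        for name in df.columns if name != "t"
    }
    phases = [Phase(p["label"], int(p["start"]), int(p["end"]))
              for p in sidecar.get("phases", [])]
    return MotionTrace(fs, activity, channels, phases,
                       participant_id=sidecar.get("participant_id"))


# ---------------------------------------------------------------------------
# functional-test measurement tables

_TEST_ROW_UNITS = {
    "plumb_line": "in", "rbb_i": "in", "rbb_s": "in", "sit_reach": "in",
    "functional_reach": "in", "single_leg_hop": "in", "y_balance": "in",
    "star_excursion": "in", "ckcue": "count", "hurdle_step": "grade",
    "uhbe": "s", "ctsib_t": "s", "romberg_t": "s",
}


def record_to_rows(participant_id: str, record: dict) -> list[dict]:
    """Flatten a raw measurement record into tidy trial rows."""

    def row(test, limb, trial, value, unit=None):
        return {"participant_id": participant_id, "test": test, "limb": limb,
                "trial_index": int(trial), "value": float(value),
                "unit": unit or _TEST_ROW_UNITS[test]}

    rows = []
    for test in ("plumb_line", "sit_reach", "functional_reach", "uhbe",
                 "single_leg_hop", "ctsib_t", "romberg_t"):
        for i, v in enumerate(record.get(test, [])):
            rows.append(row(test, "-", i, v))
    for test in ("rbb_i", "rbb_s"):
        for i, v in enumerate(record.get(test, [])):
            rows.append(row(test, "LR"[i] if i < 2 else str(i), i, v))
    if "ckcue" in record:
        spec = record["ckcue"]
        rows.append(row("ckcue", "attempted", 0, 1.0 if spec["attempted"] else 0.0,
                        unit="flag"))
        for i, v in enumerate(spec["counts"]):
            rows.append(row("ckcue", "-", i, v))
    for test, limbs in (("y_balance", ("L", "R")), ("star_excursion", ("L", "R"))):
        if test in record:
            for limb in limbs:
                for i, v in enumerate(record[test]["reaches"][limb]):
                    rows.append(row(test, limb, i, v))
    if "hurdle_step" in record:
        for side in ("left", "right"):
            for i, g in enumerate(record["hurdle_step"][side]):
                rows.append(row("hurdle_step", side, i, g))
    return rows


def acc_to_rows(participant_id: str, record: dict) -> list[dict]:
    """Flatten balance-trial planar acceleration samples into tidy rows."""
    rows = []
    for test, key in (("ctsib", "ctsib_acc"), ("romberg", "romberg_acc")):
        for trial, samples in enumerate(record.get(key, [])):
            for x, y in zip(samples.x, samples.y):
                rows.append({"participant_id": participant_id, "test": test,
                             "trial_index": trial, "x": float(x), "y": float(y)})
    return rows


def rows_to_record(trial_rows: pd.DataFrame, acc_rows: pd.DataFrame | None,
                   leg_length: float | None,
                   arm_length: float | None) -> dict:
    """Rebuild a raw measurement record from tidy rows (inverse of the writers)."""
    record: dict = {}
    if leg_length is not None:
        record["leg_length"] = float(leg_length)
    if arm_length is not None:
        record["arm_length"] = float(arm_length)

    def values(sub: pd.DataFrame) -> list[float]:
        return list(sub.sort_values("trial_index")["value"].astype(float))

    for test, sub in trial_rows.groupby("test"):
        if test in ("plumb_line", "sit_reach", "functional_reach", "uhbe",
                    "single_leg_hop", "ctsib_t", "romberg_t"):
            record[test] = values(sub)
        elif test in ("rbb_i", "rbb_s"):
            record[test] = values(sub.assign(trial_index=sub["trial_index"]))
        elif test == "ckcue":
            attempted = bool(sub.loc[sub["limb"] == "attempted", "value"].iloc[0])
            record["ckcue"] = {
                "counts": values(sub[sub["limb"] == "-"]),
                "attempted": attempted,
            }
        elif test in ("y_balance", "star_excursion"):
            length = arm_length if test == "y_balance" else leg_length
            record[test] = {
                "reaches": {limb: values(g) for limb, g in sub.groupby("limb")},
                ("arm_length" if test == "y_balance" else "leg_length"):
                    float(length),
            }
        elif test == "hurdle_step":
            record["hurdle_step"] = {
                side: [int(v) for v in values(g)]
                for side, g in sub.groupby("limb")
            }
        else:
            raise KinematicsError(f"unknown test {test!r} in trial table")

    if acc_rows is not None and len(acc_rows):
        for test, key in (("ctsib", "ctsib_acc"), ("romberg", "romberg_acc")):
            sub = acc_rows[acc_rows["test"] == test]
            if len(sub):
                record[key] = [
                    PlanarSamples(g["x"].to_numpy(float), g["y"].to_numpy(float))
                    for _, g in sub.groupby("trial_index", sort=True)
                ]
    return record


def read_cohort_tests(cohort_dir) -> dict[str, dict]:
    """Read tests.csv / balance_acc.csv / limb_lengths.csv into raw records."""
    cohort = Path(cohort_dir)
    trials = read_csv(cohort / "tests.csv",
                      dtype={"limb": str}, keep_default_na=False,
                      na_values=[""])
    acc = read_csv(cohort / "balance_acc.csv")
    limbs = read_csv(cohort / "limb_lengths.csv").set_index("participant_id")
    records = {}
    acc_by_pid = dict(tuple(acc.groupby("participant_id"))) if len(acc) else {}
    for pid, sub in trials.groupby("participant_id"):
        leg = limbs.at[pid, "leg_length"] if pid in limbs.index else None
        arm = limbs.at[pid, "arm_length"] if pid in limbs.index else None
        records[pid] = rows_to_record(sub, acc_by_pid.get(pid), leg, arm)
    return records


def read_cohort_traces(cohort_dir, participant_id: str) -> dict[str, MotionTrace]:
    """Read every available activity trace of one participant."""
    traces = {}
    tdir = Path(cohort_dir) / "traces"
    for activity in ACTIVITIES:
        base = tdir / f"{participant_id}_{activity}"
        if base.with_suffix(".csv").exists():
            traces[activity] = read_trace(base.with_suffix(".csv"),
                                          base.with_suffix(".json"))
    return traces


def read_scores(path) -> pd.DataFrame:
    df = read_csv(path)
    expected = {"participant_id", "trial_index", "score"}
    if not expected <= set(df.columns):
        raise KinematicsError(f"{path}: score table needs columns {sorted(expected)}")
    return df
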