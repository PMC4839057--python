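"""Study readers and writers.

A study directory holds one sub-directory per batch::

    study/
      index.csv                 # batch_id, scenario, partition, t_induction
      B001/
        online.csv              # t, u_Feed, u_Base, T, pH, agitation, u_C
        offline.csv             # t, X_od, PX, P[, acetate]
        meta.yaml               # t0, t_induction, v0, partition, conditions
        truth.csv               # optional fine-grid plant truth

Times are hours from t0, the first fed-batch offline sample.  Floats are
written with full precision so a write-read round trip is lossless.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import StudyFormatError
from .plant import BatchConditions, BatchRecord, OfflineSamples, OnlineSeries, ONLINE_STEP

__all__ = ["write_study", "read_study", "write_batch", "read_batch", "od_to_dcw"]

_FLOAT_FMT = "%.17g"


def od_to_dcw(od):
    """Dry cell weight (g/L) from optical density at 650 nm: 0.6 g/L per OD."""
    od = np.asarray(od, dtype=float)
    if np.any(od < 0):
        raise ValueError("OD must be non-negative")
    out = 0.6 * od
    return float(out) if out.ndim == 0 else out


def _conditions_to_dict(c: BatchConditions) -> dict:
    d = {
        "X_ind": float(c.X_ind), "T": float(c.T), "pH": float(c.pH),
        "u_C": float(c.u_C), "induction_duration": float(c.induction_duration),
    }
    if c.profiles:
        d["profiles"] = {k: [[float(t), float(v)] for t, v in bp] for k, bp in c.profiles.items()}
    return d


def _conditions_from_dict(d: dict) -> BatchConditions:
    profiles = None
    if d.get("profiles"):
        profiles = {k: tuple((float(t), float(v)) for t, v in bp) for k, bp in d["profiles"].items()}
    return BatchConditions(
        X_ind=d["X_ind"], T=d["T"], pH=d["pH"], u_C=d["u_C"],
        induction_duration=d["induction_duration"], profiles=profiles,
    )


def write_batch(record: BatchRecord, batch_dir: str | Path, include_truth: bool = False) -> None:
    batch_dir = Path(batch_dir)
    batch_dir.mkdir(parents=True, exist_ok=True)
    record.online.to_frame().to_csv(batch_dir / "online.csv", index=False, float_format=_FLOAT_FMT)
    record.offline.to_frame().to_csv(batch_dir / "offline.csv", index=False, float_format=_FLOAT_FMT)
    meta = {
        "batch_id": record.batch_id,
        "t0": float(record.t0),
        "t_induction": float(record.t_induction),
        "v0": float(record.v0),
        "partition": record.partition,
        "scenario": record.scenario,
        "conditions": _conditions_to_dict(record.conditions),
    }
    with open(batch_dir / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    if include_truth and record.truth is not None:
        record.truth.to_csv(batch_dir / "truth.csv", index=False, float_format=_FLOAT_FMT)


def read_batch(batch_dir: str | Path) -> BatchRecord:
    batch_dir = Path(batch_dir)
    try:
        with open(batch_dir / "meta.yaml") as fh:
            meta = yaml.safe_load(fh)
    except FileNotFoundError as err:
        raise StudyFormatError(f"{batch_dir}: missing meta.yaml") from err
    except yaml.YAMLError as err:
        raise StudyFormatError(f"{batch_dir}/meta.yaml: unreadable YAML ({err})") from err

    online_df = pd.read_csv(batch_dir / "online.csv", float_precision="round_trip")
    required = ["t", "u_Feed", "u_Base", "T", "pH", "agitation", "u_C"]
    missing = [c for c in required if c not in online_df.columns]
    if missing:
        raise StudyFormatError(f"{batch_dir}/online.csv: missing column(s) {missing}")
    t = online_df["t"].to_numpy(dtype=float)
    if t.size < 2 or np.max(np.abs(np.diff(t) - ONLINE_STEP)) > 1e-6:
        raise StudyFormatError(
            f"{batch_dir}/online.csv: online grid must be uniform with {ONLINE_STEP} h spacing"
        )
    offline_df = pd.read_csv(batch_dir / "offline.csv", float_precision="round_trip")
    missing = [c for c in ["t", "X_od", "PX", "P"] if c not in offline_df.columns]
    if missing:
        raise StudyFormatError(f"{batch_dir}/offline.csv: missing column(s) {missing}")

    t_ind = float(meta["t_induction"])
    if not (t[0] - 1e-9 <= t_ind <= t[-1] + 1e-9):
        raise StudyFormatError(
            f"{batch_dir}: induction time {t_ind} h outside online grid span [{t[0]}, {t[-1]}]"
        )

    truth = None
    if (batch_dir / "truth.csv").exists():
        truth = pd.read_csv(batch_dir / "truth.csv", float_precision="round_trip")

    return BatchRecord(
        batch_id=str(meta["batch_id"]),
        conditions=_conditions_from_dict(meta["conditions"]),
        online=OnlineSeries.from_frame(online_df),
        offline=OfflineSamples.from_frame(offline_df),
        t_induction=t_ind,
        t0=float(meta.get("t0", 0.0)),
        v0=float(meta.get("v0", 1.0)),
        partition=str(meta.get("partition", "")),
        scenario=str(meta.get("scenario", "")),
        truth=truth,
    )


def write_study(records: list[BatchRecord], study_dir: str | Path, include_truth: bool = False) -> None:
    study_dir = Path(study_dir)
    study_dir.mkdir(parents=True, exist_ok=True)
    index = pd.DataFrame(
        {
            "batch_id": [r.batch_id for r in records],
            "scenario": [r.scenario for r in records],
            "partition": [r.partition for r in records],
            "t_induction": [r.t_induction for r in records],
        }
    )
    index.to_csv(study_dir / "index.csv", index=False, float_format=_FLOAT_FMT)
    for r in records:
        write_batch(r, study_dir / r.batch_id, include_truth=include_truth)


def read_study(study_dir: str | Path) -> list[BatchRecord]:
    """Load a study directory; raises :class:`StudyFormatError` on malformed
    batches with the offending file in the message."""
    study_dir = Path(study_dir)
    index_path = study_dir / "index.csv"
    if not index_path.exists():
        raise StudyFormatError(f"{study_dir}: missing index.csv")
    index = pd.read_csv(index_path)
    if "batch_id" not in index.columns:
        raise StudyFormatError(f"{index_path}: missing batch_id column")
    return [read_batch(study_dir / str(bid)) for bid in index["batch_id"]]
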