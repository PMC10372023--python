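"""CSV readers/writers and run manifests.

Two plain-text schemas tie the pipeline together:

* caliper CSV — one row per animal x day:
  ``animal_id,group_id,day,width_mm,length_mm,alive`` (``alive`` optional
  0/1, default 1); UTF-8, header required, '.' decimal.
* thermal CSV — ``time_s,temp_C,laser_on`` (``laser_on`` 0/1, optional
  when on/off switch times are supplied instead).

Readers validate row by row and report offending line numbers (header =
line 1).  Every CLI run writes a :class:`RunManifest` next to its outputs
so results are reproducible from manifest + inputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .growth import CaliperRecord, FTGRTrace, TGIResult
from .photothermal import ThermalTrace

__all__ = [
    "CSVFormatError",
    "read_caliper_csv",
    "write_caliper_csv",
    "read_thermal_csv",
    "write_thermal_csv",
    "ftgr_frame",
    "tgi_frame",
    "RunManifest",
    "write_manifest",
]

_CALIPER_COLUMNS = ["animal_id", "group_id", "day", "width_mm", "length_mm"]
_THERMAL_COLUMNS = ["time_s", "temp_C"]


class CSVFormatError(ValueError):
    """The file violates the schema; the message lists the offending lines."""


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CSVFormatError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        if df[col].dtype == object and col not in ("animal_id", "group_id"):
            bad = df[col].astype(str).str.contains(",", na=False)
            if bad.any():
                lines = (df.index[bad] + 2).tolist()
                raise CSVFormatError(
                    f"{path}: locale decimal commas in column {col!r} on lines "
                    f"{lines}; use '.' as the decimal separator"
                )
    return df


def read_caliper_csv(path: str | Path) -> list[CaliperRecord]:
    """Load and validate caliper records.

    Duplicate (animal, day) pairs are a hard error listing every offending
    line; width > length rows load with a swap warning naming the line.
    """
    path = Path(path)
    df = _read_csv(path, _CALIPER_COLUMNS)
    if "alive" not in df.columns:
        df["alive"] = 1

    dup = df.duplicated(subset=["animal_id", "day"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise CSVFormatError(
            f"{path}: duplicate (animal_id, day) measurements on lines {lines}"
        )

    records: list[CaliperRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            w = float(row["width_mm"])
            l = float(row["length_mm"])
            day = int(row["day"])
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric day/width/length")
            continue
        if w > l:
            warnings.warn(
                f"{path} line {line}: width {w} > length {l}; swapping "
                "(caliper convention)",
                stacklevel=2,
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # record-level swap already reported
                rec = CaliperRecord(
                    animal_id=str(row["animal_id"]),
                    group_id=str(row["group_id"]),
                    day=day,
                    width=w,
                    length=l,
                    alive=bool(int(row["alive"])),
                )
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
            continue
        records.append(rec)
    if errors:
        raise CSVFormatError(f"{path}: " + "; ".join(errors))
    return records


def write_caliper_csv(records: Iterable[CaliperRecord], path: str | Path) -> None:
    rows = [
        {
            "animal_id": r.animal_id,
            "group_id": r.group_id,
            "day": r.day,
            "width_mm": r.width,
            "length_mm": r.length,
            "alive": int(r.alive),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_thermal_csv(
    path: str | Path, switch_times: Sequence[float] | None = None
) -> ThermalTrace:
    """Load a thermal trace; time must be strictly increasing.

    When the ``laser_on`` column is absent, ``switch_times`` (seconds at
    which the laser toggles, starting ON at t=0) reconstructs the states.
    """
    path = Path(path)
    df = _read_csv(path, _THERMAL_COLUMNS)
    time = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        bad = (np.flatnonzero(np.diff(time) <= 0) + 2).tolist()
        raise CSVFormatError(f"{path}: time_s not strictly increasing near lines {bad}")
    if "laser_on" in df.columns:
        on = df["laser_on"].to_numpy(dtype=int).astype(bool)
    elif switch_times is not None:
        on = (np.searchsorted(np.asarray(switch_times, dtype=float), time,
                              side="right") % 2 == 0)
    else:
        raise CSVFormatError(
            f"{path}: no laser_on column and no switch times supplied"
        )
    return ThermalTrace(time, df["temp_C"].to_numpy(dtype=float), on)


def write_thermal_csv(trace: ThermalTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time,
            "temp_C": trace.temp,
            "laser_on": trace.laser_on.astype(int),
        }
    ).to_csv(path, index=False)


def ftgr_frame(traces: Iterable[FTGRTrace]) -> pd.DataFrame:
    """Tidy frame of FTGR values: group_id, day, statistic, value, convention."""
    rows = []
    for trace in traces:
        for day, value in zip(trace.days, trace.values):
            rows.append(
                {
                    "group_id": trace.group_id,
                    "day": int(day),
                    "statistic": "ftgr",
                    "value": float(value),
                    "convention": trace.label_convention,
                }
            )
    return pd.DataFrame(rows)


def tgi_frame(results: Iterable[TGIResult]) -> pd.DataFrame:
    rows = [
        {
            "group_id": r.group_id,
            "day": r.eval_day,
            "statistic": "tgi",
            "value": r.tgi,
            "convention": "",
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one CLI run: inputs, seeds, configuration."""

    tool: str
    version: str
    command: str
    config: dict = field(default_factory=dict)
    config_hash: str = ""
    inputs: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    timestamp: str = ""


def write_manifest(
    out_path: str | Path,
    command: str,
    config: dict,
    input_paths: Sequence[str | Path] = (),
    seeds: dict | None = None,
) -> Path:
    """Write ``<out>.manifest.json`` next to an output file and return its path."""
    from . import __version__

    out_path = Path(out_path)
    config_json = json.dumps(config, sort_keys=True, default=str)
    manifest = RunManifest(
        tool="ftgr",
        version=__version__,
        command=command,
        config=json.loads(config_json),
        config_hash=hashlib.sha256(config_json.encode()).hexdigest()[:16],
        inputs={str(p): _digest(Path(p)) for p in input_paths},
        seeds=seeds or {},
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    manifest_path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return manifest_path
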