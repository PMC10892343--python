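"""Read/write the ten-file CSV assessment schema.

One assessment is a folder (or file set) named
``<subjectId>_<assessmentNumber>[_<suffix>].csv``:

========  ===========================================  ===========
suffix    contents                                     units
========  ===========================================  ===========
(none)    assessment metadata: date, manual FRT trials
acc       calibrated accelerometer                      m·s⁻²
acc_r     raw accelerometer                             m·s⁻²
gra       software gravity estimate                     m·s⁻²
gyr       calibrated gyroscope                          rad·s⁻¹
gyr_r     raw gyroscope                                 rad·s⁻¹
lin       software linear acceleration                  m·s⁻²
mag       calibrated magnetometer                       µT
mag_r     raw magnetometer                              µT
rot       rotation-vector quaternion                    unitless
========  ===========================================  ===========

Sensor files carry a header row and the columns ``system_ts_ms``
(milliseconds, system clock), ``sensor_ts_ns`` (nanoseconds, sensor event
clock), then ``X, Y, Z``; the ``rot`` file has a fourth value column
``rotL``.  ``rotL`` is interpreted as the scalar component *w* of the unit
quaternion (the Android rotation-vector ``values[3]``): a literal norm
column would be identically 1 and could not serve as an orientation
reference.  The metadata file uses a minimal ``key,value`` layout with the
trial results stored as a single semicolon-separated string.

Dialect: UTF-8, comma delimiter, decimal point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import KIND_UNITS, SensorStream

__all__ = ["AssessmentRecording", "read_assessment", "write_assessment", "SUFFIX_KIND"]

# suffix -> (sensor kind, raw flag)
SUFFIX_KIND: dict[str, tuple[str, bool]] = {
    "acc": ("accelerometer", False),
    "acc_r": ("accelerometer", True),
    "gra": ("gravity", False),
    "gyr": ("gyroscope", False),
    "gyr_r": ("gyroscope", True),
    "lin": ("linear_acceleration", False),
    "mag": ("magnetometer", False),
    "mag_r": ("magnetometer", True),
    "rot": ("rotation_vector", False),
}

_VALUE_COLUMNS = {"rot": ["X", "Y", "Z", "rotL"]}
_DEFAULT_COLUMNS = ["X", "Y", "Z"]


@dataclass
class AssessmentRecording:
    """One subject assessment: metadata plus the sensor stream set."""

    subject_id: str
    assessment_number: int
    date: str = ""
    manual_frt_cm: list[float] = field(default_factory=list)
    streams: dict[str, SensorStream] = field(default_factory=dict)

    def stem(self) -> str:
        return f"{self.subject_id}_{self.assessment_number}"

    @property
    def rotation_quaternions(self) -> np.ndarray | None:
        """Scalar-first (w, x, y, z) quaternions from the rot stream."""
        rot = self.streams.get("rot")
        if rot is None:
            return None
        v = rot.values
        return np.column_stack([v[:, 3], v[:, 0], v[:, 1], v[:, 2]])


def _read_sensor_file(path: Path, suffix: str) -> SensorStream:
    value_cols = _VALUE_COLUMNS.get(suffix, _DEFAULT_COLUMNS)
    expected = ["system_ts_ms", "sensor_ts_ns"] + value_cols
    df = pd.read_csv(path)
    for col in expected:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    numeric = df[expected].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        row = int(np.argmax(bad.any(axis=1).to_numpy()))
        raise ValueError(f"{path.name}: non-numeric or missing cell at data row {row}")
    kind, raw = SUFFIX_KIND[suffix]
    return SensorStream(
        kind=kind,
        t_ns=numeric["sensor_ts_ns"].to_numpy(dtype=np.int64),
        t_ms=numeric["system_ts_ms"].to_numpy(dtype=np.int64),
        values=numeric[value_cols].to_numpy(dtype=float),
        raw=raw,
        units=KIND_UNITS[kind],
    )


def _parse_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    df = pd.read_csv(path, header=None, names=["key", "value"], dtype=str)
    for _, row in df.iterrows():
        meta[str(row["key"])] = "" if pd.isna(row["value"]) else str(row["value"])
    return meta


def read_assessment(folder: str | Path, subject_id: str | None = None, assessment_number: int | None = None) -> AssessmentRecording:
    """Read an assessment file set from ``folder``.

    When ``subject_id``/``assessment_number`` are omitted, the folder must
    contain exactly one metadata file (the one without a suffix), from
    which they are inferred.  Missing optional sensor files simply yield
    absent streams.
    """
    folder = Path(folder)
    if subject_id is None or assessment_number is None:
        candidates = [
            p
            for p in sorted(folder.glob("*_*.csv"))
            if not any(p.stem.endswith("_" + s) for s in SUFFIX_KIND)
        ]
        if not candidates:
            expected = "<id>_<n>.csv plus " + ", ".join(
                f"<id>_<n>_{s}.csv" for s in SUFFIX_KIND
            )
            raise FileNotFoundError(f"no assessment metadata file in {folder}; expected {expected}")
        stem = candidates[0].stem
        subject_id, num = stem.rsplit("_", 1)
        assessment_number = int(num)
    stem = f"{subject_id}_{assessment_number}"
    meta_path = folder / f"{stem}.csv"
    rec = AssessmentRecording(subject_id=subject_id, assessment_number=assessment_number)
    if meta_path.exists():
        meta = _parse_metadata(meta_path)
        rec.date = meta.get("date", "")
        results = meta.get("frt_results", "")
        if results:
            rec.manual_frt_cm = [float(v) for v in results.split(";") if v]
    for suffix in SUFFIX_KIND:
        path = folder / f"{stem}_{suffix}.csv"
        if path.exists():
            rec.streams[suffix] = _read_sensor_file(path, suffix)
    if not rec.streams and not meta_path.exists():
        raise FileNotFoundError(f"no files for assessment {stem} in {folder}")
    return rec


def write_assessment(rec: AssessmentRecording, folder: str | Path) -> list[Path]:
    """Write ``rec`` as the ten-file schema; returns the paths written.

    Round-trips with :func:`read_assessment` (values and timestamps
    preserved).  Streams absent from ``rec.streams`` are simply not
    written.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta_path = folder / f"{rec.stem()}.csv"
    results = ";".join(repr(float(v)) for v in rec.manual_frt_cm)
    meta = pd.DataFrame([["date", rec.date], ["frt_results", results]])
    meta.to_csv(meta_path, header=False, index=False)
    written.append(meta_path)
    for suffix, stream in rec.streams.items():
        if suffix not in SUFFIX_KIND:
            raise ValueError(f"unknown stream suffix {suffix!r}")
        value_cols = _VALUE_COLUMNS.get(suffix, _DEFAULT_COLUMNS)
        if stream.values.shape[1] != len(value_cols):
            raise ValueError(
                f"stream {suffix!r} has {stream.values.shape[1]} value columns, expected {len(value_cols)}"
            )
        df = pd.DataFrame(
            {
                "system_ts_ms": stream.t_ms,
                "sensor_ts_ns": stream.t_ns,
                **{c: stream.values[:, i] for i, c in enumerate(value_cols)},
            }
        )
        path = folder / f"{rec.stem()}_{suffix}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    return written
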