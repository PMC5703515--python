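"""Reading and writing overnight SpO2 recordings and cohort tables.

A recording is an overnight series of peripheral oxygen saturation values in
percent, sampled at 1 Hz by a portable finger pulse-oximeter. Interchange
formats are a two-column CSV (``t_seconds,spo2``, one sample per row, missing
samples as empty cells) and, optionally, single-channel EDF (European Data
Format). Cohort tables hold one row per subject with the reference
apnea-hypopnea index (AHI) from polysomnography and the oximetry-based
estimates in each recording setting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpO2Recording",
    "SubjectRecord",
    "ValidityReport",
    "read_spo2",
    "write_spo2_csv",
    "write_spo2_edf",
    "check_validity",
    "read_cohort",
]

#: portable recordings shorter than this are discarded (significant signal
#: loss, battery depletion or early voluntary termination)
MIN_RECORDING_HOURS = 4.0


@dataclass
class SpO2Recording:
    """One overnight 1-Hz SpO2 series.

    ``samples`` is a float array in percent; missing samples are NaN.
    """

    subject_id: str
    samples: np.ndarray
    setting: str = "lab"  # "lab" (supervised) or "home" (unattended)
    sample_rate: float = 1.0
    start_time: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.setting not in ("lab", "home"):
            raise ValueError(f"unknown setting {self.setting!r}")
        finite = self.samples[np.isfinite(self.samples)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("saturation values must lie in [0, 100] %")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.samples)

    @property
    def duration_hours(self) -> float:
        """Total recording time in hours, (n-1)/fs, before artifact removal."""
        return (self.n_samples - 1) / self.sample_rate / 3600.0


@dataclass
class SubjectRecord:
    """Per-subject row of a cohort table (reference and estimated indices)."""

    subject_id: str
    group: str  # "nonCOPD", "COPD" or "training"
    ahi_psg: float
    ahi_ox_lab: float | None = None
    ahi_ox_home: float | None = None
    odi3: float | None = None
    odi4: float | None = None

    def __post_init__(self) -> None:
        for name in ("ahi_psg", "ahi_ox_lab", "ahi_ox_home", "odi3", "odi4"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass
class ValidityReport:
    valid: bool
    trt_hours: float
    reason: str = ""


def read_spo2(path: str | Path, format: str | None = None,
              subject_id: str | None = None, setting: str = "lab") -> SpO2Recording:
    """Read a recording from CSV or EDF; missing values are kept as NaN.

    The format is inferred from the file suffix unless given explicitly.
    """
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    sid = subject_id or path.stem
    if fmt == "csv":
        return _read_csv(path, sid, setting)
    if fmt == "edf":
        return _read_edf(path, sid, setting)
    raise ValueError(f"unknown format {fmt!r}")


def _read_csv(path: Path, subject_id: str, setting: str) -> SpO2Recording:
    ts, vals = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().lower() in ("t_seconds", "t", "time"):
                continue
            if len(row) == 1:
                t, v = len(vals), row[0]
            else:
                t, v = row[0], row[1]
            ts.append(float(t))
            v = v.strip()
            try:
                vals.append(float(v)) if v else vals.append(np.nan)
            except ValueError:
                vals.append(np.nan)  # non-numeric quality flag -> missing
    if not vals:
        raise ValueError(f"{path}: no samples found")
    ts_arr = np.asarray(ts, float)
    if len(ts_arr) > 1:
        dt = np.diff(ts_arr)
        if not np.allclose(dt, dt[0]):
            raise ValueError(f"{path}: non-uniform sampling cannot be regularized")
    rate = 1.0 if len(ts_arr) < 2 else 1.0 / float(np.diff(ts_arr)[0])
    return SpO2Recording(subject_id, np.asarray(vals), setting=setting,
                         sample_rate=rate)


def _read_edf(path: Path, subject_id: str, setting: str) -> SpO2Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = [n for n in raw.ch_names if "spo2" in n.lower().replace("_", "")]
    if not names:
        raise ValueError(f"{path}: no SpO2-labelled channel found")
    data = raw.get_data(picks=names[:1])[0]
    rate = float(raw.info["sfreq"])
    if rate != 1.0:
        # decimate/average to the 1-Hz series all processing assumes
        step = int(round(rate))
        if not np.isclose(rate, step):
            raise ValueError(f"{path}: cannot regularize {rate} Hz to 1 Hz")
        data = data[: (len(data) // step) * step].reshape(-1, step).mean(axis=1)
        rate = 1.0
    data = np.where((data < 0) | (data > 100), np.nan, data)
    return SpO2Recording(subject_id, data, setting=setting, sample_rate=rate)


def write_spo2_csv(rec: SpO2Recording, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t_seconds", "spo2"])
        for i, v in enumerate(rec.samples):
            w.writerow([i / rec.sample_rate, "" if not np.isfinite(v) else repr(float(v))])


def write_spo2_edf(rec: SpO2Recording, path: str | Path) -> None:
    """Write a minimal single-channel EDF file (synthetic writer).

    Implements just enough of the EDF layout (one SpO2 channel, 1-s data
    records, 16-bit integers) for interchange and read round-trips; it is not
    a general-purpose EDF exporter.
    """
    if rec.sample_rate != 1.0:
        raise ValueError("EDF writer only supports 1-Hz recordings")
    x = rec.samples.copy()
    x[~np.isfinite(x)] = 0.0  # EDF has no NaN; missing encoded as 0 (artifact)
    spr = 60  # samples per data record
    n = len(x)
    nrec = int(np.ceil(n / spr))
    pad = np.zeros(nrec * spr - n)
    x = np.concatenate([x, pad])
    dig = np.round(x / 100.0 * 32767).astype("<i2")

    def f(s: str, width: int) -> bytes:
        return s.ljust(width)[:width].encode("ascii")

    header = b"".join([
        f("0", 8), f(rec.subject_id, 80), f("oxiscreen", 80),
        f("01.01.00", 8), f("00.00.00", 8), f(str(256 + 256), 8), f("", 44),
        f(str(nrec), 8), f(str(spr), 8), f("1", 4),  # record length 60 s at 1 Hz
    ])
    chan = b"".join([
        f("SpO2", 16), f("pulse oximeter", 80), f("%", 8),
        f("0", 8), f("100", 8), f("0", 8), f("32767", 8),
        f("", 80), f(str(spr), 8), f("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header + chan)
        fh.write(dig.tobytes())


def check_validity(rec: SpO2Recording, setting: str | None = None,
                   min_hours: float = MIN_RECORDING_HOURS) -> ValidityReport:
    """Flag portable recordings too short to score (TRT strictly below 4 h).

    TRT is computed on the raw series, before artifact removal. A recording
    of exactly ``min_hours`` is valid (the exclusion rule is a strict "<").
    """
    trt = rec.duration_hours
    if trt < min_hours:
        return ValidityReport(False, trt, f"TRT<{min_hours:g}h")
    return ValidityReport(True, trt)


_COHORT_COLUMNS = {
    "subject_id": "subject_id", "subject": "subject_id", "id": "subject_id",
    "group": "group",
    "ahi_psg": "ahi_psg", "actual_ahi": "ahi_psg",
    "ahi_ox_lab": "ahi_ox_lab", "ahi_ox-lab": "ahi_ox_lab",
    "ahi_ox_home": "ahi_ox_home", "ahi_ox-home": "ahi_ox_home",
    "odi3": "odi3", "odi4": "odi4",
}


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read a per-subject cohort CSV (reference AHI plus optional estimates)."""
    df = pd.read_csv(path)
    df.columns = [_COHORT_COLUMNS.get(c.strip().lower(), c.strip().lower())
                  for c in df.columns]
    if "ahi_psg" not in df.columns:
        raise ValueError(f"{path}: cohort table needs an actual-AHI column")
    out = []
    for i, row in df.iterrows():
        def opt(col: str):
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        out.append(SubjectRecord(
            subject_id=str(row.get("subject_id", i)),
            group=str(row.get("group", "nonCOPD")),
            ahi_psg=float(row["ahi_psg"]),
            ahi_ox_lab=opt("ahi_ox_lab"), ahi_ox_home=opt("ahi_ox_home"),
            odi3=opt("odi3"), odi4=opt("odi4"),
        ))
    return out
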