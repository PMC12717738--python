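"""Reading, writing and validating 12-lead ECG records and triplicate groupings.

Canonical conventions used throughout the package:

* amplitudes are stored in microvolts (µV),
* times are expressed in milliseconds (ms),
* sample indices are 0-based and windows are half-open ``[start, end)``,
* the lead order is always the canonical 12-lead order
  ``I, II, III, aVR, aVL, aVF, V1 .. V6``.

On-disk format is a documented CSV dialect: a header row of lead names, one
sample per row, comma separated, with acquisition metadata in a JSON sidecar
file named ``<record>.meta.json`` next to the CSV.  The sidecar carries the
sampling rate (samples/s), the acquisition low-pass cutoff (Hz), the amplitude
unit of the CSV body (``uV`` or ``mV``), a free-text device label and an
optional acquisition timestamp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

__all__ = [
    "LEADS",
    "FRONTAL_LEADS",
    "PRECORDIAL_LEADS",
    "AcquisitionMeta",
    "EcgRecord",
    "TripletSet",
    "QualityReport",
    "EcgIoError",
    "read_record",
    "write_record",
    "validate_record",
    "read_manifest",
]

#: Canonical 12-lead order; every EcgRecord stores its rows in this order.
LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

FRONTAL_LEADS: tuple[str, ...] = LEADS[:6]
PRECORDIAL_LEADS: tuple[str, ...] = LEADS[6:]

_LEAD_BY_UPPER = {name.upper(): name for name in LEADS}

#: Amplitude units accepted in CSV sidecars, as multipliers to µV.
_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1000.0, "V": 1e6}

#: Quantization step (µV) used when writing CSV bodies.
CSV_QUANTUM_UV = 0.001


class EcgIoError(ValueError):
    """Raised for malformed records, unknown units or missing leads."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata attached to every record."""

    sampling_rate: float = 1000.0  # samples/s
    lowpass_cutoff: float | None = 150.0  # Hz
    device_label: str = "synthetic"
    acquired_at: str | None = None

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise EcgIoError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.lowpass_cutoff is not None and not self.lowpass_cutoff > 0:
            raise EcgIoError(f"lowpass_cutoff must be > 0, got {self.lowpass_cutoff}")


@dataclass(frozen=True)
class EcgRecord:
    """A 12-lead ECG: ``data[i]`` is lead ``LEADS[i]`` in µV.

    ``data`` has shape ``(12, n_samples)``; all amplitudes must be finite.
    """

    data: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    record_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] != len(LEADS):
            raise EcgIoError(
                f"expected data of shape (12, n), got {np.asarray(self.data).shape}"
            )
        if data.shape[1] == 0:
            raise EcgIoError("record has no samples")
        if not np.all(np.isfinite(data)):
            raise EcgIoError("record contains non-finite amplitudes")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def sampling_rate(self) -> float:
        return self.meta.sampling_rate

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.duration_s

    def lead(self, name: str) -> np.ndarray:
        """Return one lead by (case-insensitive) name."""
        key = name.upper()
        if key not in _LEAD_BY_UPPER:
            raise EcgIoError(f"unknown lead name {name!r}")
        return self.data[LEADS.index(_LEAD_BY_UPPER[key])]

    def ms_to_sample(self, t_ms: float) -> int:
        return int(round(t_ms * self.sampling_rate / 1000.0))

    def sample_to_ms(self, idx: int) -> float:
        return 1000.0 * idx / self.sampling_rate


@dataclass(frozen=True)
class TripletSet:
    """Three nominally 10-s records from one acquisition session, in order."""

    records: tuple[EcgRecord, EcgRecord, EcgRecord]
    subject_id: str = ""
    visit_label: str = ""

    def __post_init__(self) -> None:
        if len(self.records) != 3:
            raise EcgIoError(f"a triplicate needs exactly 3 records, got {len(self.records)}")
        rates = {r.sampling_rate for r in self.records}
        if len(rates) != 1:
            raise EcgIoError(f"triplicate members disagree on sampling rate: {sorted(rates)}")
        for k, rec in enumerate(self.records):
            if not 9.5 <= rec.duration_s <= 10.5:
                raise EcgIoError(
                    f"triplicate member {k} has duration {rec.duration_s:.2f} s, "
                    "outside the accepted 9.5-10.5 s"
                )
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def sampling_rate(self) -> float:
        return self.records[0].sampling_rate


@dataclass(frozen=True)
class QualityCheck:
    name: str
    passed: bool
    message: str


@dataclass(frozen=True)
class QualityReport:
    """Report-only output of :func:`validate_record`."""

    checks: tuple[QualityCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed_checks(self) -> list[QualityCheck]:
        return [c for c in self.checks if not c.passed]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_record(path: str | Path, format: str = "csv") -> EcgRecord:
    """Read an ECG record, normalizing unit to µV and lead order to canonical.

    Parameters
    ----------
    path:
        Path to the CSV body; the JSON sidecar ``<path>.meta.json`` must exist.
    format:
        Only ``"csv"`` (the documented dialect) is supported.
    """
    if format != "csv":
        raise EcgIoError(f"unsupported format {format!r}; supported formats: 'csv'")
    path = Path(path)
    if not path.exists():
        raise EcgIoError(f"record file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise EcgIoError(f"metadata sidecar not found: {sidecar}")
    meta_raw = json.loads(sidecar.read_text())

    unit = meta_raw.get("units")
    if unit not in _UNIT_TO_UV:
        raise EcgIoError(
            f"unknown amplitude unit {unit!r} in {sidecar}; accepted: {sorted(_UNIT_TO_UV)}"
        )
    scale = _UNIT_TO_UV[unit]
    if "sampling_rate" not in meta_raw:
        raise EcgIoError(f"sidecar {sidecar} lacks 'sampling_rate'")
    meta = AcquisitionMeta(
        sampling_rate=float(meta_raw["sampling_rate"]),
        lowpass_cutoff=meta_raw.get("lowpass_cutoff"),
        device_label=str(meta_raw.get("device_label", "")),
        acquired_at=meta_raw.get("acquired_at"),
    )

    with path.open() as fh:
        header = fh.readline().strip()
    names = [h.strip() for h in header.split(",")]
    mapped: list[str] = []
    for h in names:
        if h.upper() not in _LEAD_BY_UPPER:
            raise EcgIoError(f"unknown lead label {h!r} in {path}")
        mapped.append(_LEAD_BY_UPPER[h.upper()])
    missing = [l for l in LEADS if l not in mapped]
    if missing:
        raise EcgIoError(f"record {path} is missing lead(s): {', '.join(missing)}")
    if len(set(mapped)) != len(mapped):
        raise EcgIoError(f"record {path} has duplicated lead columns")

    body = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if body.shape[1] != len(mapped):
        raise EcgIoError(
            f"record {path}: {body.shape[1]} columns in body vs {len(mapped)} in header"
        )
    order = [mapped.index(l) for l in LEADS]
    data = body.T[order] * scale
    return EcgRecord(data=data, meta=meta, record_id=path.stem)


def write_record(record: EcgRecord, path: str | Path, format: str = "csv") -> Path:
    """Write a record in the documented CSV dialect (µV body + JSON sidecar).

    Round-trip error through :func:`read_record` is bounded by half the
    quantization step (0.001 µV).
    """
    if format != "csv":
        raise EcgIoError(f"unsupported format {format!r}; supported formats: 'csv'")
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        header = ",".join(LEADS)
        np.savetxt(path, record.data.T, delimiter=",", fmt="%.3f",
                   header=header, comments="")
        sidecar = _sidecar_path(path)
        meta = {
            "units": "uV",
            "sampling_rate": record.meta.sampling_rate,
            "lowpass_cutoff": record.meta.lowpass_cutoff,
            "device_label": record.meta.device_label,
            "acquired_at": record.meta.acquired_at,
        }
        sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    except OSError as exc:
        raise EcgIoError(f"cannot write record to {path}: {exc}") from exc
    return path


def validate_record(
    record: EcgRecord,
    expect_duration_s: tuple[float, float] | None = (9.5, 10.5),
) -> QualityReport:
    """Run report-only quality checks: duration, flatline, clipping, rate.

    ``expect_duration_s`` is the accepted duration band for triplicate
    members; pass ``None`` to skip it (e.g. for 30-s concatenated records).
    """
    checks: list[QualityCheck] = []

    if expect_duration_s is not None:
        lo, hi = expect_duration_s
        ok = lo <= record.duration_s <= hi
        checks.append(QualityCheck(
            "duration", ok,
            f"duration {record.duration_s:.2f} s "
            f"({'within' if ok else 'outside'} [{lo}, {hi}] s)",
        ))

    fs = record.sampling_rate
    max_flat = int(2.0 * fs)  # no lead may be constant for > 2 s
    flat_leads = []
    for i, name in enumerate(LEADS):
        x = record.data[i]
        # longest run of consecutive equal samples
        change = np.flatnonzero(np.diff(x) != 0)
        bounds = np.concatenate(([-1], change, [x.size - 1]))
        longest = int(np.max(np.diff(bounds)))
        if longest > max_flat:
            flat_leads.append(name)
    checks.append(QualityCheck(
        "flatline", not flat_leads,
        "no flat segments > 2 s" if not flat_leads
        else f"flat segment > 2 s on lead(s): {', '.join(flat_leads)}",
    ))

    clipped = []
    for i, name in enumerate(LEADS):
        x = record.data[i]
        lo_v, hi_v = x.min(), x.max()
        if hi_v == lo_v:
            continue  # flatline check covers this
        frac = np.mean((x == lo_v) | (x == hi_v))
        if frac > 0.01:
            clipped.append(name)
    checks.append(QualityCheck(
        "clipping", not clipped,
        "< 1% samples at range limits" if not clipped
        else f">= 1% samples at amplitude-range limits on: {', '.join(clipped)}",
    ))

    ok = fs >= 250.0
    checks.append(QualityCheck(
        "sampling_rate", ok, f"sampling rate {fs:g} samples/s ({'OK' if ok else '< 250'})"
    ))
    return QualityReport(checks=tuple(checks))


def read_manifest(path: str | Path) -> list[dict]:
    """Read a triplicate manifest: CSV with columns subject_id, visit_label,
    path_1, path_2, path_3 (paths relative to the manifest's directory)."""
    path = Path(path)
    if not path.exists():
        raise EcgIoError(f"manifest not found: {path}")
    import csv

    rows = []
    with path.open() as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "visit_label", "path_1", "path_2", "path_3"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise EcgIoError(
                f"manifest {path} must have columns {sorted(required)}; "
                f"found {reader.fieldnames}"
            )
        for row in reader:
            rows.append({
                "subject_id": row["subject_id"],
                "visit_label": row["visit_label"],
                "paths": [path.parent / row[f"path_{k}"] for k in (1, 2, 3)],
            })
    if not rows:
        raise EcgIoError(f"manifest {path} has no entries")
    return rows
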