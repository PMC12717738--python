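"""ECG parameters from fiducials and the representative beat.

Covers heart rate, PR, QRS, QT and its heart-rate corrections (Fridericia
and Bazett, both from the averaged RR interval), per-lead R/S amplitudes,
the Sokolow-Lyon voltage indices (S in V1 plus R in V5 or V6), and the
low-QRS-voltage flag (YES when every frontal lead stays <= 500 µV or every
precordial lead stays <= 1000 µV peak-to-peak within the QRS).

Voltage conventions: Sokolow-Lyon uses baseline-referenced peak amplitudes
(baseline = representative value at QRS onset, the isoelectric reference);
the low-voltage rule uses within-QRS peak-to-peak.  Both are documented
choices, exposed here explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .ecg_io import FRONTAL_LEADS, LEADS, PRECORDIAL_LEADS
from .fiducials import FiducialSet
from .representative import RepresentativeBeat

__all__ = [
    "MeasurementSet",
    "MeasureError",
    "measure_intervals",
    "qtc",
    "wave_amplitudes",
    "sokolow",
    "low_voltage_flag",
    "measure_all",
    "round_half_away",
    "MEASUREMENT_COLUMNS",
]

#: Fixed column order of the one-row-per-record CSV export.
MEASUREMENT_COLUMNS = (
    "record_id", "provenance", "n_beats", "hr_bpm", "mean_rr_ms",
    "pr_ms", "qrs_ms", "qt_ms", "qtcf_ms", "qtcb_ms",
    "soko_v5_uv", "soko_v6_uv", "low_voltage",
)


class MeasureError(ValueError):
    """Raised for missing required fiducials or non-positive inputs."""


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (display convention for reports)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class MeasurementSet:
    """All reported parameters for one analysis (single record, TAM or TCM)."""

    hr_bpm: float
    mean_rr_ms: float
    qrs_ms: float
    pr_ms: float | None = None
    qt_ms: float | None = None
    qtcf_ms: float | None = None
    qtcb_ms: float | None = None
    r_amp_uv: Mapping[str, float] = field(default_factory=dict)
    s_amp_uv: Mapping[str, float] = field(default_factory=dict)
    soko_v5_uv: float | None = None
    soko_v6_uv: float | None = None
    low_voltage: bool | None = None
    provenance: str = "single"
    n_beats: int | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.provenance not in ("single", "tam", "tcm"):
            raise MeasureError(f"unknown provenance {self.provenance!r}")
        if (self.qt_ms is None) != (self.qtcf_ms is None):
            raise MeasureError("qtcf present iff qt present")

    def as_row(self) -> dict:
        """One CSV row in the documented column order (display rounding:
        intervals 1 ms, voltages 1 µV, QTc 0.1 ms)."""
        def r(x, d=0):
            return None if x is None else round_half_away(x, d)

        return {
            "record_id": self.record_id,
            "provenance": self.provenance,
            "n_beats": self.n_beats,
            "hr_bpm": r(self.hr_bpm, 1),
            "mean_rr_ms": r(self.mean_rr_ms),
            "pr_ms": r(self.pr_ms),
            "qrs_ms": r(self.qrs_ms),
            "qt_ms": r(self.qt_ms),
            "qtcf_ms": r(self.qtcf_ms, 1),
            "qtcb_ms": r(self.qtcb_ms, 1),
            "soko_v5_uv": r(self.soko_v5_uv),
            "soko_v6_uv": r(self.soko_v6_uv),
            "low_voltage": None if self.low_voltage is None
            else ("YES" if self.low_voltage else "NO"),
        }


def measure_intervals(fids: FiducialSet, mean_rr: float) -> dict[str, float | None]:
    """PR, QRS, QT (ms) and HR (bpm) from the global marks.

    PR is absent when no P onset was found; QT is absent without a T offset.
    """
    if fids.qrs_onset_ms is None or fids.qrs_offset_ms is None:
        raise MeasureError("QRS onset/offset are required")
    if not mean_rr > 0:
        raise MeasureError(f"mean_rr must be > 0, got {mean_rr}")
    pr = None if fids.p_onset_ms is None else fids.qrs_onset_ms - fids.p_onset_ms
    qt = None if fids.t_offset_ms is None else fids.t_offset_ms - fids.qrs_onset_ms
    return {
        "pr_ms": pr,
        "qrs_ms": fids.qrs_offset_ms - fids.qrs_onset_ms,
        "qt_ms": qt,
        "hr_bpm": 60000.0 / mean_rr,
    }


def qtc(qt: float, mean_rr: float, formula: str = "fridericia") -> float:
    """Heart-rate-corrected QT from the averaged RR interval.

    Fridericia divides by the cube root of RR in seconds; Bazett by the
    square root.
    """
    if not (qt > 0 and mean_rr > 0):
        raise MeasureError(f"qt and mean_rr must be > 0, got qt={qt}, rr={mean_rr}")
    rr_s = mean_rr / 1000.0
    if formula == "fridericia":
        return qt / rr_s ** (1.0 / 3.0)
    if formula == "bazett":
        return qt / rr_s**0.5
    raise MeasureError(f"unknown QTc formula {formula!r}")


def wave_amplitudes(
    rep: RepresentativeBeat,
    fids: FiducialSet,
    baseline: str = "pr_median",
) -> dict[str, dict[str, float]]:
    """Per-lead R/S amplitudes and QRS peak-to-peak voltages (µV).

    The per-lead isoelectric reference is, by default, the median of the
    representative signal over the late PR segment ([qrs_onset − 45,
    qrs_onset − 5) ms), which is insensitive to the onset mark landing a
    couple of ms inside the Q lobe; ``baseline="onset"`` uses the value at
    the QRS onset sample instead.  Within the half-open window
    [qrs_onset, qrs_offset): R amplitude is the maximum positive excursion
    above baseline (floored at 0), S amplitude the maximum negative
    excursion below baseline (floored at 0), peak-to-peak the max minus min
    of the raw lead signal.
    """
    if fids.qrs_onset_ms is None or fids.qrs_offset_ms is None:
        raise MeasureError("QRS marks are required for amplitude measurement")
    if baseline not in ("pr_median", "onset"):
        raise MeasureError(f"unknown baseline rule {baseline!r}")
    i0 = rep.ms_to_sample(fids.qrs_onset_ms)
    i1 = rep.ms_to_sample(fids.qrs_offset_ms)
    if i1 <= i0:
        raise MeasureError("empty QRS window")
    b0 = max(rep.ms_to_sample(fids.qrs_onset_ms - 45.0), 0)
    b1 = max(rep.ms_to_sample(fids.qrs_onset_ms - 5.0), b0 + 1)
    r_amp, s_amp, p2p = {}, {}, {}
    for k, lead in enumerate(LEADS):
        seg = rep.data[k, i0:i1]
        if baseline == "pr_median":
            base = float(np.median(rep.data[k, b0:b1]))
        else:
            base = float(rep.data[k, i0])
        r_amp[lead] = float(max(seg.max() - base, 0.0))
        s_amp[lead] = float(max(base - seg.min(), 0.0))
        p2p[lead] = float(seg.max() - seg.min())
    return {"r_amp": r_amp, "s_amp": s_amp, "peak_to_peak": p2p}


def sokolow(amps: dict[str, dict[str, float]]) -> tuple[float, float]:
    """Sokolow-Lyon voltages: (S_V1 + R_V5, S_V1 + R_V6) in µV."""
    try:
        s_v1 = amps["s_amp"]["V1"]
        r_v5 = amps["r_amp"]["V5"]
        r_v6 = amps["r_amp"]["V6"]
    except KeyError as exc:
        raise MeasureError(f"missing amplitude for lead {exc}") from exc
    return s_v1 + r_v5, s_v1 + r_v6


def low_voltage_flag(peak_to_peak: Mapping[str, float]) -> bool:
    """YES iff all frontal leads <= 500 µV or all precordial leads <= 1000 µV."""
    missing = [l for l in LEADS if l not in peak_to_peak]
    if missing:
        raise MeasureError(f"missing lead(s) for low-voltage rule: {', '.join(missing)}")
    frontal_low = all(peak_to_peak[l] <= 500.0 for l in FRONTAL_LEADS)
    precordial_low = all(peak_to_peak[l] <= 1000.0 for l in PRECORDIAL_LEADS)
    return frontal_low or precordial_low


def measure_all(
    rep: RepresentativeBeat,
    fids: FiducialSet,
    provenance: str = "single",
    record_id: str = "",
) -> MeasurementSet:
    """Assemble the full MeasurementSet from a delineated representative beat."""
    intervals = measure_intervals(fids, rep.mean_rr_ms)
    qt = intervals["qt_ms"]
    qtcf = qtc(qt, rep.mean_rr_ms, "fridericia") if qt is not None else None
    qtcb = qtc(qt, rep.mean_rr_ms, "bazett") if qt is not None else None
    amps = wave_amplitudes(rep, fids)
    soko_v5, soko_v6 = sokolow(amps)
    return MeasurementSet(
        hr_bpm=intervals["hr_bpm"], mean_rr_ms=rep.mean_rr_ms,
        pr_ms=intervals["pr_ms"], qrs_ms=intervals["qrs_ms"],
        qt_ms=qt, qtcf_ms=qtcf, qtcb_ms=qtcb,
        r_amp_uv=amps["r_amp"], s_amp_uv=amps["s_amp"],
        soko_v5_uv=soko_v5, soko_v6_uv=soko_v6,
        low_voltage=low_voltage_flag(amps["peak_to_peak"]),
        provenance=provenance, n_beats=rep.n_beats, record_id=record_id,
    )
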