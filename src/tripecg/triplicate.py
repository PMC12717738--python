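"""Triplicate analysis strategies.

TAM (triplicate assessment method): each 10-s record of the triplicate is
analyzed independently through the full pipeline and the three measurement
sets are aggregated (arithmetic mean by default; majority vote for the
low-voltage flag).

TCM (triplicate concatenation method): the three records are joined into a
single ~30-s record (after per-segment, per-lead baseline alignment); beats
whose 1.2-s window intersects an exclusion zone around either junction are
discarded, and a single pooled median beat over all remaining sinus beats is
delineated once.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np

from .ecg_io import EcgRecord, TripletSet
from .measures import MeasurementSet
from .pipeline import AnalysisResult, PipelineConfig, analyze_record

__all__ = ["ConcatenatedRecord", "JUNCTION_EXCLUSION_MS",
           "concatenate_tcm", "analyze_tcm", "analyze_tam"]

#: Half-width of the beat-exclusion zone around each junction: one
#: representative-window length, so no pooled beat can straddle a join.
JUNCTION_EXCLUSION_MS = 600.0


@dataclass(frozen=True)
class ConcatenatedRecord:
    """A ~30-s concatenation with its junction bookkeeping (times in ms)."""

    record: EcgRecord
    junction_times_ms: tuple[float, float]
    excluded_zones_ms: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        j1, j2 = self.junction_times_ms
        if not 0 < j1 < j2 < self.record.duration_ms:
            raise ValueError(f"junctions must be strictly increasing inside the "
                             f"record, got {self.junction_times_ms}")
        for (lo, hi), j in zip(self.excluded_zones_ms, self.junction_times_ms):
            if not lo <= j <= hi:
                raise ValueError("excluded zone does not contain its junction")


def concatenate_tcm(
    triplet: TripletSet,
    exclusion_ms: float = JUNCTION_EXCLUSION_MS,
) -> ConcatenatedRecord:
    """Concatenate the three members in acquisition order.

    Each segment is baseline-aligned by subtracting its per-lead median
    before joining, so step artifacts at the junctions come only from the
    waveforms themselves, and segment medians agree after alignment.
    """
    segs = [rec.data - np.median(rec.data, axis=1, keepdims=True)
            for rec in triplet.records]
    data = np.concatenate(segs, axis=1)
    fs = triplet.sampling_rate
    n1, n2 = triplet.records[0].n_samples, triplet.records[1].n_samples
    j1 = n1 * 1000.0 / fs
    j2 = (n1 + n2) * 1000.0 / fs
    record = EcgRecord(
        data=data, meta=triplet.records[0].meta,
        record_id=f"{triplet.subject_id}-{triplet.visit_label}-tcm",
    )
    zones = ((j1 - exclusion_ms, j1 + exclusion_ms),
             (j2 - exclusion_ms, j2 + exclusion_ms))
    return ConcatenatedRecord(record=record, junction_times_ms=(j1, j2),
                              excluded_zones_ms=zones)


def analyze_tcm(
    triplet: TripletSet,
    cfg: PipelineConfig = PipelineConfig(),
    exclusion_ms: float = JUNCTION_EXCLUSION_MS,
) -> AnalysisResult:
    """One 30-s analysis: concatenate, drop junction-overlapping beats,
    pool the remaining sinus beats into a single median beat, delineate once.

    The pooled mean RR over all accepted sinus beats (junction-crossing RR
    pairs excluded) feeds HR and QTc.
    """
    conc = concatenate_tcm(triplet, exclusion_ms=exclusion_ms)
    return analyze_record(
        conc.record, cfg, provenance="tcm",
        excluded_zones_ms=conc.excluded_zones_ms,
    )


def _aggregate(values: list[float | None], rule: str) -> float | None:
    present = [v for v in values if v is not None]
    if len(present) != len(values):
        return None  # a parameter missing in any member is missing in TAM
    if rule == "mean":
        return float(np.mean(present))
    if rule == "median":
        return float(median(present))
    raise ValueError(f"unknown TAM aggregation rule {rule!r}")


def analyze_tam(
    triplet: TripletSet,
    cfg: PipelineConfig = PipelineConfig(),
    aggregate: str = "mean",
) -> tuple[MeasurementSet, list[AnalysisResult]]:
    """Three independent 10-s analyses plus their per-parameter aggregate.

    Any member failing hard fails TAM, naming the member.  Returns the
    aggregated MeasurementSet (provenance ``tam``) and the three per-record
    results.
    """
    results: list[AnalysisResult] = []
    for k, rec in enumerate(triplet.records):
        try:
            results.append(analyze_record(rec, cfg, provenance="single"))
        except Exception as exc:
            raise RuntimeError(
                f"TAM failed on triplicate member {k + 1} "
                f"({rec.record_id or 'unnamed'}): {exc}"
            ) from exc

    ms = [r.measurements for r in results]
    mean_rr = _aggregate([m.mean_rr_ms for m in ms], aggregate)
    qt = _aggregate([m.qt_ms for m in ms], aggregate)
    low_votes = [m.low_voltage for m in ms if m.low_voltage is not None]
    agg = MeasurementSet(
        hr_bpm=60000.0 / mean_rr,
        mean_rr_ms=mean_rr,
        pr_ms=_aggregate([m.pr_ms for m in ms], aggregate),
        qrs_ms=_aggregate([m.qrs_ms for m in ms], aggregate),
        qt_ms=qt,
        qtcf_ms=_aggregate([m.qtcf_ms for m in ms], aggregate),
        qtcb_ms=_aggregate([m.qtcb_ms for m in ms], aggregate),
        soko_v5_uv=_aggregate([m.soko_v5_uv for m in ms], aggregate),
        soko_v6_uv=_aggregate([m.soko_v6_uv for m in ms], aggregate),
        low_voltage=(sum(low_votes) * 2 > len(low_votes)) if low_votes else None,
        provenance="tam",
        n_beats=sum(m.n_beats or 0 for m in ms),
        record_id=f"{triplet.subject_id}-{triplet.visit_label}-tam",
    )
    return agg, results
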