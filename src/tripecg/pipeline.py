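"""Single-record analysis pipeline: detect → classify → median beat → VM →
fiducials → measurements.  The triplicate strategies build on this."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import BeatAnnotations, DetectorConfig, classify_beats, detect_r_peaks
from .ecg_io import EcgRecord
from .fiducials import FiducialSet, ThresholdConfig, detect_fiducials
from .measures import MeasurementSet, measure_all
from .representative import RepresentativeBeat, build_representative, vector_magnitude

__all__ = ["PipelineConfig", "AnalysisResult", "analyze_record"]


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of all tunable constants of the analysis pipeline."""

    detector: DetectorConfig = field(default_factory=DetectorConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)


@dataclass(frozen=True)
class AnalysisResult:
    """Measurements plus the intermediates that produced them."""

    measurements: MeasurementSet
    annotations: BeatAnnotations
    representative: RepresentativeBeat
    vm: np.ndarray
    fiducials: FiducialSet


def analyze_record(
    record: EcgRecord,
    cfg: PipelineConfig = PipelineConfig(),
    provenance: str = "single",
    excluded_zones_ms: tuple[tuple[float, float], ...] = (),
) -> AnalysisResult:
    """Run the full semi-automated pipeline on one record.

    ``excluded_zones_ms`` marks half-open ms intervals whose overlapping
    beats are excluded (used for concatenation junctions).
    """
    peaks = detect_r_peaks(record, cfg.detector)
    ann = classify_beats(record, peaks, cfg.detector,
                         excluded_zones_ms=excluded_zones_ms)
    rep = build_representative(record, ann)
    vm = vector_magnitude(rep)
    fids = detect_fiducials(vm, rep, cfg.thresholds)
    meas = measure_all(rep, fids, provenance=provenance,
                       record_id=record.record_id)
    return AnalysisResult(measurements=meas, annotations=ann,
                         representative=rep, vm=vm, fiducials=fids)
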