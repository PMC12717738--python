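"""R-peak detection and sinus/PVC/artifact beat classification.

Detection runs on a composite channel — the per-sample root-sum-of-squares
across all 12 leads (the same construction as the vector magnitude used for
fiducial placement, applied earlier in the pipeline).  This makes detection
robust to any single lead's polarity or amplitude.

The detector band-passes the composite (5-25 Hz), squares it, and thresholds
at a fraction of a rolling 2-s maximum with a 200-ms refractory period;
detected peaks are then refined to the local maximum of the raw composite.
Classification labels a beat as PVC when its cross-correlation with the
two-pass median beat template falls below a threshold, or when it is both
premature and moderately dissimilar.  Beats whose full 1.2-s representative
window does not fit inside the record (or intersects a caller-supplied
exclusion zone, e.g. a concatenation junction) are labelled artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .ecg_io import EcgRecord

__all__ = [
    "DetectorConfig",
    "BeatAnnotations",
    "BeatDetectionError",
    "composite_channel",
    "detect_r_peaks",
    "classify_beats",
]

# Representative-beat window geometry (shared with the representative module).
WINDOW_MS = 1200.0
R_OFFSET_MS = 400.0  # R-peak position inside the window: 400 ms pre-R, 800 post


class BeatDetectionError(RuntimeError):
    """Raised when no beats (or no sinus beats) can be found."""


@dataclass(frozen=True)
class DetectorConfig:
    """Constants of the R-peak detector and the PVC classifier.

    All time quantities are ms; thresholds are dimensionless fractions.
    """

    bandpass_low_hz: float = 5.0
    bandpass_high_hz: float = 25.0
    threshold_fraction: float = 0.4  # of the rolling 2-s maximum of the squared signal
    rolling_max_ms: float = 2000.0
    refractory_ms: float = 200.0
    refine_radius_ms: float = 50.0
    # PVC classification
    corr_window_ms: float = 150.0  # half-width of the correlation window around R
    corr_lag_ms: float = 10.0
    pvc_corr_threshold: float = 0.90
    premature_rr_fraction: float = 0.80
    premature_corr_threshold: float = 0.95
    # RR bookkeeping: drop sinus-to-sinus gaps exceeding this multiple of the
    # median gap (guards junction-crossing pairs in concatenated records)
    rr_gap_multiple: float = 1.75


def composite_channel(record: EcgRecord) -> np.ndarray:
    """Per-sample root-sum-of-squares across leads, per-lead median removed."""
    centred = record.data - np.median(record.data, axis=1, keepdims=True)
    return np.sqrt(np.sum(centred**2, axis=0))


def detect_r_peaks(record: EcgRecord, cfg: DetectorConfig = DetectorConfig()) -> np.ndarray:
    """Detect R peaks on the composite channel; returns 0-based sample indices.

    Requires a record of at least 2 s with at least one non-flat lead.
    Raises :class:`BeatDetectionError` when nothing is detected.
    """
    if record.duration_s < 2.0:
        raise BeatDetectionError(
            f"record too short for beat detection ({record.duration_s:.2f} s < 2 s)"
        )
    comp = composite_channel(record)
    if np.ptp(comp) == 0:
        raise BeatDetectionError("no beats detected: all leads are flat")

    fs = record.sampling_rate
    nyq = fs / 2.0
    sos = sps.butter(2, [cfg.bandpass_low_hz / nyq, cfg.bandpass_high_hz / nyq],
                     btype="band", output="sos")
    filt = sps.sosfiltfilt(sos, comp - comp.mean())
    energy = filt**2

    win = max(3, int(round(cfg.rolling_max_ms * fs / 1000.0)))
    from scipy.ndimage import maximum_filter1d

    local_max = maximum_filter1d(energy, size=win, mode="nearest")
    threshold = cfg.threshold_fraction * local_max
    # a global floor rejects detections in pathological all-noise stretches
    floor = 0.01 * float(np.max(energy))

    distance = max(1, int(round(cfg.refractory_ms * fs / 1000.0)))
    peaks, _ = sps.find_peaks(energy, distance=distance)
    peaks = peaks[(energy[peaks] >= threshold[peaks]) & (energy[peaks] >= floor)]
    if peaks.size == 0:
        raise BeatDetectionError("no beats detected")

    # refine each detection to the local maximum of the raw composite
    radius = int(round(cfg.refine_radius_ms * fs / 1000.0))
    refined = []
    for p in peaks:
        a, b = max(0, p - radius), min(comp.size, p + radius + 1)
        refined.append(a + int(np.argmax(comp[a:b])))
    refined = np.unique(np.asarray(refined, dtype=int))
    # enforce the refractory after refinement (keep the larger composite peak)
    keep: list[int] = []
    for p in refined:
        if keep and p - keep[-1] < distance:
            if comp[p] > comp[keep[-1]]:
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    return np.asarray(keep, dtype=int)


@dataclass(frozen=True)
class BeatAnnotations:
    """Per-beat labels plus the sinus RR series.

    ``labels[i]`` is one of ``sinus``, ``pvc``, ``artifact`` for
    ``r_peak_samples[i]``; ``rr_intervals_ms`` holds gaps between consecutive
    sinus peaks (junction-crossing outlier gaps removed); ``mean_rr_ms`` is
    their mean.
    """

    r_peak_samples: np.ndarray
    labels: tuple[str, ...]
    rr_intervals_ms: np.ndarray
    mean_rr_ms: float
    sampling_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.r_peak_samples, dtype=int)
        if np.any(np.diff(samples) <= 0):
            raise ValueError("r_peak_samples must be strictly increasing")
        object.__setattr__(self, "r_peak_samples", samples)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def sinus_samples(self) -> np.ndarray:
        mask = np.array([l == "sinus" for l in self.labels])
        return self.r_peak_samples[mask]

    @property
    def r_peak_times_ms(self) -> np.ndarray:
        return self.r_peak_samples * 1000.0 / self.sampling_rate


def _beat_matrix(comp: np.ndarray, peaks: np.ndarray, half: int) -> np.ndarray:
    return np.stack([comp[p - half: p + half + 1] for p in peaks])


def _best_lag_correlation(x: np.ndarray, template: np.ndarray, max_lag: int) -> float:
    """Max Pearson correlation of x against template over integer lags."""
    best = -1.0
    n = x.size
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = x[lag:], template[: n - lag]
        else:
            a, b = x[: n + lag], template[-lag:]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        best = max(best, r)
    return best


def classify_beats(
    record: EcgRecord,
    r_peaks: np.ndarray,
    cfg: DetectorConfig = DetectorConfig(),
    excluded_zones_ms: Sequence[tuple[float, float]] = (),
) -> BeatAnnotations:
    """Label each detected beat sinus / pvc / artifact.

    A beat is *artifact* when its full 1.2-s representative window does not
    fit in the record, or when that window intersects one of
    ``excluded_zones_ms`` (half-open ms intervals, e.g. concatenation
    junction zones).  Among the remaining beats, a beat is *pvc* when its
    best-lag correlation with the two-pass median beat template is below
    ``pvc_corr_threshold``, or when its RR to the previous beat is below
    ``premature_rr_fraction`` of the median RR *and* the correlation is below
    ``premature_corr_threshold``.  Everything else is sinus.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size < 3:
        raise BeatDetectionError(f"need >= 3 detected beats, got {r_peaks.size}")
    fs = record.sampling_rate
    comp = composite_channel(record)
    n = comp.size

    pre = int(round(R_OFFSET_MS * fs / 1000.0))
    post = int(round((WINDOW_MS - R_OFFSET_MS) * fs / 1000.0))

    labels = ["sinus"] * r_peaks.size
    times_ms = r_peaks * 1000.0 / fs
    for i, p in enumerate(r_peaks):
        if p - pre < 0 or p + post > n:
            labels[i] = "artifact"
            continue
        w_lo, w_hi = times_ms[i] - R_OFFSET_MS, times_ms[i] + (WINDOW_MS - R_OFFSET_MS)
        for z_lo, z_hi in excluded_zones_ms:
            if w_lo < z_hi and z_lo < w_hi:
                labels[i] = "artifact"
                break

    half = int(round(cfg.corr_window_ms * fs / 1000.0))
    usable = np.array([
        i for i, p in enumerate(r_peaks)
        if labels[i] != "artifact" and p - half >= 0 and p + half + 1 <= n
    ], dtype=int)
    if usable.size == 0:
        raise BeatDetectionError("no sinus beats: every beat is excluded")

    # two-pass deterministic template: median over all usable beats, then
    # correlate each beat against it (no recursive update)
    beats = _beat_matrix(comp, r_peaks[usable], half)
    template = np.median(beats, axis=0)
    max_lag = max(1, int(round(cfg.corr_lag_ms * fs / 1000.0)))

    rr_all = np.diff(times_ms)
    median_rr = float(np.median(rr_all)) if rr_all.size else np.inf

    for row, i in enumerate(usable):
        corr = _best_lag_correlation(beats[row], template, max_lag)
        premature = i > 0 and (times_ms[i] - times_ms[i - 1]) < cfg.premature_rr_fraction * median_rr
        if corr < cfg.pvc_corr_threshold or (premature and corr < cfg.premature_corr_threshold):
            labels[i] = "pvc"

    if not any(l == "sinus" for l in labels):
        raise BeatDetectionError("no sinus beats after classification")

    sinus_times = times_ms[[l == "sinus" for l in labels]]
    rr = np.diff(sinus_times)
    if rr.size:
        med = np.median(rr)
        rr = rr[rr <= cfg.rr_gap_multiple * med]
    mean_rr = float(np.mean(rr)) if rr.size else float("nan")

    return BeatAnnotations(
        r_peak_samples=r_peaks, labels=tuple(labels),
        rr_intervals_ms=rr, mean_rr_ms=mean_rr, sampling_rate=fs,
    )
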