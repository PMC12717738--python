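"""Per-lead 1.2-s median representative beat and superimposed vector magnitude.

All contributing sinus beats are aligned on the detected R-peak sample; for
each lead, each output sample is the median across beats of the sample at the
same offset from R.  The R peak sits at a fixed 400 ms inside the 1200-ms
window (400 ms pre-R, 800 ms post-R), so P and T both fit at normal sinus
intervals.  The same global set of contributing beats is used for all 12
leads, keeping the superimposed beat time-consistent across leads.

The vector magnitude is the per-sample root of the sum of the squared
per-lead representative beats — the surface on which global fiducials are
subsequently placed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import R_OFFSET_MS, WINDOW_MS, BeatAnnotations
from .ecg_io import LEADS, EcgRecord

__all__ = ["RepresentativeBeat", "build_representative", "vector_magnitude",
           "R_OFFSET_MS", "WINDOW_MS"]


@dataclass(frozen=True)
class RepresentativeBeat:
    """12-lead median beat: ``data`` has shape (12, window_samples), µV."""

    data: np.ndarray
    sampling_rate: float
    r_offset_ms: float
    n_beats: int
    mean_rr_ms: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] != len(LEADS):
            raise ValueError(f"expected (12, n) data, got {data.shape}")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        object.__setattr__(self, "data", data)

    @property
    def window_ms(self) -> float:
        return self.data.shape[1] * 1000.0 / self.sampling_rate

    def lead(self, name: str) -> np.ndarray:
        return self.data[LEADS.index(name)]

    def ms_to_sample(self, t_ms: float) -> int:
        return int(round(t_ms * self.sampling_rate / 1000.0))


def build_representative(record: EcgRecord, annotations: BeatAnnotations) -> RepresentativeBeat:
    """Median beat over all sinus beats whose full window fits the record.

    PVC and artifact beats never contribute.  With an even number of
    contributing beats the median is the mean of the two central values
    (numpy convention).  Raises ``ValueError`` when no usable sinus beat
    remains.
    """
    fs = record.sampling_rate
    pre = int(round(R_OFFSET_MS * fs / 1000.0))
    post = int(round((WINDOW_MS - R_OFFSET_MS) * fs / 1000.0))
    n = record.n_samples

    usable = [
        p for p, label in zip(annotations.r_peak_samples, annotations.labels)
        if label == "sinus" and p - pre >= 0 and p + post <= n
    ]
    if not usable:
        raise ValueError("no usable sinus beat: cannot build a representative beat")

    stack = np.stack([record.data[:, p - pre: p + post] for p in usable])
    rep = np.median(stack, axis=0)
    # per-lead baseline correction: the window median is a robust isoelectric
    # estimate (waves occupy well under half the 1.2-s window at sinus rates),
    # and removes residual DC left by baseline wander after beat averaging
    rep = rep - np.median(rep, axis=1, keepdims=True)
    return RepresentativeBeat(
        data=rep, sampling_rate=fs, r_offset_ms=R_OFFSET_MS,
        n_beats=len(usable), mean_rr_ms=annotations.mean_rr_ms,
    )


def vector_magnitude(rep: RepresentativeBeat) -> np.ndarray:
    """Per-sample root-sum-of-squares over the 12 leads (non-negative, µV)."""
    return np.sqrt(np.sum(rep.data**2, axis=0))
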