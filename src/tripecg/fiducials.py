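"""Threshold-based global fiducial placement on the vector magnitude.

A single set of marks (P onset, QRS onset/offset, T offset) is placed for
all 12 leads, consistent with the superimposed-median-beat concept.  The
method is a classical threshold scheme:

* a baseline level is the median of the (lightly smoothed) vector magnitude
  over a noise window in the TP/PR region ending 300 ms before the R peak;
* each mark is a crossing of the VM through a threshold placed a configured
  fraction of the local peak-above-baseline above the baseline;
* crossings must be *sustained* (the VM must stay on the far side of the
  threshold for a minimum duration) to avoid chatter from noise or from the
  near-cancellation pinch between adjacent QRS lobes.

Automatically placed marks are tagged ``auto``; :func:`apply_override`
implements the manual-editing contract (edited marks are tagged ``manual``,
ordering is enforced atomically).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .representative import RepresentativeBeat

__all__ = ["ThresholdConfig", "FiducialSet", "FiducialError",
           "detect_fiducials", "apply_override"]


class FiducialError(RuntimeError):
    """Raised for degenerate vector magnitudes or invalid overrides."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Constants of the threshold delineator (fractions are of the local
    peak-above-baseline; windows are ms relative to the R peak)."""

    qrs_fraction: float = 0.04
    p_fraction: float = 0.04
    t_fraction: float = 0.03
    noise_window_ms: float = 80.0  # baseline window, ending 300 ms before R
    smooth_ms: float = 8.0  # boxcar applied to the VM before thresholding
    # sustained-crossing requirements
    qrs_sustain_ms: float = 10.0
    t_sustain_ms: float = 20.0
    p_sustain_ms: float = 10.0
    # search windows relative to R (ms)
    qrs_onset_window: tuple[float, float] = (-120.0, 0.0)
    qrs_offset_window: tuple[float, float] = (0.0, 200.0)
    t_window: tuple[float, float] = (80.0, 550.0)  # upper bound scaled by sqrt(RR)
    p_window: tuple[float, float] = (-350.0, -40.0)
    # minimum peak-above-baseline for a wave to count as present (µV)
    p_min_amplitude_uv: float = 25.0
    t_min_amplitude_uv: float = 40.0

    def __post_init__(self) -> None:
        for name in ("qrs_fraction", "p_fraction", "t_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass(frozen=True)
class FiducialSet:
    """Global marks in ms within the 1.2-s representative window.

    ``p_onset_ms`` and ``t_offset_ms`` may be ``None`` (wave not found).
    ``source`` maps mark name -> 'auto' | 'manual'.
    """

    qrs_onset_ms: float
    qrs_offset_ms: float
    p_onset_ms: float | None = None
    t_offset_ms: float | None = None
    source: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.source is None:
            object.__setattr__(self, "source", {})
        _check_ordering(self.p_onset_ms, self.qrs_onset_ms,
                        self.qrs_offset_ms, self.t_offset_ms)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "p_onset": self.p_onset_ms,
            "qrs_onset": self.qrs_onset_ms,
            "qrs_offset": self.qrs_offset_ms,
            "t_offset": self.t_offset_ms,
        }


def _check_ordering(p_onset, qrs_onset, qrs_offset, t_offset) -> None:
    marks = [("p_onset", p_onset), ("qrs_onset", qrs_onset),
             ("qrs_offset", qrs_offset), ("t_offset", t_offset)]
    present = [(n, v) for n, v in marks if v is not None]
    for (n1, v1), (n2, v2) in zip(present, present[1:]):
        if not v1 < v2:
            raise FiducialError(f"fiducial ordering violated: {n1}={v1} !< {n2}={v2}")
    for n, v in present:
        if not 0 <= v < 1200.0:
            raise FiducialError(f"{n}={v} outside the [0, 1200) ms window")


def _smooth(x: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    w = max(1, int(round(smooth_ms * fs / 1000.0)))
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def _first_sustained_below(x: np.ndarray, start: int, stop: int,
                           tau: float, sustain: int) -> int | None:
    """Smallest i in [start, stop) such that x[i : i+sustain] stays < tau."""
    n = x.size
    below = x < tau
    # run_below[i] = number of consecutive below samples starting at i
    run = np.zeros(n + 1, dtype=int)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if below[i] else 0
    for i in range(start, min(stop, n)):
        if run[i] >= sustain:
            return i
    return None


def _last_sustained_below(x: np.ndarray, start: int, stop: int,
                          tau: float, sustain: int) -> int | None:
    """Largest i in [start, stop) such that x[max(i-sustain+1,0) : i+1] < tau.

    Used for backward scans (QRS onset, P onset): the returned index is the
    last sample of a sustained below-threshold stretch; the mark is placed
    at the following sample (the upward crossing).
    """
    below = x < tau
    run = np.zeros(x.size, dtype=int)
    for i in range(x.size):
        run[i] = run[i - 1] + 1 if (below[i] and i > 0) else (1 if below[i] else 0)
    for i in range(min(stop, x.size) - 1, max(start, 0) - 1, -1):
        if run[i] >= sustain:
            return i
    return None


def detect_fiducials(
    vm: np.ndarray,
    rep: RepresentativeBeat,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> FiducialSet:
    """Place P onset, QRS onset/offset and T offset on the vector magnitude.

    Raises :class:`FiducialError` for a degenerate VM (peak below 5x the
    baseline noise estimate).  A missing T peak yields ``t_offset_ms=None``
    with a warning (QT will be reported unavailable downstream); an absent P
    yields ``p_onset_ms=None`` silently (a reportable condition, not a fault).
    """
    vm = np.asarray(vm, dtype=float)
    fs = rep.sampling_rate
    r_idx = rep.ms_to_sample(rep.r_offset_ms)
    sm = _smooth(vm, fs, cfg.smooth_ms)

    def ms2i(t_ms: float) -> int:
        return int(round(t_ms * fs / 1000.0))

    # --- baseline from the TP/PR region ---
    b_hi = r_idx - ms2i(300.0)
    b_lo = b_hi - ms2i(cfg.noise_window_ms)
    b_lo, b_hi = max(b_lo, 0), max(b_hi, 1)
    baseline = float(np.median(sm[b_lo:b_hi]))

    peak = float(np.max(sm))
    if peak < 5.0 * max(baseline, 1e-6) or peak <= 0:
        raise FiducialError(
            f"degenerate vector magnitude: peak {peak:.1f} µV vs baseline "
            f"{baseline:.1f} µV"
        )

    # --- QRS marks ---
    r_lo, r_hi = r_idx - ms2i(30.0), r_idx + ms2i(30.0) + 1
    vm_r_peak = float(np.max(sm[max(r_lo, 0):r_hi]))
    tau_qrs = baseline + cfg.qrs_fraction * (vm_r_peak - baseline)
    sustain_qrs = max(1, ms2i(cfg.qrs_sustain_ms))

    on_lo = r_idx + ms2i(cfg.qrs_onset_window[0])
    i_on = _last_sustained_below(sm, on_lo, r_idx, tau_qrs, sustain_qrs)
    if i_on is None:
        raise FiducialError("QRS onset not found (no sustained sub-threshold "
                            "stretch in the search window)")
    qrs_onset = (i_on + 1) * 1000.0 / fs

    off_hi = r_idx + ms2i(cfg.qrs_offset_window[1])
    i_off = _first_sustained_below(sm, r_idx, off_hi, tau_qrs, sustain_qrs)
    if i_off is None:
        raise FiducialError("QRS offset not found in the search window")
    qrs_offset = i_off * 1000.0 / fs

    # --- T offset ---
    t_offset: float | None = None
    rr = rep.mean_rr_ms if np.isfinite(rep.mean_rr_ms) else 1000.0
    t_hi_ms = cfg.t_window[1] * np.sqrt(rr / 1000.0)  # Bazett-like scaling
    t_lo = max(i_off + ms2i(20.0), r_idx + ms2i(cfg.t_window[0]))
    t_hi = min(r_idx + ms2i(t_hi_ms), sm.size - 1)
    if t_hi > t_lo:
        i_tpk = t_lo + int(np.argmax(sm[t_lo:t_hi]))
        t_peak_amp = sm[i_tpk] - baseline
        if t_peak_amp >= cfg.t_min_amplitude_uv:
            tau_t = baseline + cfg.t_fraction * t_peak_amp
            i_toff = _first_sustained_below(
                sm, i_tpk, sm.size, tau_t, max(1, ms2i(cfg.t_sustain_ms)))
            if i_toff is not None:
                t_offset = i_toff * 1000.0 / fs
            else:
                warnings.warn("T offset not found after the T peak; QT unavailable")
        else:
            warnings.warn("no T peak found in the search window; QT unavailable")
    else:
        warnings.warn("T search window is empty; QT unavailable")

    # --- P onset ---
    p_onset: float | None = None
    p_lo = max(r_idx + ms2i(cfg.p_window[0]), 0)
    p_hi = min(r_idx + ms2i(cfg.p_window[1]), i_on)
    if p_hi > p_lo:
        i_ppk = p_lo + int(np.argmax(sm[p_lo:p_hi]))
        p_peak_amp = sm[i_ppk] - baseline
        if p_peak_amp >= cfg.p_min_amplitude_uv:
            tau_p = baseline + cfg.p_fraction * p_peak_amp
            i_pon = _last_sustained_below(
                sm, 0, i_ppk, tau_p, max(1, ms2i(cfg.p_sustain_ms)))
            if i_pon is not None and (i_pon + 1) * 1000.0 / fs < qrs_onset:
                p_onset = (i_pon + 1) * 1000.0 / fs

    fids = FiducialSet(
        qrs_onset_ms=qrs_onset, qrs_offset_ms=qrs_offset,
        p_onset_ms=p_onset, t_offset_ms=t_offset,
        source={k: "auto" for k, v in {
            "p_onset": p_onset, "qrs_onset": qrs_onset,
            "qrs_offset": qrs_offset, "t_offset": t_offset,
        }.items() if v is not None},
    )
    return fids


def apply_override(fids: FiducialSet, edits: dict[str, float]) -> FiducialSet:
    """Replace marks with manual values; all-or-nothing ordering enforcement.

    ``edits`` maps mark names (``p_onset``, ``qrs_onset``, ``qrs_offset``,
    ``t_offset``) to new values in ms.  On an ordering violation the original
    set is left untouched and :class:`FiducialError` is raised.
    """
    valid = {"p_onset", "qrs_onset", "qrs_offset", "t_offset"}
    unknown = set(edits) - valid
    if unknown:
        raise FiducialError(f"unknown fiducial mark(s): {sorted(unknown)}")
    if not edits:
        return fids

    new = dict(fids.as_dict())
    new.update(edits)
    _check_ordering(new["p_onset"], new["qrs_onset"],
                    new["qrs_offset"], new["t_offset"])
    source = dict(fids.source)
    for k in edits:
        source[k] = "manual"
    return FiducialSet(
        qrs_onset_ms=new["qrs_onset"], qrs_offset_ms=new["qrs_offset"],
        p_onset_ms=new["p_onset"], t_offset_ms=new["t_offset"], source=source,
    )
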