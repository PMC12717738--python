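"""Synthetic 12-lead sinus-rhythm ECGs with exactly known ground truth.

Beats are sums of Gaussian lobes (one lobe per wave: P, Q, R, S, T; the T
lobe is asymmetric, with a slower upstroke than downstroke, as in real
repolarization).  This trades physiological realism for an analytic truth
channel: every interval (PR, QRS, QT), every R-peak time and every wave
amplitude is known exactly by construction, which is what the downstream
delineation and agreement stages are tested against.

Ground-truth convention
-----------------------
The onset/offset of a Gaussian lobe is defined at the point where the lobe
reaches ``SUPPORT_FRACTION`` (~3.49%) of its peak amplitude, i.e. at
``SUPPORT_SIGMA = 2.590`` standard deviations from the lobe center.  This
keeps >= 99% of each lobe's mass inside its labelled segment while remaining
recoverable by a threshold detector in the presence of a rectified noise
floor on the vector magnitude.  Lobe centers are then solved so that the
requested PR, QRS and QT are exact:

* QRS onset sits at ``-0.42 * qrs`` relative to the R peak (offset at
  ``+0.58 * qrs``); the Q and S lobes are pinned so their outer support
  edges land exactly on the requested onset/offset.
* P onset = QRS onset - PR; T offset = QRS onset + QT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .ecg_io import LEADS, AcquisitionMeta, EcgRecord, TripletSet

__all__ = [
    "SUPPORT_SIGMA",
    "SUPPORT_FRACTION",
    "Wave",
    "BeatTemplate",
    "NoiseSpec",
    "GroundTruth",
    "DEFAULT_AMPLITUDES",
    "make_template",
    "random_template",
    "synth_record",
    "inject_pvc",
    "synth_triplicate",
]

#: A lobe's labelled support ends where it reaches exp(-SUPPORT_SIGMA^2 / 2)
#: of its peak; 2.590 sigma keeps 99.04% of the lobe's mass inside.
SUPPORT_SIGMA = 2.590
SUPPORT_FRACTION = math.exp(-SUPPORT_SIGMA**2 / 2.0)

#: Default per-lead wave amplitudes (µV), in canonical lead order
#: I, II, III, aVR, aVL, aVF, V1..V6.  Signs follow textbook morphology:
#: negative main deflection in aVR, deep S in V1-V2, tall R in V4-V6.
DEFAULT_AMPLITUDES: dict[str, tuple[float, ...]] = {
    "P": (60, 120, 60, -80, 40, 90, 50, 60, 70, 80, 80, 70),
    "R": (600, 900, 400, -500, 300, 600, 200, 400, 700, 1200, 1400, 1100),
    "S": (-100, -120, -80, 80, -60, -90, -800, -700, -450, -250, -150, -100),
    "T": (250, 350, 150, -250, 120, 250, 100, 300, 400, 450, 400, 300),
}
# Q defaults derive from R (small, opposite sign) and are filled in
# make_template when not supplied explicitly.
_Q_TO_R_RATIO = -0.18

_DEF_SIGMA_Q = 2.5
_DEF_SIGMA_S = 3.0
_DEF_SIGMA_P = 8.0
_DEF_SIGMA_T_RIGHT = 15.0
_T_ASYMMETRY = 2.0  # sigma_left / sigma_right of the T lobe


class SynthError(ValueError):
    """Raised for infeasible template or injection requests."""


@dataclass(frozen=True)
class Wave:
    """One Gaussian lobe shared in time across leads, with per-lead amplitude."""

    name: str
    center_ms: float  # relative to the R peak
    sigma_left_ms: float
    sigma_right_ms: float
    amplitudes_uv: np.ndarray  # shape (12,)

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes_uv, dtype=float)
        if amps.shape != (len(LEADS),):
            raise SynthError(f"wave {self.name}: need 12 amplitudes, got {amps.shape}")
        object.__setattr__(self, "amplitudes_uv", amps)

    def shape(self, t_ms: np.ndarray) -> np.ndarray:
        """Unit-amplitude lobe evaluated at times relative to the R peak."""
        t = np.asarray(t_ms, dtype=float) - self.center_ms
        sig = np.where(t < 0, self.sigma_left_ms, self.sigma_right_ms)
        return np.exp(-0.5 * (t / sig) ** 2)

    def eval(self, t_ms: np.ndarray) -> np.ndarray:
        """(12, len(t)) waveform of this lobe."""
        return np.outer(self.amplitudes_uv, self.shape(t_ms))


@dataclass(frozen=True)
class BeatTemplate:
    """A single-beat template plus its exact fiducials (ms relative to R)."""

    waves: tuple[Wave, ...]
    pr_ms: float
    qrs_ms: float
    qt_ms: float
    p_onset_ms: float
    qrs_onset_ms: float
    qrs_offset_ms: float
    t_offset_ms: float
    r_amp_true_uv: np.ndarray  # per-lead, baseline-referenced
    s_amp_true_uv: np.ndarray

    @property
    def soko_v5_true_uv(self) -> float:
        return float(self.s_amp_true_uv[LEADS.index("V1")]
                     + self.r_amp_true_uv[LEADS.index("V5")])

    @property
    def soko_v6_true_uv(self) -> float:
        return float(self.s_amp_true_uv[LEADS.index("V1")]
                     + self.r_amp_true_uv[LEADS.index("V6")])

    @property
    def support_ms(self) -> tuple[float, float]:
        """Rendering window (ms relative to R) covering all lobes."""
        lo = min(w.center_ms - (SUPPORT_SIGMA + 1.5) * w.sigma_left_ms for w in self.waves)
        hi = max(w.center_ms + (SUPPORT_SIGMA + 1.5) * w.sigma_right_ms for w in self.waves)
        return lo, hi

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        """(12, len(t)) template evaluated at times relative to the R peak."""
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros((len(LEADS), t.size))
        for w in self.waves:
            out += w.eval(t)
        return out


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: baseline wander + mains interference + broadband."""

    baseline_wander_uv: float = 0.0
    baseline_wander_hz: float = 0.3
    mains_uv: float = 0.0
    mains_hz: float = 50.0
    broadband_sd_uv: float = 0.0
    seed: int | None = None  # optional dedicated stream; record stream if None

    def __post_init__(self) -> None:
        for name in ("baseline_wander_uv", "mains_uv", "broadband_sd_uv"):
            if getattr(self, name) < 0:
                raise SynthError(f"{name} must be >= 0")

    @property
    def is_silent(self) -> bool:
        return (self.baseline_wander_uv == 0 and self.mains_uv == 0
                and self.broadband_sd_uv == 0)


NO_NOISE = NoiseSpec()


@dataclass(frozen=True)
class GroundTruth:
    """The truth channel carried next to every synthetic record."""

    r_peak_times_ms: np.ndarray
    beat_labels: tuple[str, ...]  # 'sinus' | 'pvc'
    pr_ms: float
    qrs_ms: float
    qt_ms: float
    mean_rr_ms: float  # realized mean RR over consecutive sinus beats
    soko_v5_uv: float
    soko_v6_uv: float
    template: BeatTemplate

    def __post_init__(self) -> None:
        times = np.asarray(self.r_peak_times_ms, dtype=float)
        object.__setattr__(self, "r_peak_times_ms", times)
        object.__setattr__(self, "beat_labels", tuple(self.beat_labels))
        if times.size != len(self.beat_labels):
            raise SynthError("r_peak_times and beat_labels disagree in length")

    @property
    def sinus_times_ms(self) -> np.ndarray:
        mask = np.array([l == "sinus" for l in self.beat_labels])
        return self.r_peak_times_ms[mask]

    @property
    def qtcf_ms(self) -> float:
        return self.qt_ms / (self.mean_rr_ms / 1000.0) ** (1.0 / 3.0)

    @property
    def qtcb_ms(self) -> float:
        return self.qt_ms / (self.mean_rr_ms / 1000.0) ** 0.5


def _as_amp_array(values: Sequence[float] | np.ndarray, wave: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (len(LEADS),):
        raise SynthError(f"amplitudes for wave {wave} must have length 12")
    return arr


def make_template(
    pr: float,
    qrs: float,
    qt: float,
    lead_amplitudes: Mapping[str, Sequence[float]] | None = None,
) -> BeatTemplate:
    """Build a beat template whose exact fiducials realize the requested intervals.

    Parameters
    ----------
    pr, qrs, qt:
        Requested intervals in ms; ``80 <= pr <= 400``, ``50 <= qrs <= 250``,
        ``qt > qrs``.
    lead_amplitudes:
        Optional per-wave 12-vectors of amplitudes (µV) with keys among
        ``P, Q, R, S, T``; unspecified waves use :data:`DEFAULT_AMPLITUDES`
        (Q defaults to ``-0.18 * R``).
    """
    if not 80 <= pr <= 400:
        raise SynthError(f"pr={pr} outside [80, 400] ms")
    if not 50 <= qrs <= 250:
        raise SynthError(f"qrs={qrs} outside [50, 250] ms")
    if not qt > qrs:
        raise SynthError(f"qt={qt} must exceed qrs={qrs}")

    amps = dict(DEFAULT_AMPLITUDES)
    if lead_amplitudes:
        for k, v in lead_amplitudes.items():
            if k not in ("P", "Q", "R", "S", "T"):
                raise SynthError(f"unknown wave key {k!r}")
            amps[k] = tuple(_as_amp_array(v, k))
    r_amps = _as_amp_array(amps["R"], "R")
    if "Q" in amps:
        q_amps = _as_amp_array(amps["Q"], "Q")
    else:
        q_amps = _Q_TO_R_RATIO * r_amps
    s_amps = _as_amp_array(amps["S"], "S")
    p_amps = _as_amp_array(amps["P"], "P")
    t_amps = _as_amp_array(amps["T"], "T")

    qrs_onset = -0.42 * qrs
    qrs_offset = 0.58 * qrs
    p_onset = qrs_onset - pr
    t_offset = qrs_onset + qt

    have_q = bool(np.any(q_amps != 0))
    have_s = bool(np.any(s_amps != 0))

    # R lobe: steep enough that its tails at the QRS edges stay below ~1% of
    # its peak (keeps the onset/offset governed by Q/S and the baseline at
    # QRS onset near zero for amplitude measurement).
    sigma_r_left = 0.42 * qrs / (SUPPORT_SIGMA if not have_q else 3.14)
    sigma_r_right = 0.58 * qrs / (SUPPORT_SIGMA if not have_s else 3.14)
    sigma_r_right = min(sigma_r_right, 1.4 * sigma_r_left)

    waves = [Wave("R", 0.0, sigma_r_left, sigma_r_right, r_amps)]
    if have_q:
        waves.append(Wave(
            "Q", qrs_onset + SUPPORT_SIGMA * _DEF_SIGMA_Q,
            _DEF_SIGMA_Q, _DEF_SIGMA_Q, q_amps,
        ))
    if have_s:
        waves.append(Wave(
            "S", qrs_offset - SUPPORT_SIGMA * _DEF_SIGMA_S,
            _DEF_SIGMA_S, _DEF_SIGMA_S, s_amps,
        ))
    if np.any(p_amps != 0):
        waves.append(Wave(
            "P", p_onset + SUPPORT_SIGMA * _DEF_SIGMA_P,
            _DEF_SIGMA_P, _DEF_SIGMA_P, p_amps,
        ))
    if np.any(t_amps != 0):
        # Shrink the T downstroke if a short QT would otherwise push the
        # T-peak into the QRS; refuse below a 6-ms downstroke.
        sigma_t_r = _DEF_SIGMA_T_RIGHT
        max_sigma = (t_offset - qrs_offset - 12.0) / SUPPORT_SIGMA
        sigma_t_r = min(sigma_t_r, max_sigma)
        if sigma_t_r < 6.0:
            raise SynthError(
                f"qt={qt} too short for template geometry at qrs={qrs} "
                "(T lobe cannot fit after the QRS)"
            )
        waves.append(Wave(
            "T", t_offset - SUPPORT_SIGMA * sigma_t_r,
            _T_ASYMMETRY * sigma_t_r, sigma_t_r, t_amps,
        ))

    # Exact per-lead R/S amplitudes: evaluate the full template on a fine
    # grid over the QRS support (truth is baseline-referenced at 0).
    grid = np.arange(qrs_onset, qrs_offset, 0.1)
    qrs_wave = np.zeros((len(LEADS), grid.size))
    for w in waves:
        if w.name in ("Q", "R", "S"):
            qrs_wave += w.eval(grid)
    r_true = np.maximum(qrs_wave.max(axis=1), 0.0)
    s_true = np.maximum(-qrs_wave.min(axis=1), 0.0)

    return BeatTemplate(
        waves=tuple(waves),
        pr_ms=float(pr), qrs_ms=float(qrs), qt_ms=float(qt),
        p_onset_ms=p_onset, qrs_onset_ms=qrs_onset,
        qrs_offset_ms=qrs_offset, t_offset_ms=t_offset,
        r_amp_true_uv=r_true, s_amp_true_uv=s_true,
    )


def random_template(rng: np.random.Generator) -> BeatTemplate:
    """Draw a physiologically plausible random template (for test batteries).

    Intervals: PR ~ U[120, 220], QRS ~ U[70, 115], QT ~ U[340, 430] ms.
    Per-wave amplitudes are the defaults scaled by independent U[0.7, 1.3]
    factors per lead.
    """
    pr = rng.uniform(120, 220)
    qrs = rng.uniform(70, 115)
    qt = rng.uniform(340, 430)
    amps = {}
    for wave in ("P", "R", "S", "T"):
        base = np.asarray(DEFAULT_AMPLITUDES[wave], dtype=float)
        amps[wave] = base * rng.uniform(0.7, 1.3, size=len(LEADS))
    return make_template(pr, qrs, qt, lead_amplitudes=amps)


def _render_beats(
    data: np.ndarray,
    template: BeatTemplate,
    r_samples: np.ndarray,
    fs: float,
) -> None:
    lo_ms, hi_ms = template.support_ms
    lo = int(math.floor(lo_ms * fs / 1000.0))
    hi = int(math.ceil(hi_ms * fs / 1000.0))
    rel = np.arange(lo, hi + 1)
    beat = template.waveform(rel * 1000.0 / fs)
    n = data.shape[1]
    for r in r_samples:
        a, b = r + lo, r + hi + 1
        sa, sb = max(a, 0), min(b, n)
        if sa >= sb:
            continue
        data[:, sa:sb] += beat[:, sa - a: sa - a + (sb - sa)]


def _apply_noise(
    data: np.ndarray, noise: NoiseSpec, fs: float, rng: np.random.Generator
) -> None:
    if noise.is_silent:
        return
    if noise.seed is not None:
        rng = np.random.default_rng(noise.seed)
    n = data.shape[1]
    t = np.arange(n) / fs
    if noise.baseline_wander_uv > 0:
        phases = rng.uniform(0, 2 * np.pi, size=len(LEADS))
        data += noise.baseline_wander_uv * np.sin(
            2 * np.pi * noise.baseline_wander_hz * t[None, :] + phases[:, None]
        )
    if noise.mains_uv > 0:
        phases = rng.uniform(0, 2 * np.pi, size=len(LEADS))
        data += noise.mains_uv * np.sin(
            2 * np.pi * noise.mains_hz * t[None, :] + phases[:, None]
        )
    if noise.broadband_sd_uv > 0:
        data += rng.normal(0.0, noise.broadband_sd_uv, size=data.shape)


#: First R peak of every synthetic record (ms); leaves room for the 400-ms
#: pre-R half of the representative-beat window from the second beat on.
FIRST_R_MS = 500.0


def synth_record(
    template: BeatTemplate,
    duration_s: float = 10.0,
    mean_rr: float = 1000.0,
    rr_jitter_sd: float = 0.0,
    noise: NoiseSpec = NO_NOISE,
    seed: int = 0,
    fs: float = 1000.0,
    record_id: str = "synthetic",
) -> tuple[EcgRecord, GroundTruth]:
    """Render a sinus beat train with per-beat RR ~ Normal(mean_rr, jitter).

    RR draws are truncated at ±3 SD.  Identical arguments and seed yield
    bit-identical output (single explicit random stream per call; RR draws
    are consumed before noise draws).
    """
    if duration_s <= 0:
        raise SynthError("duration must be > 0")
    if not 300 <= mean_rr <= 2000:
        raise SynthError(f"mean_rr={mean_rr} outside [300, 2000] ms")
    rng = np.random.default_rng(seed)
    duration_ms = duration_s * 1000.0

    r_times = [FIRST_R_MS]
    while True:
        if rr_jitter_sd > 0:
            rr = float(np.clip(rng.normal(mean_rr, rr_jitter_sd),
                               mean_rr - 3 * rr_jitter_sd,
                               mean_rr + 3 * rr_jitter_sd))
        else:
            rr = mean_rr
        nxt = r_times[-1] + rr
        if nxt >= duration_ms:
            break
        r_times.append(nxt)

    n = int(round(duration_s * fs))
    r_samples = np.array([int(round(t * fs / 1000.0)) for t in r_times])
    r_times_q = r_samples * 1000.0 / fs

    data = np.zeros((len(LEADS), n))
    _render_beats(data, template, r_samples, fs)
    _apply_noise(data, noise, fs, rng)

    mean_rr_true = float(np.mean(np.diff(r_times_q))) if len(r_times_q) > 1 else mean_rr
    truth = GroundTruth(
        r_peak_times_ms=r_times_q,
        beat_labels=("sinus",) * len(r_times_q),
        pr_ms=template.pr_ms, qrs_ms=template.qrs_ms, qt_ms=template.qt_ms,
        mean_rr_ms=mean_rr_true,
        soko_v5_uv=template.soko_v5_true_uv,
        soko_v6_uv=template.soko_v6_true_uv,
        template=template,
    )
    record = EcgRecord(
        data=data,
        meta=AcquisitionMeta(sampling_rate=fs, lowpass_cutoff=150.0,
                             device_label="tripecg-synth"),
        record_id=record_id,
    )
    return record, truth


def inject_pvc(
    record: EcgRecord,
    truth: GroundTruth,
    times_ms: Sequence[float] | None = None,
    prematurity: float = 0.55,
    widened_qrs: float = 160.0,
) -> tuple[EcgRecord, GroundTruth]:
    """Insert interpolated wide-QRS ectopic beats; sinus truth is unchanged.

    The PVC is a single broad lobe (support = ``widened_qrs``) with an
    inverted, amplified amplitude pattern and no P or T wave — morphologically
    distinct from the sinus template in every lead and in the composite
    root-sum-of-squares channel.  Sinus beats keep their schedule, so the
    PVC is interpolated and sinus-to-sinus RR intervals are unaffected.

    ``times_ms`` gives explicit PVC R-peak times; when omitted, a single PVC
    is placed at ``prematurity`` of the RR interval after the middle beat.
    """
    if not 0 < prematurity < 1:
        raise SynthError(f"prematurity must be in (0, 1), got {prematurity}")
    template = truth.template
    fs = record.sampling_rate
    sinus = truth.sinus_times_ms
    if times_ms is None:
        if sinus.size < 3:
            raise SynthError("need >= 3 sinus beats to auto-place a PVC")
        k = sinus.size // 2
        times_ms = [float(sinus[k] + prematurity * (sinus[k + 1] - sinus[k]))]

    min_gap = 0.5 * (widened_qrs + template.qrs_ms) + 40.0
    all_times = truth.r_peak_times_ms
    for t in times_ms:
        if not 0 <= t < record.duration_ms:
            raise SynthError(f"PVC time {t} ms outside the record")
        if np.min(np.abs(all_times - t)) < min_gap:
            raise SynthError(
                f"PVC at {t} ms overlaps an existing beat window "
                f"(min separation {min_gap:.0f} ms)"
            )

    sigma = widened_qrs / (2.0 * SUPPORT_SIGMA)
    # inverted, amplified copy of this template's own R pattern
    r_wave = next(w for w in template.waves if w.name == "R")
    pvc_amps = -1.2 * r_wave.amplitudes_uv
    pvc_wave = Wave("PVC", 0.0, sigma, sigma, pvc_amps)

    data = record.data.copy()
    lo = int(math.floor(-(SUPPORT_SIGMA + 1.5) * sigma * fs / 1000.0))
    hi = -lo
    rel = np.arange(lo, hi + 1)
    lobe = pvc_wave.eval(rel * 1000.0 / fs)
    n = data.shape[1]
    new_times = []
    for t in times_ms:
        r = int(round(t * fs / 1000.0))
        a, b = r + lo, r + hi + 1
        sa, sb = max(a, 0), min(b, n)
        data[:, sa:sb] += lobe[:, sa - a: sa - a + (sb - sa)]
        new_times.append(r * 1000.0 / fs)

    merged = np.concatenate([truth.r_peak_times_ms, np.asarray(new_times)])
    labels = list(truth.beat_labels) + ["pvc"] * len(new_times)
    order = np.argsort(merged)
    new_truth = replace(
        truth,
        r_peak_times_ms=merged[order],
        beat_labels=tuple(labels[i] for i in order),
    )
    new_record = replace(record, data=data)
    return new_record, new_truth


def synth_triplicate(
    template: BeatTemplate,
    mean_rr: float = 1000.0,
    rr_jitter_sd: float = 0.0,
    noise: NoiseSpec = NO_NOISE,
    seed: int = 0,
    duration_s: float = 10.0,
    fs: float = 1000.0,
    subject_id: str = "synthetic",
    visit_label: str = "V1",
) -> tuple[TripletSet, list[GroundTruth]]:
    """Three 10-s records sharing the template and mean RR, with independent
    RR-jitter and noise realizations (child seeds spawned from ``seed``)."""
    children = np.random.SeedSequence(seed).spawn(3)
    records, truths = [], []
    for k, child in enumerate(children):
        member_seed = int(child.generate_state(1)[0] % (2**31))
        rec, tr = synth_record(
            template, duration_s=duration_s, mean_rr=mean_rr,
            rr_jitter_sd=rr_jitter_sd, noise=noise, seed=member_seed, fs=fs,
            record_id=f"{subject_id}-{visit_label}-{k + 1}",
        )
        records.append(rec)
        truths.append(tr)
    triplet = TripletSet(records=tuple(records), subject_id=subject_id,
                         visit_label=visit_label)
    return triplet, truths
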