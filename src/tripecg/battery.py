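"""Named battery of synthetic fixtures used by tests, examples and the CLI.

Every entry is generated deterministically from an explicit seed; truth
sidecars carry the generator's exact intervals and voltages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ecg_io import EcgRecord, TripletSet, write_record
from .synth import (
    DEFAULT_AMPLITUDES,
    GroundTruth,
    NoiseSpec,
    inject_pvc,
    make_template,
    synth_record,
    synth_triplicate,
)

__all__ = ["BatteryEntry", "make_battery", "write_battery",
           "STANDARD_NOISE", "LOW_VOLTAGE_AMPLITUDES"]

#: Noise of the "noisy" battery members: modest wander and mains plus the
#: broadband level the recovery envelope is specified at.
STANDARD_NOISE = NoiseSpec(baseline_wander_uv=40.0, baseline_wander_hz=0.3,
                           mains_uv=10.0, mains_hz=50.0, broadband_sd_uv=20.0)

#: Amplitudes scaled so every frontal lead stays <= 500 µV and every
#: precordial lead <= 1000 µV peak-to-peak within the QRS.
LOW_VOLTAGE_AMPLITUDES = {
    "P": tuple(0.5 * a for a in DEFAULT_AMPLITUDES["P"]),
    "R": (150, 220, 110, -130, 80, 150, 60, 120, 200, 320, 380, 300),
    "S": (-40, -50, -30, 30, -25, -35, -220, -190, -130, -80, -50, -40),
    "T": tuple(0.4 * a for a in DEFAULT_AMPLITUDES["T"]),
}


@dataclass(frozen=True)
class BatteryEntry:
    name: str
    record: EcgRecord | None
    triplet: TripletSet | None
    truth: GroundTruth | list[GroundTruth]


def make_battery(seed: int = 0) -> list[BatteryEntry]:
    """The standard fixture battery: clean, noisy, PVC-laden, low-voltage,
    wide-QRS (myocarditis-like) single records plus clean and noisy
    triplicate sets."""
    base = make_template(pr=160, qrs=90, qt=380)
    wide = make_template(pr=170, qrs=140, qt=400)
    lowv = make_template(pr=150, qrs=85, qt=360,
                         lead_amplitudes=LOW_VOLTAGE_AMPLITUDES)

    entries: list[BatteryEntry] = []

    rec, tr = synth_record(base, mean_rr=1000, seed=seed, record_id="clean")
    entries.append(BatteryEntry("clean", rec, None, tr))

    rec, tr = synth_record(base, mean_rr=900, rr_jitter_sd=25,
                           noise=STANDARD_NOISE, seed=seed + 1,
                           record_id="noisy")
    entries.append(BatteryEntry("noisy", rec, None, tr))

    rec, tr = synth_record(base, mean_rr=1000, seed=seed + 2, record_id="pvc")
    rec, tr = inject_pvc(rec, tr, prematurity=0.55, widened_qrs=160)
    entries.append(BatteryEntry("pvc", rec, None, tr))

    rec, tr = synth_record(lowv, mean_rr=950, seed=seed + 3,
                           record_id="low_voltage")
    entries.append(BatteryEntry("low_voltage", rec, None, tr))

    rec, tr = synth_record(wide, mean_rr=1050, seed=seed + 4,
                           record_id="wide_qrs")
    entries.append(BatteryEntry("wide_qrs", rec, None, tr))

    trip, truths = synth_triplicate(base, mean_rr=1000, seed=seed + 5,
                                    subject_id="S01", visit_label="clean")
    entries.append(BatteryEntry("triplet_clean", None, trip, truths))

    trip, truths = synth_triplicate(base, mean_rr=900, rr_jitter_sd=25,
                                    noise=STANDARD_NOISE, seed=seed + 6,
                                    subject_id="S01", visit_label="noisy")
    entries.append(BatteryEntry("triplet_noisy", None, trip, truths))
    return entries


def _truth_payload(truth: GroundTruth) -> dict:
    return {
        "r_peak_times_ms": list(np.round(truth.r_peak_times_ms, 3)),
        "beat_labels": list(truth.beat_labels),
        "pr_ms": truth.pr_ms, "qrs_ms": truth.qrs_ms, "qt_ms": truth.qt_ms,
        "mean_rr_ms": truth.mean_rr_ms,
        "soko_v5_uv": truth.soko_v5_uv, "soko_v6_uv": truth.soko_v6_uv,
    }


def write_battery(out_dir: str | Path, seed: int = 0, force: bool = False) -> Path:
    """Write the battery (records as CSV + metadata, truth as JSON sidecars)
    and a triplicate manifest for the triplet entries."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out_dir} is not empty (use force to overwrite)")
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest_rows = []
    for entry in make_battery(seed):
        if entry.record is not None:
            path = out_dir / f"{entry.name}.csv"
            write_record(entry.record, path)
            truth_path = out_dir / f"{entry.name}.truth.json"
            truth_path.write_text(
                json.dumps(_truth_payload(entry.truth), indent=2) + "\n")
        else:
            paths = []
            for k, rec in enumerate(entry.triplet.records):
                path = out_dir / f"{entry.name}_{k + 1}.csv"
                write_record(rec, path)
                paths.append(path.name)
                truth_path = out_dir / f"{entry.name}_{k + 1}.truth.json"
                truth_path.write_text(
                    json.dumps(_truth_payload(entry.truth[k]), indent=2) + "\n")
            manifest_rows.append(
                (entry.triplet.subject_id, entry.triplet.visit_label, *paths))

    manifest = out_dir / "triplicates.csv"
    lines = ["subject_id,visit_label,path_1,path_2,path_3"]
    lines += [",".join(row) for row in manifest_rows]
    manifest.write_text("\n".join(lines) + "\n")
    return out_dir
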