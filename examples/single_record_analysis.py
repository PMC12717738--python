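"""Analyze one synthetic 12-lead ECG and compare against generator truth.

Builds a 10-s sinus record with known PR/QRS/QT, runs the full pipeline
(R-peak detection -> beat classification -> median representative beat ->
vector magnitude -> threshold fiducials -> measurements) and prints the
measured parameters next to the exact ground truth.
"""

from tripecg import analyze_record
from tripecg.synth import NoiseSpec, make_template, synth_record

template = make_template(pr=160, qrs=90, qt=380)
record, truth = synth_record(
    template, mean_rr=900, rr_jitter_sd=20,
    noise=NoiseSpec(broadband_sd_uv=20.0), seed=7,
)

result = analyze_record(record)
m = result.measurements

print(f"contributing sinus beats : {m.n_beats}")
print(f"heart rate               : {m.hr_bpm:6.1f} bpm   (truth {60000 / truth.mean_rr_ms:6.1f})")
print(f"PR interval              : {m.pr_ms:6.1f} ms    (truth {truth.pr_ms:6.1f})")
print(f"QRS duration             : {m.qrs_ms:6.1f} ms    (truth {truth.qrs_ms:6.1f})")
print(f"QT interval              : {m.qt_ms:6.1f} ms    (truth {truth.qt_ms:6.1f})")
print(f"QTcF                     : {m.qtcf_ms:6.1f} ms    (truth {truth.qtcf_ms:6.1f})")
print(f"Sokolow-Lyon V5          : {m.soko_v5_uv:6.0f} µV    (truth {truth.soko_v5_uv:6.0f})")
print(f"low QRS voltage          : {'YES' if m.low_voltage else 'NO'}")
print()
print("Measured values come from threshold crossings on the vector magnitude")
print("of the median beat.  Their run-to-run scatter is well under 1 ms at")
print("this noise level (the median over ~10 beats suppresses the 20 µV")
print("broadband noise), while each mark carries a small (< 5 ms) systematic")
print("offset against the generator's amplitude-support truth convention —")
print("an offset that is stable across records and therefore cancels in the")
print("method and reader comparisons the tool is built for.")
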