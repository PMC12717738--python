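"""Compare the two triplicate strategies on the same noisy session.

TAM analyzes the three 10-s records independently and averages the results;
TCM concatenates them into one 30-s record (discarding beats near the two
junctions) and analyzes it once.  On synthetic data the two should agree to
within a couple of ms for every time-derived parameter.
"""

from tripecg.synth import NoiseSpec, make_template, synth_triplicate
from tripecg.triplicate import analyze_tam, analyze_tcm

template = make_template(pr=160, qrs=90, qt=380)
noise = NoiseSpec(baseline_wander_uv=40, mains_uv=10, broadband_sd_uv=20)
triplet, truths = synth_triplicate(template, mean_rr=900, rr_jitter_sd=25,
                                   noise=noise, seed=42,
                                   subject_id="S01", visit_label="D0")

tam, members = analyze_tam(triplet)
tcm = analyze_tcm(triplet).measurements

print(f"{'parameter':12s} {'TAM':>9s} {'TCM':>9s} {'diff':>7s}   truth")
for label, attr, truth_val in [
    ("HR (bpm)", "hr_bpm", 60000 / truths[0].mean_rr_ms),
    ("PR (ms)", "pr_ms", truths[0].pr_ms),
    ("QRS (ms)", "qrs_ms", truths[0].qrs_ms),
    ("QT (ms)", "qt_ms", truths[0].qt_ms),
    ("QTcF (ms)", "qtcf_ms", truths[0].qtcf_ms),
    ("Soko V5 (µV)", "soko_v5_uv", truths[0].soko_v5_uv),
]:
    a, c = getattr(tam, attr), getattr(tcm, attr)
    print(f"{label:12s} {a:9.1f} {c:9.1f} {a - c:+7.2f}   {truth_val:.1f}")

print()
print(f"TAM pooled {tam.n_beats} beats across three analyses; "
      f"TCM used {tcm.n_beats} beats in one pooled median")
print("(TCM loses the beats whose windows touch the two junctions or the")
print("record edges).  The per-parameter differences are the quantity the")
print("non-inferiority analysis bounds at ±5 ms.")
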