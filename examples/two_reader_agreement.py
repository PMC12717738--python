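"""Full agreement analysis between two simulated readers.

Builds a 24-subject synthetic cohort (randomized beat templates, so the
cohort has genuine between-subject variance), analyzes each triplicate with
TCM, then simulates a second reader who nudges every fiducial caliper by
~1 ms before the measurements are recomputed.  The agreement suite then
produces the ICC(2,1), Bland-Altman bias/LOA, repeatability coefficient and
TOST non-inferiority verdict per parameter.
"""

import warnings

import numpy as np
import pandas as pd

from tripecg.agreement import compare_tables, comparison_table
from tripecg.fiducials import apply_override
from tripecg.measures import measure_all
from tripecg.synth import NoiseSpec, random_template, synth_triplicate
from tripecg.triplicate import analyze_tcm

rng = np.random.default_rng(11)
noise = NoiseSpec(baseline_wander_uv=40, mains_uv=10, broadband_sd_uv=20)

rows_a, rows_b = [], []
for s in range(24):
    template = random_template(rng)
    triplet, _ = synth_triplicate(
        template, mean_rr=float(rng.uniform(800, 1100)), rr_jitter_sd=25,
        noise=noise, seed=int(rng.integers(0, 2**31)),
        subject_id=f"S{s:02d}", visit_label="D0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = analyze_tcm(triplet)
        # reader B: manual ±1 ms caliper adjustments on the same VM
        edits = {k: float(v + rng.normal(0, 1.0))
                 for k, v in res.fiducials.as_dict().items() if v is not None}
        fids_b = apply_override(res.fiducials, edits)
        m_b = measure_all(res.representative, fids_b, provenance="tcm")
    common = {"subject_id": f"S{s:02d}", "visit_label": "D0"}
    rows_a.append({**common, **res.measurements.as_row()})
    rows_b.append({**common, **m_b.as_row()})

table_a, table_b = pd.DataFrame(rows_a), pd.DataFrame(rows_b)
results = compare_tables(table_a, table_b)
print(comparison_table(results).to_string(index=False))
print()
qtcf = results["qtcf_ms"]
print(f"QTcF inter-reader bias {qtcf.bias:+.2f} ms, "
      f"LOA [{qtcf.loa_lower:.2f}, {qtcf.loa_upper:.2f}] ms, ICC {qtcf.icc:.3f}.")
print("An ICC near 1 with LOA of a few ms mirrors the reproducibility level")
print("expected from semi-automated reading: the shared vector magnitude")
print("pins the marks, and the manual nudges are the only disagreement.")
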