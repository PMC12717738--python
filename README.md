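# tripecg

Semi-automated quantification of triplicate 12-lead resting ECGs, with the
method-agreement statistics needed to validate it.

## The problem

Serial ECG surveillance — QT-prolonging drugs, checkpoint-inhibitor
myocarditis, any cardio-oncology follow-up — needs interval and voltage
measurements that are reproducible to a few milliseconds and microvolts.
Manual calipers are slow and reader-dependent; fully automatic single-beat
readings are noise-sensitive.  The semi-automated approach implemented here
works on a **median representative beat**: sinus beats of a 10-s recording
are aligned on the R peak, premature ventricular contractions (PVCs) are
excluded, and each lead is collapsed to a per-sample median over beats,
giving one 1.2-s representative signal per lead.  Superimposing the 12
representative beats yields the **vector magnitude**

```
VM(t) = sqrt( Σ_lead  rep_lead(t)² )
```

on which one global set of fiducials — P onset, QRS onset/offset, T offset —
is placed by a threshold method (with a manual-override contract for every
mark).  From the fiducials and the averaged RR interval the tool derives:

* HR = 60000 / RR̄, PR, QRS, QT (ms)
* QTcF = QT / (RR̄/1000)^(1/3) (Fridericia), QTcB = QT / (RR̄/1000)^(1/2) (Bazett)
* per-lead R/S amplitudes, Sokolow–Lyon voltages
  `Soko V5 = S(V1) + R(V5)`, `Soko V6 = S(V1) + R(V6)` (µV)
* the low-QRS-voltage flag (YES when all frontal leads ≤ 500 µV or all
  precordial leads ≤ 1000 µV peak-to-peak within the QRS)

Triplicates (3 × 10 s, minutes apart) are analyzed two ways:

* **TAM** (triplicate assessment method): each record independently, results
  averaged;
* **TCM** (triplicate concatenation method): one ~30-s concatenated record,
  beats overlapping a ±600 ms zone around either junction excluded, one
  pooled median beat delineated once.

The **agreement suite** quantifies how well two arms (two readers, two
readings, TAM vs TCM) agree: Bland–Altman bias ± SD with 1.96·SD limits of
agreement and a proportional-bias regression, repeatability coefficient
RC = 1.96·SD, ICC(2,1) (two-way random effects, absolute agreement, single
measure) with its F-based 95% CI, TOST non-inferiority on paired differences
(±5 ms margin; 90% CI upper bound < 10 ms), and Benjamini–Hochberg FDR for
secondary endpoints.

Because real patient ECGs cannot ship with a package, a **synthetic
generator** produces 12-lead sinus records from Gaussian-lobe beat templates
whose PR/QRS/QT, R-peak times, wave amplitudes and noise are known exactly —
the truth channel every pipeline stage is validated against.

## Worked example

`python examples/triplicate_tam_vs_tcm.py` builds one noisy synthetic
triplicate session (RR 900 ms, 25 ms RR jitter, baseline wander + mains +
20 µV broadband noise) and analyzes it both ways:

```
parameter          TAM       TCM    diff   truth
HR (bpm)          66.6      66.6   -0.01   65.8
PR (ms)          157.0     158.0   -1.00   160.0
QRS (ms)          88.0      88.0   +0.00   90.0
QT (ms)          374.3     375.0   -0.67   380.0
QTcF (ms)        387.7     388.4   -0.71   391.8
Soko V5 (µV)    2174.5    2157.7  +16.84   2194.3

TAM pooled 30 beats across three analyses; TCM used 27 beats in one pooled median
```

The TAM–TCM differences (sub-ms for intervals here) are the quantity the
±5 ms non-inferiority analysis bounds.  Each mark also carries a small
(< 5 ms) stable offset against the generator's truth convention; being
common to both arms, it cancels in every method or reader comparison.

Other examples: `single_record_analysis.py` (pipeline vs truth on one
record), `two_reader_agreement.py` (a 24-subject cohort with a simulated
second reader, ending in the full ICC/LOA/TOST report table),
`synthetic_battery.py` (the named fixture battery plus quality checks).

A thin CLI wraps the same functions:

```bash
tripecg fixtures out/battery --seed 0          # synthetic battery + manifest
tripecg analyze out/battery/triplicates.csv --mode tcm --out meas.csv
tripecg compare meas_readerA.csv meas_readerB.csv --out-dir agreement/
```

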