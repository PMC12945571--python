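# inrmu

Measurement uncertainty of PT/INR test results at the calibration-laboratory
level of the INR traceability chain.

## The problem

Oral anticoagulant dosing is steered by the International Normalized Ratio,

```
INR = (PT / MNPT)^ISI
```

where PT is the prothrombin time of the patient plasma, MNPT is the mean
normal PT (geometric mean over ~20 healthy donors) and ISI is the
International Sensitivity Index of the thromboplastin reagent.  WHO
International Reference Preparations (IRPs) of thromboplastin anchor this
chain; calibration laboratories using the manual tilt-tube technique assign
INR values to reference materials, and those assignments carry a measurement
uncertainty that propagates to manufacturers and clinical laboratories.
This package quantifies that uncertainty.  On the natural-log scale the INR
model is linear, `ln INR = ISI · ln R` with `R = PT/MNPT`, and first-order
(GUM) error propagation over the three uncertainty sources gives

```
SD_logINR² = (ISI·SD_logPT)²/n + (ISI·SD_logMNPT)²/m + (ln R · SD_ISI)²
```

— PT repeatability (n replicates), MNPT intermediate precision (m
determinations) and ISI between-laboratory reproducibility.  The relative
standard uncertainty is `%ru ≈ 100·SD_logINR` (small-SD, log-normal
approximation), and the k = 2 expanded interval is
`exp(ln INR ∓ 2·SD_logINR)`.  All logarithms are natural logs.

The package is aimed at coagulation reference and calibration laboratories,
EQA organisers and metrologists evaluating whether the reference measurement
system fits its uncertainty budget (total INR standard uncertainty ≤ 10% at
the end user; 1/3 ≈ 3.3% rule-of-thumb share per tier, or half of the budget
for the reference thromboplastins).

Modules:

- `inrmu.core` — the propagation formula, confidence intervals, %ru,
  per-IRP summaries;
- `inrmu.profile` — CLSI-EP17-style precision profile (`%ru = a·INR^b`,
  log-log least squares) and budget allocation/checking;
- `inrmu.montecarlo` — Monte Carlo validation of the analytic formula;
- `inrmu.simulate` — synthetic multicenter calibration-study generator and
  top-down between-operator CV;
- `inrmu.io` / `inrmu.cli` — measurement-CSV I/O, report rendering and the
  `inrmu` command line.

## Worked example

The bundled dataset (`inrmu.data`) holds the calibration summaries of four
lyophilized plasmas (A ≈ INR 1 … D ≈ INR 4–5.5) measured against two WHO
thromboplastin standards, the 5th IS (rTF/16) and its harmonized successor,
the 6th IS (IRP 24/114):

```
$ python -c "from inrmu.data import example_csv_text; print(example_csv_text(), end='')" > measurements.csv
$ inrmu compute measurements.csv
irp_id      plasma_id  mean_inr  sd_log_inr  ci_95      ru_percent
----------  ---------  --------  ----------  ---------  ----------
rTF/16      Lyo A      1.00      0.010       0.98-1.02  1.0
rTF/16      Lyo B      2.25      0.047       2.05-2.47  4.7
rTF/16      Lyo C      3.40      0.070       2.96-3.91  7.0
rTF/16      Lyo D      5.49      0.097       4.52-6.67  9.7
IRP 24/114  Lyo A      0.94      0.013       0.92-0.97  1.3
IRP 24/114  Lyo B      1.84      0.022       1.76-1.92  2.2
IRP 24/114  Lyo C      2.81      0.032       2.64-3.00  3.2
IRP 24/114  Lyo D      4.10      0.041       3.78-4.46  4.1
# rTF/16: median %ru 5.8 (range 1.0-9.7, 4 plasmas)
# IRP 24/114: median %ru 2.7 (range 1.3-4.1, 4 plasmas)
```

Reading the output: the successor standard roughly halves the relative
uncertainty (median %ru 5.8 → 2.7) because its between-lab ISI spread is
twofold smaller, and the therapeutic-window plasmas B and C (2.2% and 3.2%)
stay below the 3.3% calibration-tier budget share.  `inrmu profile` fits
the power-law precision profile over INR 1.0–4.0, `inrmu oracle` checks
each row's analytic SD against a Monte Carlo simulation, and
`inrmu simulate` generates a synthetic 4-lab × 2-operator study and
compares the between-operator CV (top-down) with the analytic %ru
(bottom-up).

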