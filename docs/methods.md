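# Methods

## Model

The INR of a plasma measured with a given thromboplastin is
`INR = R^ISI`, `R = PT/MNPT`.  Taking natural logs linearizes the model,
`ln INR = ISI · ln R`, and first-order propagation of the three uncertainty
sources yields

```
SD_logINR² = (ISI·SD_logPT)²/n  +  (ISI·SD_logMNPT)²/m  +  (ln R · SD_ISI)²
```

The three addends map onto the classical precision hierarchy:

| term | source | precision component |
|---|---|---|
| `(ISI·SD_logPT)²/n` | PT replicates of the plasma | repeatability (same operator, same run) |
| `(ISI·SD_logMNPT)²/m` | repeated MNPT determinations | intermediate precision (same operator over time) |
| `(ln R·SD_ISI)²` | ISI assignment across calibration labs | reproducibility (between laboratory) |

Assumptions: log-normal PT and MNPT errors (normal on the ln scale), normal
ISI errors, and independence of the three sources.  Covariance terms are
deliberately omitted: the ISI is an externally assigned value from a
multi-laboratory exercise with fresh plasmas, the MNPT comes from prior
calibration studies, and lyophilized-plasma PT measurements are treated as
independent of both.  A structural consequence of the model worth knowing:
at `R = 1` (PT equals MNPT, INR 1) the ISI term vanishes entirely, so the
uncertainty of a normal plasma is insensitive to `SD_ISI`.

Derived quantities:

- expanded interval `exp(ln INR ∓ k·SD_logINR)` with coverage factor
  `k = 2` (≈95% under log-normality).  The interval is symmetric on the log
  scale, hence geometrically symmetric: `√(lo·hi) = INR` exactly.
- relative standard uncertainty `%ru`.  The default convention is the
  small-SD approximation `100·SD_logINR`; the exact log-normal value
  `100·(e^SD − 1)` is available as `mode="exact"`.  The exact value always
  exceeds the approximate one by less than `100·SD²` for `SD ≤ 0.2`.
- per-IRP summaries: median/min/max of the *unrounded* `%ru` values, median
  of an even count as the mean of the two central values, rounded to one
  decimal only for display.

All logarithms are natural; this is deliberately not configurable, since a
log10 variant would silently rescale every SD input.

## Parameters and units

| parameter | units | meaning |
|---|---|---|
| `pt_mean_seconds` | s | geometric mean of the n replicate PTs |
| `sd_log_pt` | ln scale | sample SD of ln(PT), (n−1) denominator |
| `mnpt_seconds` | s | geometric mean PT over ~20 healthy donors |
| `sd_log_mnpt` | ln scale | SD of ln(MNPT) across m determinations |
| `isi`, `sd_isi` | – | assigned ISI and its between-lab SD |
| `k` | – | coverage factor, default 2 |

`n = 1` or `m = 1` are accepted (new reagents may have very few MNPT
determinations — the bundled successor-IRP example has `m = 2`), but the
corresponding SD must then be supplied externally; it is never estimated
from a single value.  The printed "mean PT" of a calibration report is
interpreted as the geometric mean of the replicates, consistent with the
log-space analysis and with the MNPT definition; `ln INR` is computed from
that summary mean, not by averaging per-replicate INRs.

## Precision profile and budget

`%ru` as a function of INR is modelled as a power law `a·INR^b` (CLSI EP17
precision-profile style), fitted by ordinary least squares on the log-log
transformed points — deterministic and closed-form; points lying exactly on
a power law are recovered to machine precision.  Prediction is restricted
to the fitted domain (default INR 1.0–4.0) unless extrapolation is
explicitly requested, because the power-law shape is only validated there.

The 10% total-INR-uncertainty budget is shared linearly across tiers
(shares sum to the total): equal thirds for calibration labs, IVD
manufacturers and end users (≈3.3% each), or half to the primary+secondary
reference thromboplastins combined.  Linear sharing is the convention in
which these budgets are stated; the quadrature combination of shares is
reported separately for context (`quadrature_total`) but never used for
allocation.  Budget checks use strict inequality (`%ru < share`).

## Monte Carlo validation

`inrmu.montecarlo` draws the three sources directly —
`logPT* ~ N(ln PT̄, SD_logPT/√n)`, `logMNPT* ~ N(ln MNPT, SD_logMNPT/√m)`,
`ISI* ~ N(ISI, SD_ISI)` truncated below at 0 — and forms
`ln INR* = ISI*·(logPT* − logMNPT*)` per draw.  The validator compares the
empirical SD with the analytic value; pass means agreement within 3
standard errors, using the normal-theory `SE(SD) = SD/√(2N)` (adequate at
N ≥ 10⁴; the default is 10⁵ draws).  The check is two-sided: in the
small-SD regime the empirical SD exceeds the analytic one by a second-order
term `SD_ISI²·σ_X²` (tiny for realistic inputs), while grossly inflated ISI
uncertainty (e.g. `SD_ISI = 0.5`) leaves the regime altogether — the
positivity truncation then *reduces* the realized ISI variance and the
validator flags the breakdown with |z| ≫ 3, whichever sign it takes.
Normal ISI errors are the conventional choice; nothing in the data
constrains the ISI error law, and the truncation only matters when
`ISI/SD_ISI` is small.  Each source draws from its own child stream
(`SeedSequence.spawn`), so zeroing one source never shifts another's draws.

## Synthetic multicenter study

`inrmu.simulate` emulates the design of an IRP calibration exercise:
4 laboratories × 2 operators (defaults), each operator measuring every
plasma with n = 10 replicates and deriving an MNPT from a panel of 20
healthy donors.  Replicate and donor PTs are log-normal around their true
values; each operator's ISI is an independent normal realization truncated
positive.  `donor_log_sd` defaults to 0.05, a typical healthy-donor PT
spread on the ln scale, making the MNPT of a 20-donor panel scatter with
SD ≈ 0.011 — of the same order as the `sd_log_mnpt` values seen in
calibration reports; the generator exposes both knobs separately because
donor-level spread and between-study MNPT variation are distinct
quantities.  No lab-level random effect is included: the between-lab ISI
spread is pooled into a single SD across operators, matching how the
reproducibility component is summarised, and no variance decomposition into
lab vs operator is available to parameterize one.

The estimators mirror the analytic inputs: per-operator geometric means,
(n−1)-denominator SDs of logs, between-operator sample SD of the realized
ISIs.  The between-operator CV of the INR is the arithmetic SD/mean (×100)
of the per-operator INRs — the scale on which multicenter CVs are
conventionally reported, directly comparable to `%ru` for small spreads.

What passing the concordance test shows: when data are generated *by this
three-source model*, the top-down between-operator CV agrees with the
bottom-up analytic `%ru` (within ~15% relative, averaged over hundreds of
studies; the mean sample CV of 8 operators carries the `c₄(8) ≈ 0.965`
small-sample bias, which stays inside that tolerance).  What it does not
show: that real multicenter data contain no effects outside the model —
lab-level clustering, operator drift, reagent lot effects or
non-commutability of lyophilized materials are not simulated.

## Problem sizes and numerical choices

The test suite validates the Monte Carlo oracle at 5·10⁴–10⁵ draws per
parameter set and the study concordance over 300–500 replicated studies;
both finish in seconds.  Degenerate inputs are handled explicitly: all-zero
SDs give exactly zero uncertainty and a collapsed interval; zero-noise
generator components return the true values bit-exactly (no exp/log round
trip); the exact `%ru` uses `expm1` so it dominates the approximation even
at sub-machine-epsilon SDs.  Seeds are plain integers; every stochastic
path is reproducible bit-for-bit from (config, seed).

## Known limitations

- First-order propagation: valid for small SDs (the regime of all bundled
  examples); the Monte Carlo validator is the guard rail for anything else.
- The uncertainty estimates characterize lyophilized, non-commutable
  reference materials at the calibration-lab level; they are not the MU of
  patient INRs in routine laboratories.
- `SD_ISI` and `SD_logMNPT` are themselves estimated from small N (8
  operators, m = 2–6), which adds second-order uncertainty the formula does
  not model.
- ISI estimation itself (orthogonal regression on fresh plasmas) is out of
  scope; the ISI and its SD are inputs.
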