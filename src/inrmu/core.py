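"""Log-space measurement-uncertainty propagation for PT/INR results.

The INR reported for a plasma measured with a given thromboplastin is

    INR = (PT / MNPT)^ISI = R^ISI

where PT is the (geometric mean) prothrombin time of the plasma, MNPT is
the mean normal PT (geometric mean over ~20 healthy donors) and ISI is the
International Sensitivity Index of the reagent/measurement system.  On the
natural-log scale the model is linear, ln INR = ISI * ln R, and first-order
(GUM) propagation of the three uncertainty sources gives

    SD_logINR^2 = (ISI * SD_logPT)^2 / n
                + (ISI * SD_logMNPT)^2 / m
                + (ln R * SD_ISI)^2

with n PT replicates and m MNPT determinations.  The three addends are the
PT repeatability, MNPT intermediate-precision and ISI reproducibility
contributions.  Covariance terms are deliberately omitted: the ISI is an
externally assigned value from a multi-laboratory calibration, the MNPT
comes from prior calibration studies, and the lyophilized-plasma PT
measurements are treated as independent of both.

All logarithms in this package are natural logarithms; this is not
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ThromboplastinCalibration",
    "PlasmaMeasurement",
    "INRUncertaintyResult",
    "IRPSummary",
    "geometric_mean",
    "compute_inr",
    "sd_log_inr",
    "confidence_interval",
    "relative_uncertainty",
    "evaluate_plasma",
    "summarize_irp",
]


@dataclass(frozen=True)
class ThromboplastinCalibration:
    """Calibration state of one thromboplastin IRP / measurement system.

    Parameters
    ----------
    irp_id
        Label of the International Reference Preparation (e.g. ``"rTF/16"``).
    isi
        International Sensitivity Index (dimensionless, > 0).
    sd_isi
        Between-laboratory standard deviation of the assigned ISI
        (reproducibility component).
    mnpt_seconds
        Mean normal PT in seconds: geometric mean of healthy-donor PTs.
    sd_log_mnpt
        Standard deviation of ln(MNPT) across repeated MNPT determinations
        by the same operator (intermediate precision), natural-log scale.
    m
        Number of MNPT determinations entering the mean.
    """

    irp_id: str
    isi: float
    sd_isi: float
    mnpt_seconds: float
    sd_log_mnpt: float
    m: int

    def __post_init__(self) -> None:
        if not self.isi > 0:
            raise ValueError(f"isi must be positive, got {self.isi}")
        if not self.mnpt_seconds > 0:
            raise ValueError(f"mnpt_seconds must be positive, got {self.mnpt_seconds}")
        if self.sd_isi < 0:
            raise ValueError(f"sd_isi must be non-negative, got {self.sd_isi}")
        if self.sd_log_mnpt < 0:
            raise ValueError(f"sd_log_mnpt must be non-negative, got {self.sd_log_mnpt}")
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be a positive integer, got {self.m}")


@dataclass(frozen=True)
class PlasmaMeasurement:
    """PT summary statistics for one plasma under one measurement system.

    ``pt_mean_seconds`` is the geometric mean of the replicate PTs and
    ``sd_log_pt`` the sample SD of ln(PT) with (n-1) denominator.  If the
    raw ``replicates_seconds`` are supplied, use :meth:`from_replicates`
    so the summary fields are derived consistently.
    """

    plasma_id: str
    pt_mean_seconds: float
    sd_log_pt: float
    n: int
    replicates_seconds: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.pt_mean_seconds > 0:
            raise ValueError(f"pt_mean_seconds must be positive, got {self.pt_mean_seconds}")
        if self.sd_log_pt < 0:
            raise ValueError(f"sd_log_pt must be non-negative, got {self.sd_log_pt}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n}")
        if self.replicates_seconds is not None:
            reps = tuple(self.replicates_seconds)
            object.__setattr__(self, "replicates_seconds", reps)
            if len(reps) != self.n:
                raise ValueError(
                    f"n={self.n} does not match {len(reps)} replicates"
                )
            gm = geometric_mean(reps)
            if abs(gm - self.pt_mean_seconds) > 1e-9 * self.pt_mean_seconds:
                raise ValueError(
                    "pt_mean_seconds is not the geometric mean of the replicates "
                    f"({self.pt_mean_seconds} vs {gm})"
                )

    @classmethod
    def from_replicates(
        cls, plasma_id: str, replicates_seconds: Sequence[float]
    ) -> "PlasmaMeasurement":
        """Build the summary from raw replicate PTs.

        ``sd_log_pt`` uses the (n-1) denominator; a single replicate yields
        ``sd_log_pt = 0`` (no dispersion estimable, must be supplied
        externally if needed).
        """
        reps = tuple(float(r) for r in replicates_seconds)
        gm = geometric_mean(reps)
        n = len(reps)
        if n > 1:
            logs = [math.log(r) for r in reps]
            mean_log = sum(logs) / n
            sd = math.sqrt(sum((l - mean_log) ** 2 for l in logs) / (n - 1))
        else:
            sd = 0.0
        return cls(plasma_id, gm, sd, n, reps)


@dataclass(frozen=True)
class INRUncertaintyResult:
    """Per-plasma INR with its propagated uncertainty.

    ``term_contributions`` are the three variance addends (PT, MNPT, ISI)
    whose sum is ``sd_log_inr**2``.  The confidence interval is symmetric
    on the log scale, hence geometrically symmetric around ``mean_inr``:
    ``sqrt(ci_lower * ci_upper) == mean_inr``.
    """

    plasma_id: str
    irp_id: str
    mean_inr: float
    mean_log_inr: float
    sd_log_inr: float
    ci_lower: float
    ci_upper: float
    ru_percent: float
    k: float
    term_contributions: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.mean_inr <= self.ci_upper:
            raise ValueError("confidence interval does not bracket the mean INR")
        gm = math.sqrt(self.ci_lower * self.ci_upper)
        if abs(gm - self.mean_inr) > 1e-9 * self.mean_inr:
            raise ValueError("confidence interval is not geometrically symmetric")
        var = sum(self.term_contributions)
        if abs(var - self.sd_log_inr**2) > 1e-12:
            raise ValueError("term contributions do not sum to sd_log_inr**2")


def geometric_mean(values: Iterable[float]) -> float:
    """Geometric mean, exp of the arithmetic mean of natural logs.

    This is how the MNPT is defined (geometric mean of donor PTs) and how
    replicate PTs are summarised throughout.
    """
    vals = list(values)
    if not vals:
        raise ValueError("geometric_mean of an empty sequence")
    logs = []
    for v in vals:
        if not v > 0:
            raise ValueError(f"geometric_mean requires positive values, got {v}")
        logs.append(math.log(v))
    return math.exp(sum(logs) / len(logs))


def compute_inr(
    pt_mean_seconds: float, calib: ThromboplastinCalibration
) -> tuple[float, float]:
    """INR and ln(INR) from the summary PT and the calibration.

    ln INR = ISI * (ln PT - ln MNPT); computed from the geometric-mean PT,
    not by averaging per-replicate INRs.
    """
    if not pt_mean_seconds > 0:
        raise ValueError(f"pt_mean_seconds must be positive, got {pt_mean_seconds}")
    mean_log_inr = calib.isi * (math.log(pt_mean_seconds) - math.log(calib.mnpt_seconds))
    return math.exp(mean_log_inr), mean_log_inr


def sd_log_inr(
    plasma: PlasmaMeasurement, calib: ThromboplastinCalibration
) -> tuple[float, tuple[float, float, float]]:
    """First-order propagated SD of ln(INR) and its three variance terms.

    Returns ``(sd, (pt_term, mnpt_term, isi_term))`` with

        pt_term   = (ISI * SD_logPT)^2 / n     (repeatability)
        mnpt_term = (ISI * SD_logMNPT)^2 / m   (intermediate precision)
        isi_term  = (ln R * SD_ISI)^2          (reproducibility)

    Note the ISI term vanishes when PT equals MNPT (R = 1): for a normal
    plasma at INR 1 the ISI uncertainty contributes nothing.
    """
    log_r = math.log(plasma.pt_mean_seconds) - math.log(calib.mnpt_seconds)
    pt_term = (calib.isi * plasma.sd_log_pt) ** 2 / plasma.n
    mnpt_term = (calib.isi * calib.sd_log_mnpt) ** 2 / calib.m
    isi_term = (log_r * calib.sd_isi) ** 2
    terms = (pt_term, mnpt_term, isi_term)
    return math.sqrt(sum(terms)), terms


def confidence_interval(
    mean_log_inr: float, sd: float, k: float = 2.0
) -> tuple[float, float]:
    """Expanded interval exp(mean_log_inr -/+ k*sd) on the INR scale.

    k = 2 gives an approximate 95% level under log-normality.
    """
    if not k > 0:
        raise ValueError(f"coverage factor k must be positive, got {k}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    return math.exp(mean_log_inr - k * sd), math.exp(mean_log_inr + k * sd)


def relative_uncertainty(sd: float, mode: str = "approximate") -> float:
    """Relative standard uncertainty in percent from SD of ln(INR).

    ``approximate`` returns 100*sd (the small-SD log-normal approximation
    %ru ~ 100*SD_logINR); ``exact`` returns 100*(exp(sd) - 1), the exact
    geometric relative spread.  The exact value always exceeds the
    approximate one, by at most ~100*sd^2 for moderate sd.
    """
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if mode == "approximate":
        return 100.0 * sd
    if mode == "exact":
        return 100.0 * math.expm1(sd)
    raise ValueError(f"unknown mode {mode!r}; use 'approximate' or 'exact'")


def evaluate_plasma(
    plasma: PlasmaMeasurement,
    calib: ThromboplastinCalibration,
    k: float = 2.0,
    ru_mode: str = "approximate",
) -> INRUncertaintyResult:
    """Full per-plasma pipeline: INR, SD_logINR, CI and %ru in one result."""
    mean_inr, mean_log = compute_inr(plasma.pt_mean_seconds, calib)
    sd, terms = sd_log_inr(plasma, calib)
    lo, hi = confidence_interval(mean_log, sd, k)
    ru = relative_uncertainty(sd, ru_mode)
    return INRUncertaintyResult(
        plasma_id=plasma.plasma_id,
        irp_id=calib.irp_id,
        mean_inr=mean_inr,
        mean_log_inr=mean_log,
        sd_log_inr=sd,
        ci_lower=lo,
        ci_upper=hi,
        ru_percent=ru,
        k=k,
        term_contributions=terms,
    )


@dataclass(frozen=True)
class IRPSummary:
    """Across-plasma summary of %ru for one IRP."""

    irp_id: str
    median_ru_percent: float
    min_ru_percent: float
    max_ru_percent: float
    n_plasmas: int
    ru_values: tuple[float, ...] = field(repr=False, default=())

    @property
    def median_ru_rounded(self) -> float:
        """Median rounded to one decimal, the convention used in reports."""
        return round(self.median_ru_percent, 1)


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    if n % 2 == 1:
        return s[mid]
    return 0.5 * (s[mid - 1] + s[mid])


def summarize_irp(results: Sequence[INRUncertaintyResult]) -> IRPSummary:
    """Median / min / max %ru across plasmas for one IRP.

    The median is taken on the unrounded %ru values (even count: mean of
    the two central values); rounding to one decimal happens only at
    display time via :attr:`IRPSummary.median_ru_rounded`.
    """
    if not results:
        raise ValueError("summarize_irp of an empty result list")
    irp_ids = {r.irp_id for r in results}
    if len(irp_ids) > 1:
        raise ValueError(f"results mix IRPs: {sorted(irp_ids)}")
    rus = tuple(r.ru_percent for r in results)
    return IRPSummary(
        irp_id=results[0].irp_id,
        median_ru_percent=_median(rus),
        min_ru_percent=min(rus),
        max_ru_percent=max(rus),
        n_plasmas=len(rus),
        ru_values=rus,
    )
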