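"""Synthetic multicenter calibration-study generator.

Emulates the design of an IRP calibration exercise: 4 calibration
laboratories with 2 operators each, every operator measuring each
lyophilized plasma with n = 10 PT replicates and deriving an MNPT as the
geometric mean of 20 healthy-donor PTs.  Replicate and donor PTs are
log-normal around their true values; each operator's ISI is an independent
normal realization around the assigned ISI (truncated positive).  No
lab-level random effect is added: the between-lab ISI spread is pooled
into a single SD across all operators, which is how the reproducibility
component is summarised in practice.

The point of the module is the top-down / bottom-up comparison: the
between-operator CV of the INR (top-down, what a multicenter study
reports) should track the analytic %ru from the propagation formula
(bottom-up), because both measure the same three noise sources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    PlasmaMeasurement,
    ThromboplastinCalibration,
    geometric_mean,
)

__all__ = [
    "StudyConfig",
    "StudyData",
    "OperatorEstimate",
    "StudyEstimates",
    "generate_study",
    "estimate_parameters",
    "between_operator_cv",
    "repeat_between_operator_cv",
]


@dataclass(frozen=True)
class StudyConfig:
    """Generating parameters of one synthetic calibration study.

    ``replicate_log_sd`` is the within-operator SD of ln(PT) (repeatability
    of a single replicate), either one value for all plasmas or a
    per-plasma mapping.  ``donor_log_sd`` is the spread of ln(PT) across
    healthy donors; the MNPT an operator derives from ``donors`` donors
    then has log-scale SD ``donor_log_sd / sqrt(donors)``.  The default
    0.05 is a typical normal-donor PT spread.
    """

    true_calib: ThromboplastinCalibration
    true_plasma_pts: Mapping[str, float]
    replicate_log_sd: float | Mapping[str, float] = 0.016
    n_labs: int = 4
    operators_per_lab: int = 2
    replicates: int = 10
    donors: int = 20
    donor_log_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_labs", "operators_per_lab", "replicates", "donors"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.donor_log_sd < 0:
            raise ValueError(f"donor_log_sd must be non-negative, got {self.donor_log_sd}")
        if not self.true_plasma_pts:
            raise ValueError("true_plasma_pts must name at least one plasma")
        for pid, pt in self.true_plasma_pts.items():
            if not pt > 0:
                raise ValueError(f"true PT for plasma {pid!r} must be positive, got {pt}")
        for pid in self.plasma_ids:
            if self.sd_log_pt_for(pid) < 0:
                raise ValueError(f"replicate_log_sd for plasma {pid!r} is negative")

    @property
    def n_operators(self) -> int:
        return self.n_labs * self.operators_per_lab

    @property
    def plasma_ids(self) -> tuple[str, ...]:
        return tuple(self.true_plasma_pts)

    def sd_log_pt_for(self, plasma_id: str) -> float:
        if isinstance(self.replicate_log_sd, Mapping):
            return float(self.replicate_log_sd[plasma_id])
        return float(self.replicate_log_sd)


@dataclass(frozen=True)
class StudyData:
    """Raw output of one synthetic study.

    Arrays are indexed by operator in ``operator_ids`` order, a flat list
    of ``"lab{i}/op{j}"`` labels.
    """

    config: StudyConfig
    operator_ids: tuple[str, ...]
    plasma_ids: tuple[str, ...]
    # (n_operators, n_plasmas, replicates) PT seconds
    replicates_seconds: np.ndarray = field(repr=False)
    # (n_operators, donors) PT seconds
    donor_panels_seconds: np.ndarray = field(repr=False)
    # (n_operators,) realized ISI per operator
    operator_isi: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n_op, n_pl = len(self.operator_ids), len(self.plasma_ids)
        if self.replicates_seconds.shape != (n_op, n_pl, self.config.replicates):
            raise ValueError("replicates_seconds shape does not match config")
        if self.donor_panels_seconds.shape != (n_op, self.config.donors):
            raise ValueError("donor_panels_seconds shape does not match config")
        if self.operator_isi.shape != (n_op,):
            raise ValueError("operator_isi shape does not match config")
        if (self.replicates_seconds <= 0).any() or (self.donor_panels_seconds <= 0).any():
            raise ValueError("all PTs must be positive")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of the replicate PTs (one row per replicate)."""
        rows = []
        for i, op in enumerate(self.operator_ids):
            for j, pid in enumerate(self.plasma_ids):
                for r, pt in enumerate(self.replicates_seconds[i, j]):
                    rows.append((op, pid, r + 1, float(pt), float(self.operator_isi[i])))
        return pd.DataFrame(
            rows, columns=["operator_id", "plasma_id", "replicate", "pt_seconds", "isi"]
        )


def generate_study(config: StudyConfig) -> StudyData:
    """Draw one complete study, deterministically under ``config.seed``.

    Replicate, donor and ISI draws come from separate child streams of the
    seed, so changing e.g. the donor panel size leaves the replicate PTs
    untouched.
    """
    ss_rep, ss_donor, ss_isi = np.random.SeedSequence(config.seed).spawn(3)
    rng_rep = np.random.default_rng(ss_rep)
    rng_donor = np.random.default_rng(ss_donor)
    rng_isi = np.random.default_rng(ss_isi)

    n_op = config.n_operators
    plasma_ids = config.plasma_ids
    calib = config.true_calib

    reps = np.empty((n_op, len(plasma_ids), config.replicates))
    for j, pid in enumerate(plasma_ids):
        sd = config.sd_log_pt_for(pid)
        true_pt = config.true_plasma_pts[pid]
        if sd == 0:
            # keep zero-noise values bit-exact (no exp/log round trip)
            reps[:, j, :] = true_pt
        else:
            reps[:, j, :] = np.exp(
                rng_rep.normal(math.log(true_pt), sd, (n_op, config.replicates))
            )

    if config.donor_log_sd == 0:
        donors = np.full((n_op, config.donors), calib.mnpt_seconds)
    else:
        donors = np.exp(
            rng_donor.normal(
                math.log(calib.mnpt_seconds), config.donor_log_sd, (n_op, config.donors)
            )
        )

    if calib.sd_isi == 0:
        isi = np.full(n_op, calib.isi)
    else:
        isi = rng_isi.normal(calib.isi, calib.sd_isi, n_op)
        bad = isi <= 0
        while bad.any():
            isi[bad] = rng_isi.normal(calib.isi, calib.sd_isi, int(bad.sum()))
            bad = isi <= 0

    operator_ids = tuple(
        f"lab{lab + 1}/op{op + 1}"
        for lab in range(config.n_labs)
        for op in range(config.operators_per_lab)
    )
    return StudyData(
        config=config,
        operator_ids=operator_ids,
        plasma_ids=plasma_ids,
        replicates_seconds=reps,
        donor_panels_seconds=donors,
        operator_isi=isi,
    )


@dataclass(frozen=True)
class OperatorEstimate:
    """Per-operator summary statistics recovered from the raw data."""

    operator_id: str
    mnpt_seconds: float
    isi: float
    plasmas: tuple[PlasmaMeasurement, ...]


@dataclass(frozen=True)
class StudyEstimates:
    per_operator: tuple[OperatorEstimate, ...]
    isi_mean: float
    sd_isi: float
    sd_log_mnpt: float


def estimate_parameters(data: StudyData) -> StudyEstimates:
    """Recover the summary statistics the propagation formula consumes.

    Per operator: MNPT as the geometric mean of the donor panel and, per
    plasma, the geometric-mean PT with the (n-1)-denominator SD of ln(PT).
    Across operators: the sample SD (n-1) of the realized ISIs estimates
    SD_ISI, and the sample SD of ln(operator MNPT) estimates SD_logMNPT.
    Requires at least two operators for the between-operator SDs.
    """
    n_op = len(data.operator_ids)
    if n_op < 2:
        raise ValueError("between-operator SDs are undefined with fewer than 2 operators")
    per_op = []
    log_mnpts = []
    for i, op_id in enumerate(data.operator_ids):
        mnpt = geometric_mean(data.donor_panels_seconds[i])
        log_mnpts.append(math.log(mnpt))
        plasmas = tuple(
            PlasmaMeasurement.from_replicates(pid, data.replicates_seconds[i, j])
            for j, pid in enumerate(data.plasma_ids)
        )
        per_op.append(
            OperatorEstimate(
                operator_id=op_id,
                mnpt_seconds=mnpt,
                isi=float(data.operator_isi[i]),
                plasmas=plasmas,
            )
        )
    return StudyEstimates(
        per_operator=tuple(per_op),
        isi_mean=float(np.mean(data.operator_isi)),
        sd_isi=float(np.std(data.operator_isi, ddof=1)),
        sd_log_mnpt=float(np.std(log_mnpts, ddof=1)),
    )


def between_operator_cv(data: StudyData, plasma_id: str) -> float:
    """Top-down between-operator CV% of the INR for one plasma.

    Each operator's INR uses that operator's own geometric-mean PT, MNPT
    and realized ISI; the CV is the arithmetic SD/mean (x100) of those
    INRs, the conventional scale for between-operator CVs.
    """
    if len(data.operator_ids) < 2:
        raise ValueError("between-operator CV requires at least 2 operators")
    if plasma_id not in data.plasma_ids:
        raise KeyError(f"unknown plasma {plasma_id!r}; have {data.plasma_ids}")
    j = data.plasma_ids.index(plasma_id)
    inrs = []
    for i in range(len(data.operator_ids)):
        pt = geometric_mean(data.replicates_seconds[i, j])
        mnpt = geometric_mean(data.donor_panels_seconds[i])
        isi = float(data.operator_isi[i])
        inrs.append((pt / mnpt) ** isi)
    inrs = np.asarray(inrs)
    return float(100.0 * np.std(inrs, ddof=1) / np.mean(inrs))


def repeat_between_operator_cv(
    config: StudyConfig, plasma_id: str, n_studies: int
) -> np.ndarray:
    """Between-operator CV% across ``n_studies`` independently seeded
    replications of the study design (seeds spawned from ``config.seed``)."""
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n_studies)
    cvs = np.empty(n_studies)
    for i, child in enumerate(children):
        # derive a plain integer child seed so each study is itself reproducible
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        cfg_i = StudyConfig(
            true_calib=config.true_calib,
            true_plasma_pts=config.true_plasma_pts,
            replicate_log_sd=config.replicate_log_sd,
            n_labs=config.n_labs,
            operators_per_lab=config.operators_per_lab,
            replicates=config.replicates,
            donors=config.donors,
            donor_log_sd=config.donor_log_sd,
            seed=sub_seed,
        )
        cvs[i] = between_operator_cv(generate_study(cfg_i), plasma_id)
    return cvs
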