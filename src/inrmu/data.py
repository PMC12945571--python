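"""Worked-example dataset: WHO thromboplastin IRP calibration summaries.

Four lyophilized plasmas (A: INR ~1, normal; B: ~2, therapeutic;
C: ~3, therapeutic; D: ~4-5.5, supratherapeutic) measured with the manual
tilt-tube technique against two WHO International Reference Preparations:
the 5th IS human recombinant thromboplastin (rTF/16) and its successor,
the 6th IS (coded 24/114).  PT summaries are geometric means of n = 10
replicates; the rTF/16 MNPT pools m = 6 determinations, the 24/114 MNPT
only m = 2 (the reagent is new).  SD_ISI for rTF/16 reflects a 20-lab
non-harmonized study; for 24/114 a 4-lab (2 operators each) harmonized
study, hence the twofold smaller value.
"""

from __future__ import annotations

from .core import PlasmaMeasurement, ThromboplastinCalibration

__all__ = ["RTF16", "IRP24114", "example_rows", "example_csv_text"]

RTF16 = ThromboplastinCalibration(
    irp_id="rTF/16", isi=1.11, sd_isi=0.063,
    mnpt_seconds=12.17, sd_log_mnpt=0.014, m=6,
)

IRP24114 = ThromboplastinCalibration(
    irp_id="IRP 24/114", isi=1.08, sd_isi=0.030,
    mnpt_seconds=11.28, sd_log_mnpt=0.016, m=2,
)

_PLASMAS: dict[str, list[tuple[str, float, float, int]]] = {
    "rTF/16": [
        ("Lyo A", 12.17, 0.021, 10),
        ("Lyo B", 25.25, 0.0090, 10),
        ("Lyo C", 36.64, 0.011, 10),
        ("Lyo D", 56.46, 0.020, 10),
    ],
    "IRP 24/114": [
        ("Lyo A", 10.69, 0.016, 10),
        ("Lyo B", 19.80, 0.016, 10),
        ("Lyo C", 29.38, 0.016, 10),
        ("Lyo D", 41.70, 0.017, 10),
    ],
}


def example_rows() -> list[tuple[PlasmaMeasurement, ThromboplastinCalibration]]:
    """The eight (plasma, calibration) pairs of the worked example."""
    calibs = {c.irp_id: c for c in (RTF16, IRP24114)}
    rows = []
    for irp_id, plasmas in _PLASMAS.items():
        calib = calibs[irp_id]
        for plasma_id, pt, sd, n in plasmas:
            rows.append((PlasmaMeasurement(plasma_id, pt, sd, n), calib))
    return rows


def example_csv_text() -> str:
    """The worked example rendered in the measurement-CSV input format."""
    lines = ["irp_id,plasma_id,pt_mean_s,sd_log_pt,n,mnpt_s,sd_log_mnpt,m,isi,sd_isi"]
    for plasma, calib in example_rows():
        lines.append(
            f"{calib.irp_id},{plasma.plasma_id},{plasma.pt_mean_seconds},"
            f"{plasma.sd_log_pt},{plasma.n},{calib.mnpt_seconds},"
            f"{calib.sd_log_mnpt},{calib.m},{calib.isi},{calib.sd_isi}"
        )
    return "\n".join(lines) + "\n"
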