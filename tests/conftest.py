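import pytest

from inrmu.data import IRP24114, RTF16, example_rows


@pytest.fixture(scope="session")
def worked_rows():
    """The eight (plasma, calibration) pairs of the IRP worked example."""
    return example_rows()


@pytest.fixture(scope="session")
def rtf16():
    return RTF16


@pytest.fixture(scope="session")
def irp24114():
    return IRP24114


# printed report values of the worked example:
# (irp_id, plasma_id) -> (mean INR, SD_logINR, CI lower, CI upper, %ru)
PRINTED_OUTPUTS = {
    ("rTF/16", "Lyo A"): (1.00, 0.010, 0.98, 1.02, 1.0),
    ("rTF/16", "Lyo B"): (2.25, 0.047, 2.05, 2.47, 4.7),
    ("rTF/16", "Lyo C"): (3.40, 0.070, 2.95, 3.91, 7.0),
    ("rTF/16", "Lyo D"): (5.49, 0.098, 4.52, 6.67, 9.8),
    ("IRP 24/114", "Lyo A"): (0.94, 0.014, 0.92, 0.97, 1.4),
    ("IRP 24/114", "Lyo B"): (1.84, 0.022, 1.76, 1.92, 2.2),
    ("IRP 24/114", "Lyo C"): (2.81, 0.032, 2.64, 3.00, 3.2),
    ("IRP 24/114", "Lyo D"): (4.10, 0.042, 3.78, 4.46, 4.2),
}


@pytest.fixture(scope="session")
def printed_outputs():
    return PRINTED_OUTPUTS
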