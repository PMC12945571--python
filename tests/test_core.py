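"""Unit and property tests for the log-space INR uncertainty core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inrmu import (
    PlasmaMeasurement,
    ThromboplastinCalibration,
    compute_inr,
    confidence_interval,
    evaluate_plasma,
    geometric_mean,
    relative_uncertainty,
    sd_log_inr,
    summarize_irp,
)


class TestGeometricMean:
    def test_two_point(self):
        assert geometric_mean([2, 8]) == pytest.approx(4.0)

    def test_singleton_identity(self):
        assert geometric_mean([12.17]) == pytest.approx(12.17)

    def test_twenty_lognormal_draws_match_exp_mean_log_oracle(self):
        # 20 donor-like PTs drawn as exp(Normal(ln 11.28, 0.05)); the frozen
        # expectation is exp(mean(ln x)) evaluated independently with numpy
        rng = np.random.default_rng(20240114)
        draws = np.exp(rng.normal(np.log(11.28), 0.05, 20))
        assert geometric_mean(draws) == pytest.approx(11.308668461729445, rel=1e-12)

    @pytest.mark.parametrize("bad", [[], [1.0, 0.0], [1.0, -2.0]])
    def test_rejects_empty_or_nonpositive(self, bad):
        with pytest.raises(ValueError):
            geometric_mean(bad)


class TestComputeInr:
    def test_therapeutic_plasma(self, rtf16):
        inr, _ = compute_inr(25.25, rtf16)
        assert inr == pytest.approx(2.25, abs=0.01)

    def test_pt_equal_mnpt_forces_unit_inr(self, rtf16):
        inr, log_inr = compute_inr(12.17, rtf16)
        assert inr == 1.0
        assert log_inr == 0.0

    def test_successor_irp_plasma(self, irp24114):
        inr, _ = compute_inr(19.80, irp24114)
        assert inr == pytest.approx(1.84, abs=0.01)

    def test_rejects_nonpositive_pt(self, rtf16):
        with pytest.raises(ValueError):
            compute_inr(0.0, rtf16)


class TestSdLogInr:
    def test_therapeutic_row(self, rtf16):
        plasma = PlasmaMeasurement("Lyo B", 25.25, 0.0090, 10)
        sd, _ = sd_log_inr(plasma, rtf16)
        assert sd == pytest.approx(0.047, abs=0.002)

    def test_successor_row(self, irp24114):
        plasma = PlasmaMeasurement("Lyo C", 29.38, 0.016, 10)
        sd, _ = sd_log_inr(plasma, irp24114)
        assert sd == pytest.approx(0.032, abs=0.002)

    def test_zero_sds_give_zero(self):
        calib = ThromboplastinCalibration("x", 1.1, 0.0, 12.0, 0.0, 4)
        plasma = PlasmaMeasurement("p", 30.0, 0.0, 10)
        sd, terms = sd_log_inr(plasma, calib)
        assert sd == 0.0
        assert terms == (0.0, 0.0, 0.0)

    def test_unit_ratio_annihilates_isi_term(self, rtf16):
        # PT == MNPT: ln R = 0, so the ISI reproducibility term vanishes
        plasma = PlasmaMeasurement("Lyo A", 12.17, 0.021, 10)
        sd, terms = sd_log_inr(plasma, rtf16)
        assert terms[2] == 0.0
        assert sd == pytest.approx(0.010, abs=0.002)

    def test_monotone_in_each_sd_and_antitone_in_counts(self):
        base = dict(isi=1.1, sd_isi=0.03, mnpt=12.0, sd_mnpt=0.015, m=4,
                    pt=30.0, sd_pt=0.02, n=10)

        def sd_of(**over):
            p = {**base, **over}
            calib = ThromboplastinCalibration("x", p["isi"], p["sd_isi"],
                                              p["mnpt"], p["sd_mnpt"], p["m"])
            plasma = PlasmaMeasurement("p", p["pt"], p["sd_pt"], p["n"])
            return sd_log_inr(plasma, calib)[0]

        for key, grid in [("sd_pt", [0, 0.01, 0.02, 0.05]),
                          ("sd_mnpt", [0, 0.01, 0.02, 0.05]),
                          ("sd_isi", [0, 0.02, 0.05, 0.1])]:
            vals = [sd_of(**{key: g}) for g in grid]
            assert vals == sorted(vals)
        for key in ("n", "m"):
            vals = [sd_of(**{key: g}) for g in [1, 2, 10, 100]]
            assert vals == sorted(vals, reverse=True)

    def test_vanishes_in_large_sample_limit_without_isi_uncertainty(self):
        calib = ThromboplastinCalibration("x", 1.1, 0.0, 12.0, 0.02, 10**9)
        plasma = PlasmaMeasurement("p", 30.0, 0.02, 10**9)
        sd, _ = sd_log_inr(plasma, calib)
        assert sd < 1e-6


class TestConfidenceInterval:
    def test_therapeutic_row(self):
        lo, hi = confidence_interval(math.log(2.25), 0.047, 2)
        assert lo == pytest.approx(2.05, abs=0.03)
        assert hi == pytest.approx(2.47, abs=0.03)

    def test_zero_sd_collapses(self):
        lo, hi = confidence_interval(math.log(3.4), 0.0, 2)
        assert lo == hi == pytest.approx(3.4)

    def test_rejects_nonpositive_k(self):
        with pytest.raises(ValueError):
            confidence_interval(0.5, 0.02, 0)

    @settings(derandomize=True, max_examples=200)
    @given(
        log_inr=st.floats(-2, 2),
        sd=st.floats(0, 0.5),
        k=st.floats(0.5, 4),
    )
    def test_interval_is_geometrically_symmetric(self, log_inr, sd, k):
        lo, hi = confidence_interval(log_inr, sd, k)
        mean = math.exp(log_inr)
        assert lo <= mean <= hi
        assert math.sqrt(lo * hi) == pytest.approx(mean, rel=1e-9)


class TestRelativeUncertainty:
    def test_approximate_is_100_sd(self):
        assert relative_uncertainty(0.047, "approximate") == pytest.approx(4.7)

    def test_exact_expm1_form(self):
        assert relative_uncertainty(0.047, "exact") == pytest.approx(4.812, abs=0.001)

    def test_zero_in_both_modes(self):
        assert relative_uncertainty(0.0, "approximate") == 0.0
        assert relative_uncertainty(0.0, "exact") == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            relative_uncertainty(0.01, "log10")

    @settings(derandomize=True, max_examples=200)
    @given(sd=st.floats(0, 0.2))
    def test_exact_dominates_approximate_within_second_order(self, sd):
        exact = relative_uncertainty(sd, "exact")
        approx = relative_uncertainty(sd, "approximate")
        assert exact >= approx
        assert exact - approx <= 100 * sd**2


class TestSummaries:
    def test_reference_irp_median(self, worked_rows):
        results = [evaluate_plasma(p, c) for p, c in worked_rows if c.irp_id == "rTF/16"]
        s = summarize_irp(results)
        assert s.median_ru_rounded == pytest.approx(5.8)

    def test_successor_irp_median_and_range(self, worked_rows):
        results = [evaluate_plasma(p, c) for p, c in worked_rows if c.irp_id == "IRP 24/114"]
        s = summarize_irp(results)
        assert s.median_ru_rounded == pytest.approx(2.7)
        assert s.min_ru_percent == pytest.approx(1.4, abs=0.15)
        assert s.max_ru_percent == pytest.approx(4.2, abs=0.15)

    def test_singleton_summary(self, worked_rows):
        r = evaluate_plasma(*worked_rows[0])
        s = summarize_irp([r])
        assert s.median_ru_percent == s.min_ru_percent == s.max_ru_percent == r.ru_percent

    def test_empty_and_mixed_irp_rejected(self, worked_rows):
        with pytest.raises(ValueError):
            summarize_irp([])
        mixed = [evaluate_plasma(p, c) for p, c in worked_rows]
        with pytest.raises(ValueError):
            summarize_irp(mixed)


class TestDomainTypes:
    def test_from_replicates_derives_summary(self):
        reps = [12.1, 12.3, 12.0]
        p = PlasmaMeasurement.from_replicates("p", reps)
        logs = [math.log(r) for r in reps]
        assert p.n == 3
        assert p.pt_mean_seconds == pytest.approx(math.exp(sum(logs) / 3))
        mean_log = sum(logs) / 3
        sd = math.sqrt(sum((l - mean_log) ** 2 for l in logs) / 2)
        assert p.sd_log_pt == pytest.approx(sd)

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(ValueError):
            PlasmaMeasurement("p", 13.0, 0.01, 3, (12.1, 12.3, 12.0))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(isi=0.0),
            dict(mnpt_seconds=-1.0),
            dict(sd_isi=-0.1),
            dict(m=0),
        ],
    )
    def test_calibration_invariants(self, kwargs):
        base = dict(irp_id="x", isi=1.1, sd_isi=0.03, mnpt_seconds=12.0,
                    sd_log_mnpt=0.01, m=2)
        with pytest.raises(ValueError):
            ThromboplastinCalibration(**{**base, **kwargs})

    def test_result_carries_variance_decomposition(self, worked_rows):
        r = evaluate_plasma(*worked_rows[1])
        assert sum(r.term_contributions) == pytest.approx(r.sd_log_inr**2, abs=1e-12)
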