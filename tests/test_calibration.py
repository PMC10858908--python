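"""Segmented exponential mass-RT calibration: fitting, prediction, Mw tools."""

import json

import numpy as np
import pytest

from chitosec.calibration import (
    CalibrationModel,
    CalibrationStandard,
    dispersity,
    fit_calibration,
    load_standards_csv,
    mw_distribution,
    peak_max_mw,
)
from chitosec.errors import FitError, NoPeakError, ValidationError
from chitosec.ri import Chromatogram
from conftest import SEED, gaussian_trace

BOUNDS = ((100.0, 1_000.0), (1_000.0, 10_000.0), (10_000.0, 1_000_000.0))
# one ln(M) = a + b*RT line per segment, used to simulate standards
TRUE_LINES = {0: (13.8, -0.77), 1: (15.2, -0.92), 2: (17.8, -1.32)}


def make_standards(n_per_segment=8, rt_noise=0.0, rng=None):
    rng = rng or np.random.default_rng(SEED)
    standards = []
    for i, (lo, hi) in enumerate(BOUNDS):
        a, b = TRUE_LINES[i]
        masses = np.exp(np.linspace(np.log(lo) + 0.05, np.log(hi), n_per_segment))
        masses[-1] = hi  # exact boundary mass (goes to this, the lower, segment)
        for j, m in enumerate(masses):
            rt = (np.log(m) - a) / b + rng.normal(0.0, rt_noise)
            standards.append(CalibrationStandard(f"s{i}_{j}", m, m / 1.5, rt))
    return standards


class TestFit:
    def test_two_exact_points_per_segment(self):
        model = fit_calibration(make_standards(2), BOUNDS)
        for seg, (a, b) in zip(sorted(model.segments, key=lambda s: s.mass_lo),
                               TRUE_LINES.values()):
            assert seg.r2 == pytest.approx(1.0, abs=1e-12)
            assert seg.slope == pytest.approx(b, rel=1e-9)
            assert seg.intercept == pytest.approx(a, rel=1e-9)

    def test_slope_recovery_under_rt_noise(self):
        model = fit_calibration(make_standards(8, rt_noise=0.02), BOUNDS)
        for seg, (a, b) in zip(sorted(model.segments, key=lambda s: s.mass_lo),
                               TRUE_LINES.values()):
            assert seg.slope == pytest.approx(b, rel=0.05)
            assert seg.r2 >= 0.99

    def test_single_point_segment_errors(self):
        standards = make_standards(2)[1:]  # lowest segment loses a point
        with pytest.raises(FitError, match="100"):
            fit_calibration(standards, BOUNDS)

    def test_mn_statistic(self):
        model = fit_calibration(make_standards(4), BOUNDS, statistic="Mn")
        assert model.statistic == "Mn"
        for seg in model.segments:
            assert seg.slope < 0

    def test_boundary_standard_goes_to_lower_segment(self):
        standards = make_standards(2)
        a, b = TRUE_LINES[0]
        standards.append(CalibrationStandard("edge", 1_000.0, 600.0, (np.log(1000) - a) / b))
        model = fit_calibration(standards, BOUNDS)
        low = min(model.segments, key=lambda s: s.mass_lo)
        assert low.n == 3

    def test_standards_csv(self, tmp_path):
        path = tmp_path / "standards.csv"
        path.write_text("id,mw_da,mn_da,rt_min,source\nP1,134000,67000,4.2,SEC-MALS-RI\n"
                        "P2,66000,,4.8,supplier\n")
        stds = load_standards_csv(path)
        assert stds[0].mw_da == 134000 and stds[0].mn_da == 67000
        assert stds[1].mn_da is None


class TestPrediction:
    def test_round_trip_identities(self, cal_model):
        for mass in (150.0, 500.0, 3e3, 5e4, 8e5):
            rt, ex = cal_model.predict_rt(mass)
            assert not ex
            back, _ = cal_model.predict_mass(rt)
            assert back == pytest.approx(mass, rel=1e-9)
        for rt in (3.5, 7.0, 10.5):
            mass, _ = cal_model.predict_mass(rt)
            assert cal_model.predict_rt(mass)[0] == pytest.approx(rt, rel=1e-9)

    def test_log_linear_interpolation_is_geometric_mean(self):
        model = fit_calibration(make_standards(2), BOUNDS)
        seg = max(model.segments, key=lambda s: s.mass_hi)
        m1, _ = model.predict_mass(seg.rt_lo)
        m2, _ = model.predict_mass(seg.rt_hi)
        mid, _ = model.predict_mass((seg.rt_lo + seg.rt_hi) / 2)
        assert mid == pytest.approx(np.sqrt(m1 * m2), rel=1e-9)

    def test_monotone_decreasing_across_segments(self, cal_model):
        rts = np.linspace(3.0, 12.0, 200)
        masses = [cal_model.predict_mass(rt)[0] for rt in rts]
        assert all(b < a for a, b in zip(masses[:-1], masses[1:]))

    def test_extrapolation_flagged(self, cal_model):
        _, ex = cal_model.predict_mass(13.5)
        assert ex
        _, ex = cal_model.predict_rt(5e6)
        assert ex
        with pytest.raises(ValidationError):
            cal_model.predict_mass(-1.0)

    def test_positive_slope_rejected(self):
        from chitosec.calibration import Segment
        with pytest.raises(ValidationError):
            CalibrationModel("Mw", [Segment(1e2, 1e3, 9, 12, 10.0, 0.5, 1.0)])

    def test_json_round_trip(self, cal_model, tmp_path):
        path = tmp_path / "model.json"
        cal_model.to_json(path)
        back = CalibrationModel.from_json(path)
        assert back.statistic == cal_model.statistic
        for rt in (4.0, 8.0, 11.0):
            assert back.predict_mass(rt) == cal_model.predict_mass(rt)


class TestMwDistribution:
    def test_zero_trace(self, cal_model):
        t = np.linspace(0, 14, 1401)
        dist = mw_distribution(cal_model, Chromatogram(t, np.zeros_like(t)), (3.0, 8.0))
        assert (dist.riu == 0).all()
        assert (np.diff(dist.mw_da) < 0).all()

    def test_single_sample_region(self, cal_model):
        t = np.linspace(0, 14, 1401)
        dist = mw_distribution(cal_model, Chromatogram(t, np.ones_like(t)), (5.0, 5.005))
        assert len(dist) == 1


class TestPeakMaxMw:
    def test_gaussian_at_120kda(self, cal_model):
        rt0, _ = cal_model.predict_rt(120_000.0)
        t, s = gaussian_trace([rt0], [10.0])
        mw, ex = peak_max_mw(cal_model, Chromatogram(t, s), (3.0, 8.0))
        assert not ex
        assert mw == pytest.approx(120_000.0, rel=0.02)

    def test_all_zero_region_raises(self, cal_model):
        t, s = gaussian_trace([], [])
        with pytest.raises(NoPeakError):
            peak_max_mw(cal_model, Chromatogram(t, s), (3.0, 8.0))

    def test_equal_bimodal_takes_earlier_rt(self, cal_model):
        t, s = gaussian_trace([4.0, 6.0], [5.0, 5.0])
        mw, _ = peak_max_mw(cal_model, Chromatogram(t, s), (3.0, 8.0))
        assert mw == pytest.approx(cal_model.predict_mass(4.0)[0], rel=0.01)


class TestDispersity:
    @pytest.mark.parametrize("mw,mn,expect", [(100.0, 100.0, 1.0), (134000.0, 67000.0, 2.0)])
    def test_values(self, mw, mn, expect):
        assert dispersity(mw, mn) == pytest.approx(expect)

    def test_invariant_violation(self):
        with pytest.raises(ValidationError):
            dispersity(50.0, 100.0)
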