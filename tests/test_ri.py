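"""RI trace loading, baseline correction, peak detection and window areas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chitosec.errors import (
    ConfigurationError,
    FormatError,
    ParameterError,
    UndefinedShareError,
    ValidationError,
)
from chitosec.ri import (
    Chromatogram,
    DPWindowMap,
    correct_baseline,
    detect_peaks,
    integrate_polymer,
    integrate_windows,
    load_ri_csv,
    split_fractions,
    windows_from_ladder,
)
from conftest import gaussian_trace


class TestLoad:
    def test_well_formed_two_rows(self, tmp_path):
        p = tmp_path / "ri.csv"
        p.write_text("time_min,riu\n0.0,1.0\n0.1,2.0\n")
        c = load_ri_csv(p)
        assert len(c) == 2

    def test_shuffled_times_rejected(self, tmp_path):
        p = tmp_path / "ri.csv"
        p.write_text("time_min,riu\n0.2,1.0\n0.1,2.0\n0.3,0.5\n")
        with pytest.raises(FormatError):
            load_ri_csv(p)

    def test_too_few_rows(self, tmp_path):
        p = tmp_path / "ri.csv"
        p.write_text("time_min,riu\n0.0,1.0\n")
        with pytest.raises(FormatError):
            load_ri_csv(p)

    def test_14min_10hz_grid(self, tmp_path):
        t, s = gaussian_trace([7.0], [1.0])
        p = tmp_path / "ri.csv"
        p.write_text("time_min,riu\n" + "\n".join(f"{a:.8g},{b:.8g}" for a, b in zip(t, s)))
        assert len(load_ri_csv(p)) == 14 * 60 * 10 + 1  # 8401 samples

    def test_jitter_rejected(self):
        t = np.array([0.0, 0.1, 0.25, 0.3])
        with pytest.raises(ValidationError):
            Chromatogram(t, np.zeros_like(t))


class TestBaseline:
    def test_constant_offset_removed(self):
        t = np.arange(0, 14.001, 0.1 / 60)
        c = correct_baseline(Chromatogram(t, np.full_like(t, 7.5)))
        assert np.abs(c.signal).max() < 1e-9

    def test_zero_trace_unchanged(self):
        t = np.arange(0, 14.001, 0.1 / 60)
        c = correct_baseline(Chromatogram(t, np.zeros_like(t)))
        assert np.abs(c.signal).max() < 1e-12

    def test_gaussian_on_offset_recovered(self):
        t, s = gaussian_trace([7.0], [5.0], sigma=0.05, offset=3.0)
        c = correct_baseline(Chromatogram(t, s), window=2.0)
        area = np.trapezoid(c.signal, c.time)
        assert area == pytest.approx(5.0, rel=0.01)

    def test_window_longer_than_trace(self):
        t = np.arange(0, 1.001, 0.1 / 60)
        with pytest.raises(ParameterError):
            correct_baseline(Chromatogram(t, np.zeros_like(t)), window=5.0)

    def test_offset_invariance_of_window_areas(self, window_map):
        lo, hi = window_map.window_for(4)
        t, s0 = gaussian_trace([(lo + hi) / 2], [2.0], sigma=0.02)
        a0 = integrate_windows(correct_baseline(Chromatogram(t, s0)), window_map)[4]
        a1 = integrate_windows(
            correct_baseline(Chromatogram(t, s0 + 40.0)), window_map
        )[4]
        assert a1 == pytest.approx(a0, rel=0.01)


class TestPeaks:
    def test_two_separated_gaussians(self):
        t, s = gaussian_trace([5.0, 9.0], [2.0, 3.0], sigma=0.05)
        peaks = detect_peaks(Chromatogram(t, s), min_height=0.1)
        assert len(peaks) == 2
        assert peaks[0].area == pytest.approx(2.0, rel=0.01)
        assert peaks[1].area == pytest.approx(3.0, rel=0.01)

    def test_flat_trace(self):
        t = np.arange(0, 14.001, 0.1 / 60)
        assert detect_peaks(Chromatogram(t, np.zeros_like(t))) == []

    def test_apex_location(self):
        t, s = gaussian_trace([6.283], [1.0], sigma=0.05)
        peaks = detect_peaks(Chromatogram(t, s), min_height=0.1)
        assert len(peaks) == 1
        assert abs(peaks[0].rt_apex - 6.283) <= 1.0 / 600 + 1e-12  # within one sample


class TestWindows:
    def test_overlapping_windows_rejected(self):
        with pytest.raises(ConfigurationError):
            DPWindowMap({3: (9.0, 9.6), 2: (9.5, 10.0)}, (2.0, 8.0))

    def test_sec_elution_order_enforced(self):
        with pytest.raises(ConfigurationError):
            DPWindowMap({2: (9.0, 9.4), 3: (9.5, 10.0)}, (2.0, 8.0))

    def test_csv_round_trip(self, window_map, tmp_path):
        p = tmp_path / "windows.csv"
        window_map.to_csv(p)
        back = DPWindowMap.from_csv(p)
        assert back.dps == window_map.dps
        assert back.polymer_region == pytest.approx(window_map.polymer_region)

    def test_gaussian_fully_inside_dp4_window(self, window_map):
        lo, hi = window_map.window_for(4)
        t, s = gaussian_trace([(lo + hi) / 2], [2.5], sigma=0.02)
        areas = integrate_windows(Chromatogram(t, s), window_map)
        assert areas[4] == pytest.approx(2.5, rel=0.01)
        assert areas[7] == pytest.approx(0.0, abs=1e-9)

    def test_equal_gaussians_in_dp3_and_dp5(self, window_map):
        c3 = sum(window_map.window_for(3)) / 2
        c5 = sum(window_map.window_for(5)) / 2
        t, s = gaussian_trace([c3, c5], [1.7, 1.7], sigma=0.02)
        areas = integrate_windows(Chromatogram(t, s), window_map)
        assert areas[3] == pytest.approx(areas[5], rel=0.01)

    def test_polymer_region_area(self, window_map):
        t, s = gaussian_trace([5.0], [4.0], sigma=0.05)
        assert integrate_polymer(Chromatogram(t, s), window_map) == pytest.approx(4.0, rel=0.01)

    def test_windows_from_ladder(self, window_map):
        centers = [sum(window_map.window_for(d)) / 2 for d in range(2, 11)]
        t, s = gaussian_trace(centers, [1.0] * len(centers), sigma=0.02)
        derived = windows_from_ladder(Chromatogram(t, s), dp_max=10, min_height=0.5)
        assert derived.dps == list(range(2, 11))
        for d in range(2, 11):
            lo, hi = derived.window_for(d)
            assert lo < sum(window_map.window_for(d)) / 2 < hi


class TestSplitFractions:
    def test_half_and_half(self):
        assert split_fractions({4: 0.5, 5: 0.5}, 1.0) == pytest.approx((0.5, 0.5))

    def test_polymer_only(self):
        assert split_fractions({4: 0.0}, 2.0) == pytest.approx((0.0, 1.0))

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedShareError):
            split_fractions({4: 0.0}, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            split_fractions({4: -1.0}, 2.0)

    @given(st.lists(st.floats(0, 1e3), min_size=1, max_size=9), st.floats(0, 1e3))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_shares_sum_to_one(self, areas, polymer):
        dp_areas = dict(enumerate(areas, start=2))
        if sum(areas) + polymer <= 0:
            with pytest.raises(UndefinedShareError):
                split_fractions(dp_areas, polymer)
        else:
            small, poly = split_fractions(dp_areas, polymer)
            assert small + poly == pytest.approx(1.0, abs=1e-12)
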