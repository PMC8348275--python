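"""Spectrum I/O and post-processing: despiking, Jacobian, stitching, peaks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jetraman import (
    Spectrum,
    concentration_scaling,
    despike,
    jacobian_correct,
    peak_height,
    read_spectrum,
    stitch_segments,
    write_spectrum,
)


def make_spectrum(lo=100.0, n=200, h=0.1, fn=None):
    x = lo + h * np.arange(n)
    y = fn(x) if fn else np.zeros(n)
    return Spectrum(x, y, {"source": "test"})


class TestIO:
    def test_header_and_points(self, tmp_path):
        p = tmp_path / "s.dat"
        p.write_text("# window: 3\n# free comment\n100.0 1.0\n100.1 2.0\n100.2 3.0\n")
        s = read_spectrum(p)
        assert s.wavenumber.size == 3
        assert s.metadata["window"] == "3"
        assert s.metadata["comments"] == ["free comment"]

    def test_parse_error_reports_line(self, tmp_path):
        p = tmp_path / "bad.dat"
        p.write_text("100.0 1.0\noops\n")
        with pytest.raises(ValueError, match="line 2"):
            read_spectrum(p)

    def test_unsorted_axis_sorted_with_warning(self, tmp_path):
        p = tmp_path / "u.dat"
        p.write_text("100.2 3.0\n100.0 1.0\n100.1 2.0\n")
        with pytest.warns(UserWarning, match="unsorted"):
            s = read_spectrum(p)
        assert np.all(np.diff(s.wavenumber) > 0)
        assert "warning" in s.metadata

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=25)
    def test_round_trip_full_precision(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        tmp = tmp_path_factory.mktemp("io")
        s = Spectrum(
            100.0 + 0.1 * np.arange(50),
            rng.normal(size=50),
            {"seed": repr(seed)},
        )
        path = tmp / "rt.dat"
        write_spectrum(s, path)
        back = read_spectrum(path)
        assert np.array_equal(back.wavenumber, s.wavenumber)
        assert np.array_equal(back.intensity, s.intensity)
        assert back.metadata["seed"] == repr(seed)


class TestDespike:
    def test_identical_scans_unchanged(self):
        a = np.arange(10.0)
        assert np.array_equal(despike([a, a, a]), a)

    def test_median_removes_single_spike(self):
        clean = np.ones(50)
        spiked = clean.copy()
        spiked[17] = 1e6
        out = despike([clean, spiked, clean])
        assert np.array_equal(out, clean)

    def test_two_scans_take_minimum(self):
        a, b = np.full(5, 2.0), np.full(5, 3.0)
        b[1] = 1.0
        out = despike([a, b])
        assert out.tolist() == [2.0, 1.0, 2.0, 2.0, 2.0]

    def test_single_scan_passthrough_warns(self):
        with pytest.warns(UserWarning):
            out = despike([np.arange(4.0)])
        assert out.tolist() == [0, 1, 2, 3]

    def test_random_spikes_removed(self):
        rng = np.random.default_rng(42)
        truth = rng.normal(10.0, 0.1, size=5000)
        scans = []
        for _ in range(3):
            s = truth.copy()
            hits = rng.random(truth.size) < 1e-3
            s[hits] += 1e5
            scans.append(s)
        out = despike(scans)
        assert np.mean(out == truth) >= 0.999


class TestJacobian:
    def test_linear_mapping_uniform_rescale(self):
        counts = np.array([1.0, 2.0, 3.0, 4.0])
        nu = np.array([100.0, 100.2, 100.4, 100.6])
        s = jacobian_correct(counts, nu)
        assert s.intensity == pytest.approx(counts / 0.2)

    def test_integral_preserved_quadratic_mapping(self):
        px = np.arange(400.0)
        nu = 500.0 + 0.5 * px + 2e-4 * px**2
        counts = np.exp(-((px - 200.0) ** 2) / 800.0)
        s = jacobian_correct(counts, nu)
        assert s.integral() == pytest.approx(counts.sum(), rel=1e-3)

    def test_constant_counts_inverse_widths(self):
        nu = np.array([0.0, 1.0, 3.0, 6.0])
        s = jacobian_correct(np.ones(4), nu)
        widths = np.gradient(nu)
        assert s.intensity == pytest.approx(1.0 / widths)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            jacobian_correct(np.ones(3), np.array([1.0, 3.0, 2.0]))


class TestStitch:
    def _segment(self, lo, n, scale=1.0):
        x = lo + 0.1 * np.arange(n)
        y = scale * (1.0 + np.exp(-((x - (lo + 0.05 * n)) ** 2)))
        return Spectrum(x, y)

    def test_identity_for_identical_segments(self):
        s = self._segment(100.0, 100)
        out = stitch_segments([s, s], anchors=[105.0])
        assert out.intensity == pytest.approx(s.intensity)

    def test_rescaled_segment_recovered(self):
        s1 = self._segment(100.0, 200)
        s2 = self._segment(110.0, 200, scale=2.0)
        out = stitch_segments([s1, s2], anchors=[115.0])
        # the doubled segment is scaled back to the first one's level
        i = np.argmin(np.abs(out.wavenumber - 125.0))
        ref = self._segment(110.0, 200)
        j = np.argmin(np.abs(ref.wavenumber - 125.0))
        assert out.intensity[i] == pytest.approx(ref.intensity[j], rel=1e-9)

    def test_chain_of_random_scales_equalises_anchors(self):
        rng = np.random.default_rng(1)
        base = [self._segment(100.0 + 8.0 * k, 120) for k in range(5)]
        scaled = [
            Spectrum(s.wavenumber, s.intensity * rng.uniform(0.2, 5.0)) for s in base
        ]
        anchors = [100.0 + 8.0 * k + 9.0 for k in range(4)]
        out = stitch_segments(scaled, anchors)
        ref = stitch_segments(base, anchors)
        assert out.intensity / out.intensity[0] == pytest.approx(
            ref.intensity / ref.intensity[0], rel=1e-9
        )

    def test_stitching_idempotent(self):
        s1 = self._segment(100.0, 200)
        s2 = self._segment(110.0, 200, scale=3.0)
        once = stitch_segments([s1, s2], anchors=[115.0])
        twice = stitch_segments([once], anchors=[])
        assert twice.intensity == pytest.approx(once.intensity)

    def test_missing_anchor_raises(self):
        s1 = self._segment(100.0, 100)
        s2 = self._segment(200.0, 100)
        with pytest.raises(ValueError, match="anchor"):
            stitch_segments([s1, s2], anchors=[150.0])


class TestPeakHeight:
    def test_gaussian_amplitude(self):
        s = make_spectrum(fn=lambda x: 3.0 * np.exp(-((x - 110.0) ** 2) / 2.0))
        h, pos, edge = peak_height(s, 110.0, 5.0)
        assert h == pytest.approx(3.0, rel=1e-6)
        assert pos == pytest.approx(110.0)
        assert not edge

    def test_tilted_baseline_subtracted(self):
        s = make_spectrum(
            fn=lambda x: 2.0 * np.exp(-((x - 110.0) ** 2) / 2.0) + 0.05 * (x - 100.0)
        )
        h, _, _ = peak_height(s, 110.0, 8.0, baseline="linear_endpoints")
        assert h == pytest.approx(2.0, rel=0.01)

    def test_peak_outside_window_flags_edge(self):
        s = make_spectrum(fn=lambda x: np.exp(-((x - 118.0) ** 2) / 2.0))
        _, _, edge = peak_height(s, 105.0, 3.0)
        assert edge

    def test_empty_window_rejected(self):
        s = make_spectrum()
        with pytest.raises(ValueError):
            peak_height(s, 50.0, 1.0)

    def test_low_window_validity_flag_warns(self):
        s = make_spectrum(fn=lambda x: np.exp(-((x - 105.0) ** 2) / 2.0))
        s.metadata["low_window_edge"] = 108.0
        with pytest.warns(UserWarning, match="poorly illuminated"):
            peak_height(s, 105.0, 3.0)


class TestConcentrationScaling:
    @pytest.mark.parametrize("power,expected", [(1.0, 1.0), (2.0, 2.0)])
    def test_exact_power_laws(self, power, expected):
        c = np.array([0.5, 1.0, 1.5, 2.0])
        slope, se = concentration_scaling(c**power, c)
        assert slope == pytest.approx(expected, abs=1e-12)

    def test_noisy_intermediate_exponent(self):
        rng = np.random.default_rng(6)
        c = np.array([0.5, 0.8, 1.0, 1.5, 2.0, 3.0])
        h = c**1.5 * np.exp(rng.normal(0.0, 0.05, size=6))
        slope, se = concentration_scaling(h, c)
        assert slope == pytest.approx(1.5, abs=0.2)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            concentration_scaling([1.0, 2.0], [1.0, 2.0])
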