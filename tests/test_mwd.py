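import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hasec import (
    HA_DIMER_MW,
    WATER_MW,
    SimulationSpec,
    detect_main_peak,
    differential_distribution,
    dispersity,
    dp_boundaries,
    dp_n,
    dp_w,
    integrate,
    number_average,
    peak_average_mw,
    simulate_chromatogram,
    theoretical_mw,
    weight_average,
)
from hasec.chromatogram import Chromatogram, Peak
from hasec.errors import (
    CalibrationDirectionError,
    ClippedAreaWarning,
    DomainError,
    EmptyDistributionError,
)


class TestTheoreticalMw:
    def test_monomer_and_kilomer(self):
        assert theoretical_mw(1) == pytest.approx(864.8)
        assert theoretical_mw(1000) == pytest.approx(846_818.0)

    def test_dp_below_one_rejected(self):
        with pytest.raises(DomainError):
            theoretical_mw(0)

    @given(k=st.integers(1, 100_000))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_dp_round_trip_exact(self, k):
        assert dp_n(theoretical_mw(k)) == pytest.approx(k, abs=1e-9)
        assert dp_w(theoretical_mw(k)) == pytest.approx(k, abs=1e-9)

    def test_dp_averages_reject_mass_below_water(self):
        with pytest.raises(DomainError):
            dp_n(WATER_MW)


class TestDpAveragesFromReportedMoments:
    """DP averages recomputed from measured number-average masses."""

    @pytest.mark.parametrize(
        "mn,expected",
        [(77_372.1, 91.3), (912_577.4, 1077.7), (980_633.7, 1158.0), (864.8, 1.0)],
    )
    def test_dp_n(self, mn, expected):
        assert round(dp_n(mn), 1) == pytest.approx(expected, abs=0.05)


class TestDispersity:
    @pytest.mark.parametrize(
        "mn,mw,expected",
        [(77_372.1, 90_938.5, 1.18), (980_633.7, 1_427_015.0, 1.46)],
    )
    def test_measured_sample_values(self, mn, mw, expected):
        assert dispersity(mn, mw) == pytest.approx(expected, abs=0.005)

    def test_monodisperse_unity(self):
        assert dispersity(5e5, 5e5) == 1.0

    def test_non_positive_mn_rejected(self):
        with pytest.raises(DomainError):
            dispersity(0.0, 1e5)


class TestDpBoundaries:
    def test_strictly_decreasing_with_dp(self, mw_fit, geom):
        edges = dp_boundaries(np.arange(1, 101), mw_fit, geom)
        assert edges.size == 101
        assert np.all(np.diff(edges) < 0)

    def test_adjacent_windows_share_exactly_one_edge(self, mw_fit, geom):
        grid = np.arange(1, 51)
        edges = dp_boundaries(grid, mw_fit, geom)
        windows = [(edges[i + 1], edges[i]) for i in range(len(grid))]
        for (lo1, hi1), (lo2, hi2) in zip(windows, windows[1:]):
            assert lo1 == hi2  # lower edge of fraction i is upper edge of i+1
        assert all(lo < hi for lo, hi in windows)

    def test_edges_match_simulator_law(self, make_spec, mw_fit):
        spec = make_spec()
        grid = np.arange(1, 1001)
        edges = dp_boundaries(grid, mw_fit, spec.geom)
        expected = spec.true_retention_time(theoretical_mw(np.arange(1, 1002)))
        assert np.allclose(edges, expected, atol=1e-9)

    def test_positive_slope_rejected(self, mw_fit, geom):
        from dataclasses import replace

        bad = replace(mw_fit, slope=0.1)
        with pytest.raises(CalibrationDirectionError):
            dp_boundaries(np.arange(1, 10), bad, geom)

    def test_monodisperse_apex_lands_on_its_dp_window(self, make_spec, mw_fit):
        # a zero-noise dp-mer elutes with apex at tR(dp) within one grid step
        dp = 500
        spec = make_spec(
            mixture=[(theoretical_mw(dp), 1.0)], noise_sd=0.0, drift=0.0,
            sampling_interval=0.002,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chrom, _ = simulate_chromatogram(spec)
        peak = detect_main_peak(chrom)
        assert peak.t_apex == pytest.approx(
            spec.true_retention_time(theoretical_mw(dp)), abs=0.002
        )


class TestDifferentialDistribution:
    def test_zero_signal_raises(self, mw_fit, geom):
        t = np.linspace(8, 19, 500)
        chrom = Chromatogram(t, np.zeros_like(t), {})
        with pytest.raises(EmptyDistributionError):
            differential_distribution(chrom, mw_fit, geom, np.arange(1, 100))

    def test_narrow_peak_confined_to_one_fraction(self, make_spec, mw_fit):
        # a pure dp-mer with tiny broadening: its fraction holds >= 99.9% of area
        dp = 100
        spec = make_spec(
            mixture=[(theoretical_mw(dp) + 0.5 * HA_DIMER_MW, 1.0)],
            noise_sd=0.0, drift=0.0, peak_sigma_min=0.0, sampling_interval=0.0005,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chrom, _ = simulate_chromatogram(spec)
        dist = differential_distribution(
            chrom, mw_fit, spec.geom, np.arange(dp - 50, dp + 50)
        )
        share = dist.n_i[dist.dp == dp].sum() / dist.total_area
        assert share >= 0.999

    def test_area_conservation_over_union_window(self, make_spec, mw_fit):
        spec = make_spec(noise_sd=0.0, drift=0.0, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chrom, _ = simulate_chromatogram(spec)
        dist = differential_distribution(chrom, mw_fit, spec.geom)
        lo = max(dist.t_bounds[-1], chrom.t_min)
        hi = min(dist.t_bounds[0], chrom.t_max)
        total = integrate(chrom, lo, hi)
        assert dist.total_area == pytest.approx(total, rel=1e-6)

    def test_negative_areas_clipped_and_counted(self, mw_fit, geom):
        rng = np.random.default_rng(5)
        t = np.linspace(8, 19, 2000)
        sig = np.exp(-0.5 * ((t - 12) / 0.3) ** 2) * 100 + rng.normal(0, 1, t.size)
        chrom = Chromatogram(t, sig, {})
        with pytest.warns(ClippedAreaWarning):
            dist = differential_distribution(chrom, mw_fit, geom)
        assert dist.n_clipped > 0
        assert np.all(dist.n_i >= 0)


class TestMoments:
    def test_hand_evaluated_two_fraction_mixture(self):
        n, m = np.array([1.0, 1.0]), np.array([100.0, 300.0])
        assert number_average((n, m)) == pytest.approx(200.0)
        assert weight_average((n, m)) == pytest.approx(250.0)

    def test_single_fraction_is_monodisperse(self):
        n = np.zeros(10)
        n[4] = 3.7
        m = np.linspace(1e3, 1e4, 10)
        assert number_average((n, m)) == weight_average((n, m)) == m[4]

    def test_brute_force_species_oracle(self):
        rng = np.random.default_rng(11)
        n = rng.uniform(0, 1, 50)
        m = rng.uniform(1e3, 1e6, 50)
        # independent oracle: explicit loops over species
        mn_oracle = sum(ni * mi for ni, mi in zip(n, m)) / sum(n)
        mw_oracle = sum(ni * mi * mi for ni, mi in zip(n, m)) / sum(
            ni * mi for ni, mi in zip(n, m)
        )
        assert number_average((n, m)) == pytest.approx(mn_oracle, rel=1e-9)
        assert weight_average((n, m)) == pytest.approx(mw_oracle, rel=1e-9)

    @given(k=st.floats(1e-6, 1e6), seed=st.integers(0, 2**16))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_scale_invariance(self, k, seed):
        rng = np.random.default_rng(seed)
        n = rng.uniform(0.01, 1, 20)
        m = rng.uniform(1e3, 1e6, 20)
        assert number_average((k * n, m)) == pytest.approx(
            number_average((n, m)), rel=1e-9
        )
        assert weight_average((k * n, m)) == pytest.approx(
            weight_average((n, m)), rel=1e-9
        )

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_dispersity_at_least_one(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.uniform(0, 1, 30)
        n[rng.integers(0, 30)] += 0.5  # ensure some area
        m = rng.uniform(1e3, 1e7, 30)
        mn = number_average((n, m))
        mw = weight_average((n, m))
        assert dispersity(mn, mw) >= 1.0 - 1e-12


class TestGridRefinement:
    def test_halving_spacing_changes_moments_below_0p1_percent(
        self, make_spec, mw_fit
    ):
        spec = make_spec(noise_sd=0.0, drift=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chrom, _ = simulate_chromatogram(spec)
        results = {}
        for step in (4, 2, 1):
            dist = differential_distribution(
                chrom, mw_fit, spec.geom, np.arange(1, 10_001, step)
            )
            results[step] = (number_average(dist), weight_average(dist))
        for coarse, fine in ((4, 2), (2, 1)):
            for a, b in zip(results[coarse], results[fine]):
                assert abs(a / b - 1) < 1e-3


class TestPeakAverageMw:
    def test_monodisperse_sample_returns_species_mass(self, make_spec, mw_fit):
        target = 9e5
        spec = make_spec(mixture=[(target, 1.0)], noise_sd=0.0, drift=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chrom, _ = simulate_chromatogram(spec)
            peak = detect_main_peak(chrom)
            assert peak_average_mw(peak, mw_fit, spec.geom) == pytest.approx(
                target, rel=1e-2
            )

    def test_ordering_mp_mn_mw_for_log_symmetric_peak(self, make_spec, mw_fit):
        # with areas as the abundances, the averages are mass-weighted, so by
        # Jensen's inequality a log-symmetric peak has Mp (mass median at the
        # apex) <= Mn <= Mw
        spec = make_spec(noise_sd=0.0, drift=0.0, sigma_ln_mw=0.407)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chrom, _ = simulate_chromatogram(spec)
            peak = detect_main_peak(chrom)
            dist = differential_distribution(
                chrom, mw_fit, spec.geom, window=(peak.t_start, peak.t_end)
            )
            mp = peak_average_mw(peak, mw_fit, spec.geom)
        assert mp <= number_average(dist) <= weight_average(dist)
        # and the apex stays within the distribution's bulk
        assert mp == pytest.approx(number_average(dist), rel=0.15)

    def test_apex_outside_column_window_rejected(self, mw_fit, geom):
        peak = Peak(t_start=1.0, t_apex=2.0, t_end=3.0, area=1.0, height=1.0)
        with pytest.raises(DomainError):
            peak_average_mw(peak, mw_fit, geom)
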