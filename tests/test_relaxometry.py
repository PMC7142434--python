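"""Discrete multi-exponential fits, regularized inversion, pools."""

import numpy as np
import pytest

from fishnmr.profiles import TREATMENT_PROFILES
from fishnmr.relaxometry import (
    DEFAULT_LAM_LADDER,
    Peak,
    T2Distribution,
    T2Grid,
    assign_water_pools,
    detect_and_integrate_peaks,
    fit_discrete_multiexp,
    invert_t2_distribution,
    pools_from_components,
)
from fishnmr.synthetic import DecayCurve, RelaxComponent, simulate_cpmg_decay

from conftest import profile_components


@pytest.fixture(scope="module")
def grid():
    return T2Grid.log_spaced()


class TestT2Grid:
    def test_default_grid_is_log_spaced_over_decay_range(self, grid):
        assert grid.n_points == 128
        assert grid.min_ms == pytest.approx(0.01)
        assert grid.max_ms == pytest.approx(10000.0)
        ratios = grid.values_ms[1:] / grid.values_ms[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)

    def test_non_log_spacing_rejected(self):
        with pytest.raises(ValueError):
            T2Grid(np.linspace(1.0, 100.0, 16))


class TestDiscreteFit:
    def test_single_component_recovered_exactly(self, acq):
        decay = simulate_cpmg_decay(
            [RelaxComponent(t2_ms=50.0, amplitude=2.0)], acq, noise_sd=0.0
        )
        comps, resid = fit_discrete_multiexp(decay, 1)
        assert comps[0].t2_ms == pytest.approx(50.0, abs=1e-6)
        assert comps[0].amplitude == pytest.approx(2.0, abs=1e-8)
        assert resid <= 1e-10

    def test_control_row_middle_and_slow_t2_recovered(self, control_decay):
        comps, _ = fit_discrete_multiexp(control_decay, 3)
        assert comps[1].t2_ms == pytest.approx(51.04, rel=0.005)
        assert comps[2].t2_ms == pytest.approx(429.96, rel=0.005)

    def test_frying_row_middle_and_slow_t2_recovered(self, frying_decay):
        comps, _ = fit_discrete_multiexp(frying_decay, 3)
        assert comps[1].t2_ms == pytest.approx(17.43, rel=0.005)
        assert comps[2].t2_ms == pytest.approx(142.94, rel=0.005)

    @pytest.mark.parametrize("name", sorted(TREATMENT_PROFILES))
    def test_all_rows_t2_and_area_recovered_within_one_percent(self, acq, name):
        profile = TREATMENT_PROFILES[name]
        decay = simulate_cpmg_decay(profile_components(profile), acq, noise_sd=0.0)
        comps, _ = fit_discrete_multiexp(decay, 3)
        for i in (1, 2):  # immobilized and free pools
            assert comps[i].t2_ms == pytest.approx(
                profile.pool_t2_means[i], rel=0.01
            )
            assert comps[i].amplitude == pytest.approx(
                profile.pool_area_means[i], rel=0.01
            )

    def test_components_sorted_and_bounded(self, control_decay):
        comps, _ = fit_discrete_multiexp(control_decay, 3)
        t2 = [c.t2_ms for c in comps]
        assert t2 == sorted(t2)
        assert all(0.01 <= v <= 10000 for v in t2)
        assert all(c.amplitude >= 0 for c in comps)

    def test_preconditions(self, control_decay):
        with pytest.raises(ValueError):
            fit_discrete_multiexp(control_decay, 0)
        short = DecayCurve(
            times_ms=np.arange(1.0, 9.0), signal=np.exp(-np.arange(1.0, 9.0) / 5)
        )
        with pytest.raises(ValueError):
            fit_discrete_multiexp(short, 3)


class TestInversion:
    def test_single_exponential_apex_and_area(self, acq, grid):
        decay = simulate_cpmg_decay(
            [RelaxComponent(t2_ms=100.0, amplitude=7.0)], acq, noise_sd=0.0
        )
        dist = invert_t2_distribution(decay, grid, lam="auto")
        apex = grid.values_ms[np.argmax(dist.amplitudes)]
        assert abs(np.log(apex / 100.0)) <= np.log(grid.step_ratio) + 1e-12
        assert dist.total_amplitude == pytest.approx(7.0, rel=0.01)

    def test_zero_signal_gives_zero_distribution(self, acq, grid):
        decay = DecayCurve(
            times_ms=acq.echo_times_ms, signal=np.zeros(acq.n_echoes)
        )
        dist = invert_t2_distribution(decay, grid)
        assert dist.total_amplitude == 0.0

    def test_nan_signal_rejected(self, acq, grid):
        signal = np.ones(acq.n_echoes)
        signal[100] = np.nan
        decay = DecayCurve(times_ms=acq.echo_times_ms, signal=signal)
        with pytest.raises(ValueError):
            invert_t2_distribution(decay, grid)

    def test_control_simulation_gives_three_peaks_in_pool_windows(
        self, control_decay, grid
    ):
        dist = invert_t2_distribution(control_decay, grid, lam="auto")
        peaks = detect_and_integrate_peaks(dist, min_area_frac=0.005)
        assert len(peaks) == 3
        windows = [(0.1, 10.0), (10.0, 200.0), (200.0, 1000.0)]
        for peak, (lo, hi) in zip(peaks, windows):
            assert lo <= peak.apex_t2_ms < hi

    def test_amplitudes_nonnegative_for_noisy_input(self, acq, grid, rng):
        comps = [
            RelaxComponent(t2_ms=2.0, amplitude=300.0),
            RelaxComponent(t2_ms=80.0, amplitude=5000.0),
        ]
        decay = simulate_cpmg_decay(comps, acq, noise_sd=100.0, seed=17)
        dist = invert_t2_distribution(decay, grid, lam="auto")
        assert np.all(dist.amplitudes >= 0)

    def test_regularization_monotonicity(self, acq, grid):
        comps = [
            RelaxComponent(t2_ms=5.0, amplitude=400.0),
            RelaxComponent(t2_ms=60.0, amplitude=6000.0),
        ]
        decay = simulate_cpmg_decay(comps, acq, noise_sd=20.0, seed=5)
        K = np.exp(-decay.times_ms[:, None] / grid.values_ms[None, :])
        lam_abs = DEFAULT_LAM_LADDER[::4] * np.linalg.norm(K, 2)
        residuals, seminorms = [], []
        from fishnmr.relaxometry import _second_difference

        L = _second_difference(grid.n_points)
        for lam in lam_abs:
            dist = invert_t2_distribution(decay, grid, lam=float(lam))
            residuals.append(dist.fit_residual_norm)
            seminorms.append(np.linalg.norm(L @ dist.amplitudes))
        assert np.all(np.diff(residuals) >= -1e-6 * residuals[0] - 1e-9)
        assert np.all(np.diff(seminorms) <= 1e-6 * seminorms[0] + 1e-9)

    def test_bad_lam_rejected(self, control_decay, grid):
        with pytest.raises(ValueError):
            invert_t2_distribution(control_decay, grid, lam=-1.0)
        with pytest.raises(ValueError):
            invert_t2_distribution(control_decay, grid, lam="corner")


def _log_gaussian_mixture(grid, masses, apexes_ms, sigma_decades=0.1):
    x = np.log10(grid.values_ms)
    total = np.zeros_like(x)
    parts = []
    for mass, apex in zip(masses, apexes_ms):
        bump = np.exp(-0.5 * ((x - np.log10(apex)) / sigma_decades) ** 2)
        bump *= mass / bump.sum()
        parts.append(bump)
        total = total + bump
    return total, parts


class TestPeakDetection:
    def test_unimodal_distribution_gives_single_peak_with_total_area(self, grid):
        amplitudes, _ = _log_gaussian_mixture(grid, [5.0], [30.0])
        dist = T2Distribution(
            grid=grid, amplitudes=amplitudes, lam=0.0, fit_residual_norm=0.0
        )
        peaks = detect_and_integrate_peaks(dist)
        assert len(peaks) == 1
        assert peaks[0].area == pytest.approx(dist.total_amplitude, rel=1e-12)

    def test_three_bump_mixture_areas_match_generating_masses(self, grid):
        masses = [1.0, 10.0, 0.2]
        amplitudes, parts = _log_gaussian_mixture(grid, masses, [1.0, 50.0, 400.0])
        dist = T2Distribution(
            grid=grid, amplitudes=amplitudes, lam=0.0, fit_residual_norm=0.0
        )
        peaks = detect_and_integrate_peaks(dist)
        assert len(peaks) == 3
        for peak, part in zip(peaks, parts):
            assert peak.area == pytest.approx(part.sum(), rel=0.02)

    def test_zero_distribution_gives_no_peaks(self, grid):
        dist = T2Distribution(
            grid=grid,
            amplitudes=np.zeros(grid.n_points),
            lam=0.0,
            fit_residual_norm=0.0,
        )
        assert detect_and_integrate_peaks(dist) == []

    def test_min_area_fraction_filters_small_peaks(self, grid):
        amplitudes, _ = _log_gaussian_mixture(grid, [0.02, 10.0], [1.0, 60.0])
        dist = T2Distribution(
            grid=grid, amplitudes=amplitudes, lam=0.0, fit_residual_norm=0.0
        )
        assert len(detect_and_integrate_peaks(dist, min_area_frac=0.01)) == 1

    def test_area_conservation_on_random_distributions(self, grid, rng):
        for _ in range(20):
            amplitudes = np.maximum(rng.normal(0, 1, grid.n_points), 0.0)
            dist = T2Distribution(
                grid=grid, amplitudes=amplitudes, lam=0.0, fit_residual_norm=0.0
            )
            peaks = detect_and_integrate_peaks(dist)
            total = sum(p.area for p in peaks)
            assert total == pytest.approx(amplitudes.sum(), rel=1e-9, abs=1e-12)


class TestPoolAssignment:
    def test_immobilized_water_apex_assigned_to_t22(self):
        peak = Peak(apex_t2_ms=51.04, left_ms=20.0, right_ms=150.0, area=10.0)
        pools = assign_water_pools([peak], mass_g=1.0)
        assert pools.t22_ms == pytest.approx(51.04)
        assert pools.a22 == pytest.approx(10.0)

    def test_free_water_apex_assigned_to_t23(self):
        peak = Peak(apex_t2_ms=429.96, left_ms=250.0, right_ms=900.0, area=3.0)
        pools = assign_water_pools([peak], mass_g=1.0)
        assert pools.t23_ms == pytest.approx(429.96)
        assert pools.a23 == pytest.approx(3.0)

    def test_bound_water_area_normalized_per_gram(self):
        peak = Peak(apex_t2_ms=5.0, left_ms=1.0, right_ms=9.0, area=8.0)
        pools = assign_water_pools([peak], mass_g=2.0)
        assert pools.t21_ms == pytest.approx(5.0)
        assert pools.a21 == pytest.approx(4.0)

    def test_two_peaks_in_one_window_merge_by_area_weight(self):
        peaks = [
            Peak(apex_t2_ms=30.0, left_ms=15.0, right_ms=45.0, area=1.0),
            Peak(apex_t2_ms=90.0, left_ms=60.0, right_ms=150.0, area=3.0),
        ]
        pools = assign_water_pools(peaks, mass_g=1.0, mode="windows")
        assert pools.a22 == pytest.approx(4.0)
        assert pools.t22_ms == pytest.approx((30 * 1 + 90 * 3) / 4)

    def test_out_of_window_peak_reported_separately(self):
        peaks = [
            Peak(apex_t2_ms=51.0, left_ms=20.0, right_ms=150.0, area=10.0),
            Peak(apex_t2_ms=5000.0, left_ms=2000.0, right_ms=9000.0, area=1.0),
        ]
        pools = assign_water_pools(peaks, mass_g=2.0)
        assert len(pools.unassigned) == 1
        assert pools.unassigned[0].area == pytest.approx(0.5)

    def test_blue_shifted_free_pool_resolved_ordinally(self):
        """Strongly cooked tissue: both T22 and the blue-shifted T23 sit in
        the nominal immobilized window; ranking keeps three pools."""
        peaks = [
            Peak(apex_t2_ms=1.44, left_ms=0.5, right_ms=4.0, area=470.28),
            Peak(apex_t2_ms=17.43, left_ms=8.0, right_ms=60.0, area=1707.53),
            Peak(apex_t2_ms=142.94, left_ms=80.0, right_ms=400.0, area=1113.33),
        ]
        pools = assign_water_pools(peaks, mass_g=1.0)
        assert pools.t22_ms == pytest.approx(17.43)
        assert pools.a22 == pytest.approx(1707.53)
        assert pools.t23_ms == pytest.approx(142.94)
        assert pools.a23 == pytest.approx(1113.33)

    def test_area_conservation_including_unassigned(self, rng):
        for _ in range(20):
            peaks = []
            for _ in range(rng.integers(1, 6)):
                apex = float(10 ** rng.uniform(-2.5, 4.0))
                peaks.append(
                    Peak(
                        apex_t2_ms=apex,
                        left_ms=apex,
                        right_ms=apex,
                        area=float(rng.uniform(0, 10)),
                    )
                )
            mass = float(rng.uniform(0.5, 10))
            pools = assign_water_pools(peaks, mass_g=mass, mode="windows")
            total = (pools.a21 + pools.a22 + pools.a23) * mass + sum(
                p.area for p in pools.unassigned
            ) * mass
            assert total == pytest.approx(sum(p.area for p in peaks), rel=1e-9)

    def test_close_discrete_components_merged_before_assignment(self):
        comps = [
            RelaxComponent(t2_ms=50.0, amplitude=2.0),
            RelaxComponent(t2_ms=52.0, amplitude=4.0),
            RelaxComponent(t2_ms=400.0, amplitude=1.0),
        ]
        pools = pools_from_components(comps, mass_g=1.0)
        assert pools.a22 == pytest.approx(6.0)
        assert pools.t22_ms == pytest.approx((50 * 2 + 52 * 4) / 6)
        assert pools.a23 == pytest.approx(1.0)


class TestInversionPoolRecovery:
    @pytest.mark.parametrize("name", ["control", "frying"])
    def test_immobilized_area_recovered_within_two_percent(self, acq, name):
        profile = TREATMENT_PROFILES[name]
        decay = simulate_cpmg_decay(profile_components(profile), acq, noise_sd=0.0)
        dist = invert_t2_distribution(decay, T2Grid.log_spaced(), lam="auto")
        peaks = detect_and_integrate_peaks(dist, min_area_frac=0.005)
        pools = assign_water_pools(peaks, mass_g=1.0)
        assert pools.a22 == pytest.approx(profile.pool_area_means[1], rel=0.02)
        assert pools.a23 == pytest.approx(profile.pool_area_means[2], rel=0.05)
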