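"""Zwanzig estimator, error model, λ schedules, cycle and Kd conversion."""

import numpy as np
import pytest

from pepmd import (
    CycleSpec,
    FepSyntheticSpec,
    FepWindow,
    KB_KCAL_PER_MOL_K,
    accumulate,
    combine_windows,
    cycle_ddg,
    ddg_from_kd,
    generate_fep_samples,
    lambda_schedule,
    statistical_inefficiency,
    window_error,
    zwanzig_window_dg,
)
from pepmd.errors import ConfigError, ContractError, DataError, ScheduleError

KT300 = KB_KCAL_PER_MOL_K * 300.0


def _win(du, temperature=300.0, **kw):
    return FepWindow(0.0, 1.0, np.asarray(du, float), temperature, **kw)


class TestZwanzig:
    def test_zero_differences_give_zero(self):
        assert zwanzig_window_dg(_win(np.zeros(100))) == 0.0

    def test_constant_differences_are_exact(self):
        assert np.isclose(zwanzig_window_dg(_win(np.full(50, 2.75))), 2.75, atol=1e-12)

    def test_gaussian_matches_closed_form_within_3se(self):
        rng = np.random.default_rng(100)
        win = _win(rng.normal(1.0, 0.5, 10**6))
        dg = zwanzig_window_dg(win)
        sigma = window_error(win)
        truth = 1.0 - 0.25 / (2 * KT300)
        assert abs(dg - truth) <= 3 * sigma

    def test_overflow_safe_for_huge_energies(self):
        dg = zwanzig_window_dg(_win([5000.0, 5000.0, 5000.0]))
        assert np.isclose(dg, 5000.0)
        dg = zwanzig_window_dg(_win([-5000.0, -4000.0]))
        assert np.isfinite(dg)

    def test_equilibration_prefix_discarded(self):
        du = np.concatenate([np.full(10, 99.0), np.full(90, 1.0)])
        assert np.isclose(zwanzig_window_dg(_win(du, discard=10)), 1.0)

    def test_empty_series_rejected(self):
        with pytest.raises(DataError):
            _win(np.array([]))


class TestStatisticalInefficiency:
    def test_white_noise_ratio_near_one(self):
        x = np.random.default_rng(0).standard_normal(10**5)
        est = statistical_inefficiency(x)
        assert 0.9 <= est.sampling_ratio <= 1.2

    def test_ar1_ratio_matches_closed_form(self):
        phi = 0.5
        spec = FepSyntheticSpec(mu=[0.0], sigma=[1.0], ar1_phi=phi, n_samples=10**5, seed=1)
        (win,), _ = generate_fep_samples(spec)
        est = statistical_inefficiency(win.delta_u)
        assert abs(est.sampling_ratio - 3.0) / 3.0 <= 0.10  # (1+phi)/(1-phi) = 3
        assert est.effective_n <= win.delta_u.size

    def test_constant_series_is_degenerate(self):
        est = statistical_inefficiency(np.full(100, 1.5))
        assert est.degenerate
        assert est.sampling_ratio == 1.0

    def test_short_series_rejected(self):
        with pytest.raises(DataError):
            statistical_inefficiency(np.ones(10))


class TestWindowError:
    def test_constant_series_has_zero_error(self):
        assert window_error(_win(np.full(100, 3.0))) == 0.0

    def test_error_calibrated_against_replicates(self):
        # empirical SD of the estimator over 200 seeds vs mean reported sigma
        rng = np.random.default_rng(7)
        dgs, sigmas = [], []
        for _ in range(200):
            win = _win(rng.normal(0.8, 0.5, 1500))
            dgs.append(zwanzig_window_dg(win))
            sigmas.append(window_error(win))
        assert abs(np.std(dgs) - np.mean(sigmas)) / np.std(dgs) < 0.20

    def test_error_shrinks_by_sqrt2_when_n_doubles(self):
        rng = np.random.default_rng(8)
        s1 = window_error(_win(rng.normal(1.0, 0.5, 40000)))
        s2 = window_error(_win(rng.normal(1.0, 0.5, 80000)))
        assert abs(s1 / s2 - np.sqrt(2)) < 0.15

    def test_autocorrelation_inflates_error_on_matched_seeds(self):
        seed = 99
        iid = generate_fep_samples(
            FepSyntheticSpec(mu=[1.0], sigma=[0.5], ar1_phi=0.0, n_samples=20000, seed=seed)
        )[0][0]
        corr = generate_fep_samples(
            FepSyntheticSpec(mu=[1.0], sigma=[0.5], ar1_phi=0.8, n_samples=20000, seed=seed)
        )[0][0]
        assert window_error(corr) > window_error(iid)


class TestAccumulate:
    def test_totals_are_pythagorean(self):
        result = combine_windows([1.0, 2.0], [0.3, 0.4])
        assert np.isclose(result.total_dg, 3.0)
        assert np.isclose(result.total_sigma, 0.5)

    def test_single_window_spanning_unit_interval(self):
        win = _win(np.random.default_rng(0).normal(0.5, 0.2, 500))
        result = accumulate([win])
        assert result.n_windows == 1
        assert np.isclose(result.total_dg, zwanzig_window_dg(win))

    def test_gap_in_tiling_names_breakpoint(self):
        w1 = FepWindow(0.0, 0.4, np.ones(10))
        w2 = FepWindow(0.5, 1.0, np.ones(10))
        with pytest.raises(ScheduleError, match="0.4"):
            accumulate([w1, w2])

    def test_synthetic_schedule_recovers_ground_truth(self):
        rng = np.random.default_rng(13)
        spec = FepSyntheticSpec(
            mu=rng.normal(0.3, 0.5, 20), sigma=np.abs(rng.normal(0.4, 0.1, 20)),
            ar1_phi=0.3, n_samples=4000, seed=13,
        )
        windows, truth = generate_fep_samples(spec)
        result = accumulate(windows)
        assert abs(result.total_dg - truth) <= 3 * result.total_sigma

    def test_sample_splitting_consistency(self):
        # the two half-series estimates of one window agree with the full
        # estimate within the combined statistical error
        rng = np.random.default_rng(21)
        du = rng.normal(1.0, 0.5, 20000)
        full = _win(du)
        h1, h2 = _win(du[:10000]), _win(du[10000:])
        dg_full = zwanzig_window_dg(full)
        dg_halves = 0.5 * (zwanzig_window_dg(h1) + zwanzig_window_dg(h2))
        combined = np.sqrt(window_error(h1) ** 2 + window_error(h2) ** 2) / 2
        assert abs(dg_full - dg_halves) <= 3 * (combined + window_error(full))

    def test_temperature_mismatch_rejected(self):
        w1 = FepWindow(0.0, 0.5, np.ones(10), 300.0)
        w2 = FepWindow(0.5, 1.0, np.ones(10), 310.0)
        with pytest.raises(ContractError):
            accumulate([w1, w2])


class TestLambdaSchedule:
    def test_uniform_grid_for_density_one(self):
        assert np.allclose(lambda_schedule(4, 1.0), [0.0, 0.25, 0.5, 0.75, 1.0])

    @pytest.mark.parametrize("n,density", [(5, 2.0), (12, 3.0), (69, 2.0), (118, 2.0)])
    def test_endpoint_windows_narrower_than_middle(self, n, density):
        breaks = lambda_schedule(n, density)
        assert breaks[0] == 0.0 and breaks[-1] == 1.0
        assert np.all(np.diff(breaks) > 0)
        widths = np.diff(breaks)
        mid = widths[len(widths) // 2]
        assert widths[0] < mid and widths[-1] < mid

    @pytest.mark.parametrize("n", [69, 118])
    def test_published_window_counts_tile_and_accumulate(self, n):
        breaks = lambda_schedule(n, 2.0)
        windows = [
            FepWindow(float(a), float(b), np.full(5, 0.1))
            for a, b in zip(breaks[:-1], breaks[1:])
        ]
        result = accumulate(windows)
        assert result.n_windows == n
        assert np.isclose(result.total_dg, 0.1 * n)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigError):
            lambda_schedule(0)
        with pytest.raises(ConfigError):
            lambda_schedule(5, 0.5)


class TestCycle:
    def test_equal_legs_cancel(self):
        leg = combine_windows([2.0], [0.5])
        ddg, sigma = cycle_ddg(CycleSpec(leg, leg))
        assert ddg == 0.0
        assert np.isclose(sigma, np.sqrt(0.5))

    def test_combination_rule(self):
        bound = combine_windows([10.0], [2.0])
        free = combine_windows([1.4], [6.4])
        ddg, sigma = cycle_ddg(CycleSpec(bound, free))
        assert np.isclose(ddg, 8.6)
        assert np.isclose(round(sigma, 1), 6.7)

    def test_synthetic_two_leg_recovery(self):
        rng = np.random.default_rng(31)
        specs = {}
        for name, seed in (("bound", 31), ("free", 32)):
            specs[name] = FepSyntheticSpec(
                mu=rng.normal(0.5, 0.4, 12), sigma=np.abs(rng.normal(0.3, 0.05, 12)),
                ar1_phi=0.2, n_samples=3000, seed=seed,
            )
        results = {}
        truths = {}
        for name, spec in specs.items():
            windows, truth = generate_fep_samples(spec)
            results[name] = accumulate(windows)
            truths[name] = truth
        ddg, sigma = cycle_ddg(CycleSpec(results["bound"], results["free"]))
        assert abs(ddg - (truths["bound"] - truths["free"])) <= 3 * sigma

    def test_temperature_mismatch_is_contract_error(self):
        with pytest.raises(ContractError):
            CycleSpec(combine_windows([1.0], [0.1], 300.0),
                      combine_windows([1.0], [0.1], 310.0))


class TestKdConversion:
    def test_equal_kds_give_zero(self):
        assert ddg_from_kd(1e-6, 1e-6, 300.0) == 0.0

    def test_published_kd_pair_rounds_to_157(self):
        assert round(ddg_from_kd(7.2e-6, 100e-6, 300.0), 2) == 1.57

    def test_ln_e_identity(self):
        t = 0.6 / KB_KCAL_PER_MOL_K  # temperature at which RT = 0.6 kcal/mol
        assert np.isclose(ddg_from_kd(1e-6, np.e * 1e-6, t), 0.6, atol=1e-12)

    def test_non_positive_kd_rejected(self):
        with pytest.raises(DataError):
            ddg_from_kd(0.0, 1e-6, 300.0)
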