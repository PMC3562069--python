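"""Monte Carlo population simulation and readout conversion."""

import numpy as np
import pytest

from apopsynergy.network import Trajectory, default_grid, integrate
from apopsynergy.population import (PopulationSpec, death_time,
                                    run_population,
                                    sample_initial_conditions,
                                    to_fold_change, viability)


class TestSampling:
    def test_row_count_matches_spec(self, combo_variant):
        table = sample_initial_conditions(combo_variant.network,
                                          PopulationSpec(500, 0.4, seed=0))
        assert len(table) == 500

    def test_cv_zero_reproduces_network_state(self, combo_variant):
        table = sample_initial_conditions(combo_variant.network,
                                          PopulationSpec(10, 0.0, seed=0))
        for sp in combo_variant.network.species.values():
            assert (table[sp.name] == sp.initial_amount).all()

    def test_empirical_moments_match_target(self, combo_variant):
        spec = PopulationSpec(10_000, 0.4, seed=42)
        table = sample_initial_conditions(combo_variant.network, spec)
        mean = combo_variant.network.species["pC8"].initial_amount
        draws = table["pC8"]
        se = 0.4 * mean / np.sqrt(len(draws))
        # CV 0.4 truncation bias at zero is ~0.1% of the mean; allow it
        assert abs(draws.mean() - mean) < 3 * se + 0.005 * mean
        assert draws.std() / draws.mean() == pytest.approx(0.4, rel=0.05)
        assert (draws >= 0).all()

    def test_seed_reproducibility(self, combo_variant):
        spec = PopulationSpec(50, 0.4, seed=7)
        a = sample_initial_conditions(combo_variant.network, spec)
        b = sample_initial_conditions(combo_variant.network, spec)
        assert a.equals(b)

    def test_extreme_cv_warns(self, combo_variant):
        with pytest.warns(UserWarning, match="truncation"):
            sample_initial_conditions(combo_variant.network,
                                      PopulationSpec(5, 1.2, seed=0))

    def test_unknown_varied_species_rejected(self, combo_variant):
        with pytest.raises(ValueError, match="not in network"):
            sample_initial_conditions(
                combo_variant.network,
                PopulationSpec(5, 0.4, seed=0, varied_species=("Ghost",)))


def make_parp_trajectory(times, cleaved_fraction):
    times = np.asarray(times, dtype=float)
    frac = np.asarray(cleaved_fraction, dtype=float)
    total = 100.0
    values = np.vstack([total * (1 - frac), total * frac])
    return Trajectory(times, values, ["PARP", "cPARP"])


class TestDeathTime:
    def test_linear_interpolation_between_grid_points(self):
        traj = make_parp_trajectory([0, 6, 8], [0.0, 0.4, 0.6])
        assert death_time(traj) == pytest.approx(7.0)

    def test_exactly_half_at_grid_point_counts_as_dead(self):
        traj = make_parp_trajectory([0, 2, 4], [0.0, 0.5, 0.9])
        assert death_time(traj) == pytest.approx(2.0)

    def test_capped_below_threshold_returns_none(self):
        traj = make_parp_trajectory([0, 10, 24], [0.0, 0.3, 0.49])
        assert death_time(traj) is None

    def test_zero_parp_pool_raises(self):
        traj = Trajectory(np.array([0.0, 1.0]), np.zeros((2, 2)),
                          ["PARP", "cPARP"])
        with pytest.raises(ValueError, match="PARP"):
            death_time(traj)


class TestRunPopulation:
    def test_identical_seed_reproduces_result(self, combo_variant):
        spec = PopulationSpec(12, 0.4, seed=3)
        grid = default_grid(24.0, step=0.2)
        a = run_population(combo_variant, spec, grid)
        b = run_population(combo_variant, spec, grid)
        np.testing.assert_array_equal(a.death_times, b.death_times)
        np.testing.assert_array_equal(a.averaged, b.averaged)

    def test_cv_zero_cells_die_together(self, combo_variant):
        res = run_population(combo_variant,
                             PopulationSpec(4, 0.0, seed=0,
                                            flagged_fraction=0.0),
                             default_grid(24.0))
        assert np.isfinite(res.death_times).all()
        assert np.ptp(res.death_times) < 1e-9

    def test_untreated_population_survives(self):
        from apopsynergy.models import build_variant
        res = run_population(build_variant("untreated"),
                             PopulationSpec(10, 0.4, seed=2),
                             default_grid(24.0))
        assert res.death_fraction_at(24.0) == 0.0

    def test_death_fraction_curve_monotone_in_unit_interval(
            self, combo_variant, small_spec):
        res = run_population(combo_variant, small_spec, default_grid(24.0))
        assert (np.diff(res.death_fraction) >= 0).all()
        assert res.death_fraction.min() >= 0
        assert res.death_fraction.max() <= 1

    def test_population_average_blurs_single_cell_switch(self, combo_variant):
        """Individual dying cells switch much more sharply than the
        population mean (variable death-time delays smear the average)."""
        spec = PopulationSpec(20, 0.4, seed=9)
        grid = default_grid(24.0)
        res = run_population(combo_variant, spec, grid)
        avg_slope = np.max(np.gradient(
            res.averaged[res.species.index("C3a")], grid))
        table = sample_initial_conditions(combo_variant.network, spec)
        cell = integrate(combo_variant.network, combo_variant.events, grid,
                         initial_state=table.iloc[0][
                             combo_variant.network.species_names].to_numpy())
        cell_slope = np.max(np.gradient(cell.get("C3a"), grid))
        assert death_time(cell) is not None
        assert cell_slope > avg_slope


def test_death_fraction_stable_under_population_scaling(combo_variant):
    """Summary statistics at different Monte Carlo sizes agree within
    three standard errors."""
    grid = default_grid(24.0)
    fractions, ns = [], [100, 400]
    for n in ns:
        res = run_population(combo_variant, PopulationSpec(n, 0.4, seed=13),
                             grid)
        fractions.append(res.death_fraction_at(24.0))
    se = sum(np.sqrt(max(f * (1 - f), 0.01) / n)
             for f, n in zip(fractions, ns))
    assert abs(fractions[0] - fractions[1]) <= 3 * se


class TestViability:
    @pytest.mark.parametrize("deaths,expected", [
        (np.array([1.0, 2.0]), 0.0),
        (np.array([np.nan, np.nan]), 1.0),
    ])
    def test_limits(self, combo_variant, deaths, expected):
        from apopsynergy.population import PopulationResult
        grid = default_grid(24.0)
        curve = np.array([np.mean(deaths[~np.isnan(deaths)] <= t)
                          if np.any(~np.isnan(deaths)) else 0.0
                          for t in grid])
        res = PopulationResult("x", grid, deaths, np.zeros((1, len(grid))),
                               ["PARP"], curve)
        assert viability(res) == expected
        assert viability(res) == 1.0 - res.death_fraction_at(24.0)


class TestFoldChange:
    def make_result(self, c8, c3):
        from apopsynergy.population import PopulationResult
        times = np.arange(len(c8), dtype=float)
        avg = np.vstack([c8, c3])
        return PopulationResult("x", times, np.array([np.nan]), avg,
                                ["C8a", "C3a"],
                                np.zeros(len(times)))

    def test_baseline_is_exactly_one(self, combo_variant, small_spec):
        res = run_population(combo_variant, small_spec, default_grid(4.0))
        fc = to_fold_change(res, "caspase8_like")
        assert fc.fold_change[0] == 1.0

    def test_constant_signal_gives_constant_one(self):
        res = self.make_result([5.0, 5.0, 5.0], [1.0, 1.0, 1.0])
        fc = to_fold_change(res, "caspase8_like")
        assert fc.fold_change == pytest.approx([1.0, 1.0, 1.0])

    def test_doubling_all_inputs_gives_two(self):
        res = self.make_result([5.0, 10.0], [1.0, 2.0])
        fc = to_fold_change(res, "caspase8_like", background=0.5)
        # signal = 1*C8a + 0.3*C3a + 0.5 doubles except for background
        expected = (10.0 + 0.6 + 0.5) / (5.0 + 0.3 + 0.5)
        assert fc.fold_change[1] == pytest.approx(expected)

    def test_hand_computed_crosstalk_ratio(self):
        res = self.make_result([2.0, 8.0], [10.0, 40.0])
        fc = to_fold_change(res, "caspase8_like",
                            weights={"C8a": 1.0, "C3a": 0.3}, background=1.0)
        assert fc.fold_change[1] == pytest.approx((8 + 12 + 1) / (2 + 3 + 1))

    def test_zero_background_rejected(self):
        res = self.make_result([0.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="background"):
            to_fold_change(res, "caspase8_like", background=0.0)

    def test_negative_weights_rejected(self):
        res = self.make_result([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="non-negative"):
            to_fold_change(res, "caspase8_like", weights={"C8a": -1.0})
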