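"""Generator contracts: determinism, engineered correlations, ground truth."""

import datetime as dt
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from seabirdniche.grids import study_grid
from seabirdniche.synthetic import (
    ARCHETYPES,
    COLONY,
    IsotopeGenParams,
    IsotopeGroupParams,
    WarmTongueRegime,
    default_regime,
    generate_env_fields,
    simulate_isotopes,
    simulate_tracks,
    year_dates,
)


def _var(fields, name):
    return [f for f in fields if f.variable == name]


class TestEnvFields:
    def test_three_coregistered_fields_per_day(self, env_fields, dates):
        assert len(env_fields) == 3 * len(dates)
        for name in ("sst", "eac_prob", "sst_sd"):
            assert len(_var(env_fields, name)) == len(dates)

    def test_probabilities_bounded(self, env_fields):
        for f in _var(env_fields, "eac_prob"):
            assert f.values.min() >= 0.0 and f.values.max() <= 1.0

    def test_no_tongue_no_eac_water(self, grid, dates):
        regime = WarmTongueRegime(tongue_amplitude=0.0, baseline_prob=0.0)
        fields = generate_env_fields(grid, dates, regime, seed=1)
        for f in _var(fields, "eac_prob"):
            assert (f.values < 0.5).all()

    def test_saturated_tongue_full_dominance(self, grid, dates):
        regime = WarmTongueRegime(baseline_prob=1.0)
        fields = generate_env_fields(grid, dates, regime, seed=1)
        for f in _var(fields, "eac_prob"):
            assert (f.values > 0.5).all()

    def test_determinism_under_seed(self, grid, dates):
        a = generate_env_fields(grid, dates, default_regime("2014"), seed=9)
        b = generate_env_fields(grid, dates, default_regime("2014"), seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.values, fb.values)

    @pytest.mark.parametrize("year", ["2012", "2013", "2014"])
    def test_engineered_correlation_structure(self, grid, year):
        """SST drives EAC probability; EAC water is thermally uniform."""
        fields = generate_env_fields(grid, year_dates(year, 30), default_regime(year), seed=3)
        sst = np.concatenate([f.values.ravel() for f in _var(fields, "sst")])
        eac = np.concatenate([f.values.ravel() for f in _var(fields, "eac_prob")])
        ssd = np.concatenate([f.values.ravel() for f in _var(fields, "sst_sd")])
        assert np.corrcoef(sst, eac)[0, 1] >= 0.8
        assert np.corrcoef(eac, ssd)[0, 1] <= 0.0

    def test_empty_dates_rejected(self, grid):
        with pytest.raises(ValueError):
            generate_env_fields(grid, [], WarmTongueRegime(), seed=0)

    def test_nonpositive_noise_rejected(self, grid, dates):
        with pytest.raises(ValueError):
            generate_env_fields(grid, dates, WarmTongueRegime(noise_sd=0.0), seed=0)


class TestTrackSimulation:
    def test_zero_step_scale_stays_at_colony(self, env_fields):
        arch = replace(ARCHETYPES["little_penguin"], step_scale_km=0.0)
        trk = simulate_tracks(arch, COLONY, env_fields, n_birds=2, seed=0)
        assert (trk["lon"] == COLONY[0]).all()
        assert (trk["lat"] == COLONY[1]).all()

    def test_fix_count_six_active_hours(self, env_fields, dates):
        trk = simulate_tracks(
            ARCHETYPES["crested_tern"], COLONY, env_fields, n_birds=1,
            fix_interval_s=240, days=dates[:1], active_hours=6.0, seed=0,
        )
        # floor(6 h * 3600 / 240 s) + 1
        assert len(trk) == 91

    def test_fixes_inside_grid(self, tern_tracks, grid):
        assert grid.contains(tern_tracks["lon"], tern_tracks["lat"]).all()

    def test_daily_central_place_return(self, tern_tracks):
        last = tern_tracks.groupby(
            ["bird_id", tern_tracks["timestamp"].dt.date]
        ).tail(1)
        assert (last["lon"] == COLONY[0]).all()
        assert (last["lat"] == COLONY[1]).all()

    def test_strong_eac_avoidance_lowers_visited_probability(self, grid, env_fields):
        """Oracle: recompute visited-cell and all-cell means from the output."""
        arch = replace(
            ARCHETYPES["crested_tern"], eac_avoidance_slope=30.0,
            eac_avoidance_threshold=0.2, sstsd_avoidance_slope=0.0,
        )
        trk = simulate_tracks(arch, COLONY, env_fields, n_birds=8, seed=11)
        eac_by_day = {f.date: f for f in env_fields if f.variable == "eac_prob"}
        visited = np.concatenate(
            [
                eac_by_day[d].value_at(g["lon"], g["lat"])
                for d, g in trk.groupby(trk["timestamp"].dt.date)
            ]
        )
        overall = np.concatenate(
            [f.values.ravel() for f in env_fields if f.variable == "eac_prob"]
        )
        assert np.nanmean(visited) < overall.mean()

    def test_determinism_under_seed(self, env_fields):
        a = simulate_tracks(ARCHETYPES["silver_gull"], COLONY, env_fields, n_birds=3, seed=5)
        b = simulate_tracks(ARCHETYPES["silver_gull"], COLONY, env_fields, n_birds=3, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_inputs_rejected(self, env_fields):
        with pytest.raises(ValueError):
            simulate_tracks(ARCHETYPES["silver_gull"], COLONY, env_fields, n_birds=0, seed=0)
        with pytest.raises(ValueError):
            simulate_tracks(
                ARCHETYPES["silver_gull"], (120.0, -36.2), env_fields, n_birds=1, seed=0
            )


class TestIsotopeSimulation:
    def test_large_sample_recovers_parameters(self):
        params = IsotopeGenParams(
            groups=(
                IsotopeGroupParams(
                    species="a", year="2012", mean=(-17.0, 15.0),
                    cov=((0.01, 0.0), (0.0, 0.01)), n=10_000,
                ),
            )
        )
        df = simulate_isotopes(params, seed=13)
        xy = df[["d13C", "d15N"]].to_numpy()
        cov = np.cov(xy, rowvar=False)
        np.testing.assert_allclose(cov, 0.01 * np.eye(2), atol=0.0005)  # 5% of 0.01
        se = np.sqrt(0.01 / 10_000)
        assert abs(xy[:, 0].mean() - (-17.0)) < 3 * se
        assert abs(xy[:, 1].mean() - 15.0) < 3 * se

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            IsotopeGroupParams(
                species="a", year="2012", mean=(0, 0), cov=((1, 0), (0, 1)), n=2
            )

    def test_nonpositive_definite_covariance_rejected(self):
        with pytest.raises(ValueError):
            IsotopeGroupParams(
                species="a", year="2012", mean=(0, 0), cov=((1.0, 2.0), (2.0, 1.0)), n=5
            )

    def test_determinism_under_seed(self):
        params = IsotopeGenParams(
            groups=(
                IsotopeGroupParams(
                    species="a", year="2012", mean=(0, 0), cov=((1, 0), (0, 1)), n=5
                ),
            )
        )
        a = simulate_isotopes(params, seed=3)
        b = simulate_isotopes(params, seed=3)
        pd.testing.assert_frame_equal(a, b)
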