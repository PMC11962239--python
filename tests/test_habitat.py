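"""Use-availability construction, environmental proxies and mixed models."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from seabirdniche.fields import EnvField
from seabirdniche.grids import GridSpec
from seabirdniche.habitat import (
    compare_years,
    daily_sst_sd,
    eac_dominance,
    fit_area_model,
    fit_occurrence_model,
    mask_presence_absence,
    sst_sd_from_sst,
)
from seabirdniche.ud import KUDContour, kud_area


def _field(grid, var, values, day=dt.date(2013, 10, 1)):
    return EnvField(date=day, variable=var, grid=grid, values=values)


def _contour(grid, mask):
    return KUDContour(
        level=0.95, cells=mask, grid=grid, contained_mass=0.95,
        area_km2=kud_area(mask, grid),
    )


class TestMaskPresenceAbsence:
    def test_record_count_equals_grid_cells(self, grid, rng):
        mask = rng.random(grid.shape) > 0.6
        eac = _field(grid, "eac_prob", rng.random(grid.shape))
        ssd = _field(grid, "sst_sd", rng.random(grid.shape))
        cells = mask_presence_absence(_contour(grid, mask), (eac, ssd), 5, "tern")
        assert len(cells) == grid.n_cells
        assert cells["presence"].sum() == mask.sum()

    def test_full_contour_all_presence(self, grid, rng):
        mask = np.ones(grid.shape, dtype=bool)
        eac = _field(grid, "eac_prob", rng.random(grid.shape))
        ssd = _field(grid, "sst_sd", rng.random(grid.shape))
        cells = mask_presence_absence(_contour(grid, mask), (eac, ssd), 3, "gull")
        assert (cells["presence"] == 1).all()

    def test_avoided_habitat_shows_in_group_means(self, grid, env_fields):
        """Synthetic strong-avoidance tracks: used cells have lower EAC
        probability than available cells (direct group-means oracle)."""
        from dataclasses import replace

        from seabirdniche.synthetic import ARCHETYPES, COLONY, simulate_tracks
        from seabirdniche.tracks import compute_centroids, pool_daily
        from seabirdniche.ud import contour_mask, estimate_ud

        arch = replace(
            ARCHETYPES["crested_tern"], eac_avoidance_slope=30.0,
            eac_avoidance_threshold=0.2, sstsd_avoidance_slope=0.0,
        )
        trk = simulate_tracks(arch, COLONY, env_fields, n_birds=8, seed=21)
        pts, n_tracked = pool_daily(compute_centroids(trk))
        by_date = {}
        for f in env_fields:
            by_date.setdefault(f.date, {})[f.variable] = f
        frames = []
        for (sp, day), grp in pts.groupby(["species", "day"]):
            ud = estimate_ud(grp, grid)
            contour = contour_mask(ud, 0.95)
            frames.append(
                mask_presence_absence(
                    contour, (by_date[day]["eac_prob"], by_date[day]["sst_sd"]), 8, sp, day
                )
            )
        cells = pd.concat(frames)
        means = cells.groupby("presence")["eac_prob"].mean()
        assert means.loc[1] < means.loc[0]

    def test_grid_mismatch_rejected(self, grid, rng):
        other = GridSpec(-36.6, -35.8, 149.8, 150.8, 0.05)
        eac = _field(other, "eac_prob", rng.random(other.shape))
        ssd = _field(other, "sst_sd", rng.random(other.shape))
        mask = np.ones(grid.shape, dtype=bool)
        with pytest.raises(ValueError):
            mask_presence_absence(_contour(grid, mask), (eac, ssd), 2, "tern")


class TestEnvProxies:
    def test_all_cells_above_threshold(self, grid):
        prox = eac_dominance(_field(grid, "eac_prob", np.full(grid.shape, 0.9)))
        assert prox.eac_dominance_pct == 100.0

    def test_half_cells_above_threshold(self, grid):
        vals = np.full(grid.shape, 0.1)
        vals.ravel()[: grid.n_cells // 2] = 0.9
        prox = eac_dominance(_field(grid, "eac_prob", vals))
        assert prox.eac_dominance_pct == 50.0

    def test_zero_dominance_guarded_log(self, grid):
        prox = eac_dominance(_field(grid, "eac_prob", np.zeros(grid.shape)))
        assert prox.eac_dominance_pct == 0.0
        eps = 0.5 * 100.0 / grid.n_cells
        assert prox.log_eac_dominance == pytest.approx(np.log(eps))

    def test_dominance_monotone_in_cell_values(self, grid, rng):
        vals = rng.random(grid.shape)
        base = eac_dominance(_field(grid, "eac_prob", vals)).eac_dominance_pct
        bumped = eac_dominance(
            _field(grid, "eac_prob", np.minimum(vals + 0.2, 1.0))
        ).eac_dominance_pct
        assert bumped >= base

    def test_daily_sst_sd_is_mean(self, grid):
        vals = np.full(grid.shape, 0.2)
        vals.ravel()[0] = 0.8
        expected = vals.mean()
        assert daily_sst_sd(_field(grid, "sst_sd", vals)) == pytest.approx(expected)

    def test_constant_field_mean(self, grid):
        assert daily_sst_sd(_field(grid, "sst_sd", np.full(grid.shape, 0.37))) == pytest.approx(0.37)

    def test_wrong_variable_rejected(self, grid):
        f = _field(grid, "sst", np.full(grid.shape, 18.0))
        with pytest.raises(ValueError):
            eac_dominance(f)
        with pytest.raises(ValueError):
            daily_sst_sd(f)

    def test_sst_sd_derivation_spatial_anomaly(self, grid):
        vals = np.full(grid.shape, 18.0)
        vals[0, 0] = 20.0
        sd = sst_sd_from_sst(_field(grid, "sst", vals))
        assert sd.variable == "sst_sd"
        expected = np.abs(vals - vals.mean())
        np.testing.assert_allclose(sd.values, expected)


def _simulate_occurrence(seed, beta_eac, beta_sd, n_days=25, n_cells=50, sigma_day=0.5):
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sigma_day, n_days)
    frames = []
    for d in range(n_days):
        eac = rng.random(n_cells)
        ssd = rng.random(n_cells) * 1.5
        for si, sp in enumerate(("tern", "penguin")):
            eta = 0.3 + beta_eac[si] * eac + beta_sd[si] * ssd + u[d] + np.log10(8)
            frames.append(
                pd.DataFrame(
                    {
                        "day": d,
                        "species": sp,
                        "presence": (rng.random(n_cells) < expit(eta)).astype(int),
                        "eac_prob": eac,
                        "sst_sd": ssd,
                        "n_tracked": 8,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


class TestOccurrenceModel:
    def test_recovers_injected_eac_slope(self):
        fit = _simulate_and_fit = fit_occurrence_model(
            _simulate_occurrence(3, beta_eac=(-4.0, -4.0), beta_sd=(-1.0, -1.0))
        )
        row = fit.terms[fit.terms["Variables"] == "penguin x EAC probability"].iloc[0]
        assert abs(row["Est"] - (-4.0)) < 2.0 * row["SE"]

    def test_term_table_shape(self):
        fit = fit_occurrence_model(_simulate_occurrence(5, (-2.0, -2.0), (0.0, 0.0)))
        assert set(fit.terms["Type"]) == {"Fixed", "Random"}
        assert len(fit.terms[fit.terms["Type"] == "Fixed"]) == 4  # 2 species x 2 covars
        assert 0.0 <= fit.deviance_explained_pct <= 100.0

    def test_single_species_rejected(self):
        df = _simulate_occurrence(1, (-1.0, -1.0), (0.0, 0.0))
        with pytest.raises(ValueError):
            fit_occurrence_model(df[df["species"] == "tern"])

    def test_missing_covariate_rejected(self):
        df = _simulate_occurrence(1, (-1.0, -1.0), (0.0, 0.0))
        df.loc[0, "eac_prob"] = np.nan
        with pytest.raises(ValueError):
            fit_occurrence_model(df)


class TestAreaModel:
    def _daily_areas(self, seed, beta_sd=(0.0, 0.0), n_days=40):
        rng = np.random.default_rng(seed)
        rows = []
        u = rng.normal(0, 0.1, n_days)
        for d in range(n_days):
            eac = rng.random()
            ssd = rng.random() * 1.5
            for si, sp in enumerate(("tern", "penguin")):
                log_area = 2.0 + beta_sd[si] * ssd + u[d] + rng.normal(0, 0.15) + np.log10(8)
                rows.append(
                    {
                        "species": sp,
                        "day": d,
                        "area_km2": 10.0**log_area,
                        "eac_prob": eac,
                        "sst_sd": ssd,
                        "n_tracked": 8,
                    }
                )
        return pd.DataFrame(rows)

    def test_recovers_injected_sst_sd_slope(self):
        df = self._daily_areas(11, beta_sd=(3.0, 0.0))
        fit = fit_area_model(df)
        row = fit.terms[fit.terms["Variables"] == "tern x SST SD"].iloc[0]
        assert abs(row["Est"] - 3.0) < 2.0 * row["SE"]

    def test_response_scaling_shifts_only_intercept(self):
        df = self._daily_areas(13)
        fit1 = fit_area_model(df)
        df2 = df.copy()
        df2["area_km2"] = df2["area_km2"] * 10.0
        fit2 = fit_area_model(df2)
        c1 = fit1.metadata["coefficients"]
        c2 = fit2.metadata["coefficients"]
        assert c2["Intercept"] - c1["Intercept"] == pytest.approx(1.0, abs=1e-6)
        for k in c1:
            if k != "Intercept":
                assert c2[k] == pytest.approx(c1[k], abs=1e-6)

    def test_nonpositive_area_rejected(self):
        df = self._daily_areas(1)
        df.loc[0, "area_km2"] = 0.0
        with pytest.raises(ValueError):
            fit_area_model(df)


class TestCompareYears:
    def test_identical_distributions_not_significant(self):
        base = np.sin(np.arange(30))  # any fixed values, copied across years
        df = pd.DataFrame(
            {"year": np.repeat(["2012", "2013", "2014"], 30), "value": np.tile(base, 3)}
        )
        res = compare_years(df)
        assert res["anova"]["p"] > 0.05
        assert res["anova"]["F"] == pytest.approx(0.0, abs=1e-9)

    def test_three_years_give_three_tukey_pairs(self, rng):
        df = pd.DataFrame(
            {
                "year": np.repeat(["2012", "2013", "2014"], 20),
                "value": rng.normal(size=60),
            }
        )
        assert len(compare_years(df)["tukey"]) == 3

    def test_large_shift_detected_in_both_contrasts(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(10, 1, 20)])
        df = pd.DataFrame({"year": np.repeat(["2012", "2013", "2014"], 20), "value": vals})
        res = compare_years(df)
        tk = res["tukey"]
        shifted = tk[(tk["group1"] == "2014") | (tk["group2"] == "2014")]
        assert shifted["reject"].all()
        assert res["anova"]["p"] < 0.001

    def test_underfilled_year_rejected(self):
        df = pd.DataFrame({"year": ["2012", "2012", "2013"], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            compare_years(df)
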