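"""PCA environment space, Schoener's D and the resampling framework."""

import numpy as np
import pandas as pd
import pytest

from seabirdniche.grids import GridSpec
from seabirdniche.niche import (
    NicheDensity,
    env_pca,
    niche_density,
    occurrence_raster,
    overlap_summary,
    pc_frame,
    resample_overlaps,
    schoeners_d,
    sensitivity_anova,
)


class TestOccurrenceRaster:
    def test_points_in_one_cell(self, grid):
        pts = np.tile([150.32, -36.22], (10, 1))
        occ = occurrence_raster(pts, grid)
        assert occ.counts.max() == 10
        assert occ.counts.sum() == 10

    def test_total_count_conserved_with_dropped_points(self, grid, rng):
        lon = rng.uniform(149.0, 151.5, 500)  # some out of bounds
        lat = rng.uniform(-37.0, -35.5, 500)
        occ = occurrence_raster(np.column_stack([lon, lat]), grid)
        inside = grid.contains(lon, lat).sum()
        assert occ.counts.sum() == inside
        assert occ.n_dropped == 500 - inside

    def test_edge_point_half_open_convention(self):
        g = GridSpec(0.0, 1.0, 0.0, 1.0, 0.5)
        occ = occurrence_raster(np.array([[0.5, 0.5]]), g)
        assert occ.counts[1, 1] == 1

    def test_all_points_outside_rejected(self, grid):
        with pytest.raises(ValueError):
            occurrence_raster(np.array([[0.0, 0.0]]), grid)


class TestEnvPCA:
    def test_eigenvalue_proportions_sum_to_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 4)), columns=["lat", "lon", "eac_prob", "sst_sd"])
        model, _ = env_pca(df)
        assert model.explained_proportion.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scores_orthogonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=["lat", "lon", "eac_prob", "sst_sd"])
        _, scores = env_pca(df)
        assert abs(np.corrcoef(scores[:, 0], scores[:, 1])[0, 1]) < 1e-10

    def test_correlated_block_loads_first_component(self, rng):
        """Closed form: with one perfectly correlated pair plus two
        independent variables, PC1 loads the pair equally (up to sign)."""
        a = rng.normal(size=2000)
        df = pd.DataFrame(
            {
                "lat": a,
                "lon": a,
                "eac_prob": rng.normal(size=2000),
                "sst_sd": rng.normal(size=2000),
            }
        )
        model, _ = env_pca(df)
        pc1 = model.components[0]
        assert abs(pc1[0]) == pytest.approx(abs(pc1[1]), abs=1e-10)
        assert abs(pc1[0]) == pytest.approx(1.0 / np.sqrt(2.0), abs=0.05)
        assert model.explained_proportion[0] == pytest.approx(0.5, abs=0.03)

    def test_constant_column_rejected_by_name(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=["lat", "lon", "eac_prob", "sst_sd"])
        df["sst_sd"] = 1.0
        with pytest.raises(ValueError, match="sst_sd"):
            env_pca(df)


class TestNicheDensity:
    def test_density_normalised(self, rng):
        scores = rng.normal(size=(100, 2))
        frame = pc_frame(scores, R=50)
        z = niche_density(scores, None, frame)
        assert z.z.sum() == pytest.approx(1.0, abs=1e-9)
        assert (z.z >= 0).all()

    def test_single_cell_tiny_bandwidth_concentrates_mass(self):
        frame = (np.linspace(-1, 1, 50), np.linspace(-1, 1, 50))
        z = niche_density(np.array([[0.153, -0.388]]), None, frame, bandwidth=1e-3)
        iy, ix = np.unravel_index(np.argmax(z.z), z.z.shape)
        assert frame[0][ix] == pytest.approx(0.153, abs=(frame[0][1] - frame[0][0]))
        assert frame[1][iy] == pytest.approx(-0.388, abs=(frame[1][1] - frame[1][0]))
        assert z.z.max() > 0.99

    def test_identical_inputs_identical_fields(self, rng):
        scores = rng.normal(size=(40, 2))
        w = rng.integers(1, 5, size=40).astype(float)
        frame = pc_frame(scores, R=60)
        z1 = niche_density(scores, w, frame)
        z2 = niche_density(scores, w, frame)
        np.testing.assert_array_equal(z1.z, z2.z)

    def test_coarse_frame_rejected(self, rng):
        scores = rng.normal(size=(20, 2))
        frame = (np.linspace(-1, 1, 5), np.linspace(-1, 1, 5))
        with pytest.raises(ValueError):
            niche_density(scores, None, frame)


class TestSchoenersD:
    def _dens(self, z):
        z = np.asarray(z, dtype=float)
        return NicheDensity(
            pc1_centers=np.arange(z.shape[1], dtype=float),
            pc2_centers=np.arange(z.shape[0], dtype=float),
            z=z / z.sum(),
        )

    def test_identical_densities(self):
        z = self._dens([[0.2, 0.3], [0.1, 0.4]])
        assert schoeners_d(z, z) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        z1 = self._dens([[1.0, 0.0], [0.0, 0.0]])
        z2 = self._dens([[0.0, 0.0], [0.0, 1.0]])
        assert schoeners_d(z1, z2) == pytest.approx(0.0)

    def test_hand_computed_two_cell_case(self):
        # p1 = (1, 0), p2 = (0.5, 0.5): D = 1 - 0.5*(0.5 + 0.5) = 0.5
        z1 = self._dens([[1.0, 0.0]])
        z2 = self._dens([[0.5, 0.5]])
        assert schoeners_d(z1, z2) == pytest.approx(0.5)

    def test_invariant_to_common_scaling(self):
        raw = np.array([[0.2, 0.3], [0.1, 0.4]])
        z1 = self._dens(raw)
        z2 = self._dens(raw * 37.0)
        assert schoeners_d(z1, z2) == pytest.approx(1.0)

    def test_mismatched_grids_rejected(self):
        z1 = self._dens([[0.5, 0.5]])
        z2 = self._dens([[0.3, 0.3], [0.2, 0.2]])
        with pytest.raises(ValueError):
            schoeners_d(z1, z2)


@pytest.fixture(scope="module")
def small_study(grid, env_fields):
    """Two species, one year, a handful of birds."""
    from seabirdniche.synthetic import ARCHETYPES, COLONY, simulate_tracks
    from seabirdniche.tracks import compute_centroids

    frames = []
    for sp, seed in (("crested_tern", 1), ("little_penguin", 2)):
        trk = simulate_tracks(ARCHETYPES[sp], COLONY, env_fields, n_birds=4, seed=seed)
        frames.append(trk)
    cen = compute_centroids(pd.concat(frames, ignore_index=True))
    cen["year"] = "2013"
    return cen


class TestResampleOverlaps:
    def test_record_count(self, small_study, env_fields, grid):
        rec = resample_overlaps(
            small_study, {"2013": env_fields}, grid, n_sub=3, iterations=5, seed=1
        )
        assert len(rec) == 1 * 1 * 5  # 1 pair x 1 year x 5 iterations
        assert rec["schoener_d"].between(0, 1).all()
        assert rec["kud_overlap_pct"].between(0, 100).all()

    def test_identical_species_full_overlap(self, small_study, env_fields, grid):
        dup = small_study.copy()
        dup["species"] = np.where(
            dup["species"] == "crested_tern", "mirror_a", "mirror_b"
        )
        # make mirror_b an exact copy of mirror_a
        a = dup[dup["species"] == "mirror_a"].copy()
        b = a.copy()
        b["species"] = "mirror_b"
        b["bird_id"] = b["bird_id"] + "_m"
        both = pd.concat([a, b], ignore_index=True)
        rec = resample_overlaps(
            both, {"2013": env_fields}, grid, n_sub=100, iterations=1, seed=0
        )
        assert rec["schoener_d"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert rec["kud_overlap_pct"].iloc[0] == pytest.approx(100.0, abs=1e-12)

    def test_deterministic_under_seed(self, small_study, env_fields, grid):
        kw = dict(n_sub=3, iterations=4, seed=42)
        r1 = resample_overlaps(small_study, {"2013": env_fields}, grid, **kw)
        r2 = resample_overlaps(small_study, {"2013": env_fields}, grid, **kw)
        pd.testing.assert_frame_equal(r1, r2)

    def test_full_population_single_iteration_is_seed_free(self, small_study, env_fields, grid):
        """n_sub >= population uses everyone: no randomness remains."""
        r1 = resample_overlaps(small_study, {"2013": env_fields}, grid, n_sub=99, iterations=1, seed=1)
        r2 = resample_overlaps(small_study, {"2013": env_fields}, grid, n_sub=99, iterations=1, seed=777)
        pd.testing.assert_frame_equal(r1, r2)

    def test_n_sub_below_two_rejected(self, small_study, env_fields, grid):
        with pytest.raises(ValueError):
            resample_overlaps(small_study, {"2013": env_fields}, grid, n_sub=1, iterations=1)


class TestSensitivityAnova:
    def _records(self, pair_shift=0.0, iteration_noise=True, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for pair_i, pair in enumerate(("a~b", "a~c", "b~c")):
            for year in ("2012", "2013"):
                for it in range(1, 21):
                    noise = rng.normal(0, 0.02) if iteration_noise else 0.0
                    d = 0.5 + (pair_shift if pair == "a~b" else 0.0) + 0.05 * pair_i + noise
                    rows.append(
                        {
                            "pair": pair,
                            "year": year,
                            "iteration": it,
                            "schoener_d": d,
                            "kud_overlap_pct": 100 * d / 2,
                        }
                    )
        return pd.DataFrame(rows)

    def test_iteration_never_significant_for_invariant_records(self):
        tables = sensitivity_anova(self._records())
        for tab in tables.values():
            assert tab.loc["C(iteration)", "PR(>F)"] > 0.05

    def test_injected_pair_effect_detected(self):
        tables = sensitivity_anova(self._records(pair_shift=0.3))
        assert tables["schoener_d"].loc["C(pair)", "PR(>F)"] < 0.05

    def test_three_factors_per_metric(self):
        tables = sensitivity_anova(self._records())
        for tab in tables.values():
            factors = [ix for ix in tab.index if ix != "Residual"]
            assert len(factors) == 3

    def test_summary_has_one_row_per_pair_year(self):
        s = overlap_summary(self._records())
        assert len(s) == 6
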