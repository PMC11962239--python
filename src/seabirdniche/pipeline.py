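"""Config-driven orchestration of the full niche-partitioning analysis.

Stage order mirrors the analysis workflow: synthetic (or file-based) inputs
-> 12-min centroid standardisation -> daily species KUDs and areas ->
use-availability habitat models and environmental proxies -> resampled
environmental-niche / spatial overlap series -> isotope models and Bayesian
ellipse areas.  Every run writes a manifest (config hash, package version,
per-stage output checksums and wall times) before exit, on success or
failure, and all CSV outputs use fixed column orders with 6-significant-
digit floats so a fixed seed reproduces byte-identical files.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fields import EnvField, fields_by_date, read_netcdf, write_netcdf
from .grids import GridSpec
from .habitat import (
    compare_years,
    daily_sst_sd,
    eac_dominance,
    fit_area_model,
    fit_occurrence_model,
    mask_presence_absence,
)
from .isotopes import ellipse_summary_table, fit_isotope_model, sea_bayes
from .niche import overlap_summary, resample_overlaps, sensitivity_anova
from .synthetic import (
    ARCHETYPES,
    COLONY,
    FIX_INTERVAL_S,
    N_BIRDS,
    YEARS,
    child_seed,
    default_grid,
    default_isotope_params,
    default_regime,
    generate_env_fields,
    simulate_isotopes,
    simulate_tracks,
    year_dates,
)
from .tracks import compute_centroids, pool_daily, read_tracks_csv, trip_statistics, write_tracks_csv
from .ud import contour_mask, estimate_ud

FLOAT_FMT = "%.6g"


@dataclass
class YearConfig:
    label: str
    start: dt.date
    n_days: int
    fix_interval_s: int = 240


@dataclass
class RunConfig:
    """Resolved run configuration (synthetic or file mode)."""

    mode: str = "synthetic"
    seed: int = 0
    outdir: str = "runs/demo"
    grid: GridSpec = dc_field(default_factory=default_grid)
    colony: tuple[float, float] = COLONY
    years: list[YearConfig] = dc_field(default_factory=list)
    n_birds: dict = dc_field(default_factory=lambda: dict(N_BIRDS))
    active_hours: float = 6.0
    kud_level: float = 0.95
    n_sub: int = 8
    iterations: int = 100
    posterior_draws: int = 100_000
    tracks_csv: str | None = None
    env_netcdf: dict = dc_field(default_factory=dict)  # year label -> path
    isotopes_csv: str | None = None

    def __post_init__(self) -> None:
        if not self.years:
            self.years = [
                YearConfig(
                    label=y,
                    start=dt.date(int(y), 10, 1),
                    n_days=15,
                    fix_interval_s=FIX_INTERVAL_S[y],
                )
                for y in YEARS
            ]
        labels = [y.label for y in self.years]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate year labels")
        spans = sorted(
            (y.start, y.start + dt.timedelta(days=y.n_days - 1), y.label) for y in self.years
        )
        for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"year windows {l1!r} and {l2!r} overlap")
        if self.mode == "files":
            for p in filter(None, [self.tracks_csv, self.isotopes_csv, *self.env_netcdf.values()]):
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "grid" in kw:
            kw["grid"] = GridSpec(**kw["grid"])
        if "colony" in kw:
            kw["colony"] = tuple(kw["colony"])
        if "years" in kw:
            kw["years"] = [
                YearConfig(
                    label=str(y["label"]),
                    start=dt.date.fromisoformat(str(y["start"])),
                    n_days=int(y["n_days"]),
                    fix_interval_s=int(y.get("fix_interval_s", 240)),
                )
                for y in kw["years"]
            ]
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "outdir": self.outdir,
            "grid": {
                "lat_min": self.grid.lat_min,
                "lat_max": self.grid.lat_max,
                "lon_min": self.grid.lon_min,
                "lon_max": self.grid.lon_max,
                "resolution": self.grid.resolution,
            },
            "colony": list(self.colony),
            "years": [
                {
                    "label": y.label,
                    "start": y.start.isoformat(),
                    "n_days": y.n_days,
                    "fix_interval_s": y.fix_interval_s,
                }
                for y in self.years
            ],
            "n_birds": dict(self.n_birds),
            "active_hours": self.active_hours,
            "kud_level": self.kud_level,
            "n_sub": self.n_sub,
            "iterations": self.iterations,
            "posterior_draws": self.posterior_draws,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_deployment(
    device_mass_g: float, body_mass_g: float, threshold_pct: float = 5.0
) -> tuple[float, bool]:
    """Device load as % of body mass (one decimal) and a pass flag.

    A deployment passes when the load does not exceed the threshold
    (default 5% -- the conventional upper bound for externally attached
    tags on flying seabirds).  The percentage is truncated (not rounded)
    to one decimal, matching how such loads are conventionally reported.
    """
    if device_mass_g <= 0 or body_mass_g <= 0:
        raise ValueError("masses must be positive")
    import math

    load = math.floor(1000.0 * device_mass_g / body_mass_g + 1e-9) / 10.0
    return load, load <= threshold_pct


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineRun:
    """Executes the staged analysis and accumulates a run manifest."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config_hash": config.config_hash(),
            "version": __version__,
            "config": config.to_dict(),
            "stages": {},
            "status": "running",
        }
        # state shared between stages
        self.env_by_year: dict[str, list[EnvField]] = {}
        self.fixes: pd.DataFrame | None = None
        self.isotope_samples: pd.DataFrame | None = None
        self.centroids: pd.DataFrame | None = None
        self.daily_areas: pd.DataFrame | None = None
        self.contours: dict = {}
        self.n_tracked: pd.DataFrame | None = None

    # -- helpers -----------------------------------------------------------

    def _write_csv(self, df: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        df.to_csv(path, index=False, float_format=FLOAT_FMT)
        return path

    def _record(self, stage: str, t0: float, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    def _year_of_day(self, day: dt.date) -> str | None:
        for y in self.config.years:
            if y.start <= day <= y.start + dt.timedelta(days=y.n_days - 1):
                return y.label
        return None

    # -- stages ------------------------------------------------------------

    def stage_inputs(self) -> None:
        t0 = time.perf_counter()
        cfg = self.config
        outputs: list[Path] = []
        if cfg.mode == "synthetic":
            frames = []
            for ycfg in cfg.years:
                dates = [ycfg.start + dt.timedelta(days=k) for k in range(ycfg.n_days)]
                env = generate_env_fields(
                    cfg.grid,
                    dates,
                    default_regime(ycfg.label) if ycfg.label in YEARS else None,
                    seed=child_seed(cfg.seed, f"env:{ycfg.label}"),
                )
                self.env_by_year[ycfg.label] = env
                nc = self.outdir / f"env_{ycfg.label}.nc"
                write_netcdf(env, nc)
                for sp, arch in ARCHETYPES.items():
                    frames.append(
                        simulate_tracks(
                            arch,
                            cfg.colony,
                            env,
                            n_birds=int(cfg.n_birds.get(sp, 8)),
                            fix_interval_s=ycfg.fix_interval_s,
                            active_hours=cfg.active_hours,
                            seed=child_seed(cfg.seed, f"tracks:{ycfg.label}:{sp}"),
                            bird_id_prefix=f"{sp[:4]}{ycfg.label}",
                        )
                    )
            self.fixes = pd.concat(frames, ignore_index=True)
            tracks_path = self.outdir / "tracks.csv"
            write_tracks_csv(self.fixes, tracks_path)
            self.isotope_samples = simulate_isotopes(
                default_isotope_params(), seed=child_seed(cfg.seed, "isotopes")
            )
            iso_path = self._write_csv(self.isotope_samples, "isotopes.csv")
            outputs = [tracks_path, iso_path]
        else:
            if cfg.tracks_csv is None:
                raise ValueError("file mode requires tracks_csv")
            self.fixes = read_tracks_csv(cfg.tracks_csv)
            if len(self.fixes) == 0:
                raise ValueError("track_processing: empty track CSV")
            for label, path in cfg.env_netcdf.items():
                self.env_by_year[label] = read_netcdf(path, cfg.grid)
            if cfg.isotopes_csv:
                self.isotope_samples = pd.read_csv(
                    cfg.isotopes_csv, dtype={"year": str}
                )
        self._record("inputs", t0, outputs)

    def stage_tracks(self) -> None:
        t0 = time.perf_counter()
        if self.fixes is None or len(self.fixes) == 0:
            raise ValueError("track_processing: no GPS fixes available")
        self.centroids = compute_centroids(self.fixes)
        self.centroids["year"] = [self._year_of_day(d) for d in self.centroids["day"]]
        self.centroids = self.centroids[self.centroids["year"].notna()].reset_index(drop=True)
        trips = trip_statistics(self.centroids, self.config.colony)
        p1 = self._write_csv(self.centroids, "centroids.csv")
        p2 = self._write_csv(trips, "trip_statistics.csv")
        self._record("track_processing", t0, [p1, p2])

    def stage_ud(self) -> None:
        t0 = time.perf_counter()
        points, n_tracked = pool_daily(self.centroids)
        self.n_tracked = n_tracked
        rows = []
        for (sp, day), grp in points.groupby(["species", "day"]):
            ud = estimate_ud(grp, self.config.grid, species=sp, day=day)
            contour = contour_mask(ud, self.config.kud_level)
            self.contours[(sp, day)] = contour
            rows.append(
                {
                    "species": sp,
                    "day": day,
                    "level": self.config.kud_level,
                    "area_km2": contour.area_km2,
                    "contained_mass": contour.contained_mass,
                }
            )
        self.daily_areas = pd.DataFrame(rows)
        path = self._write_csv(self.daily_areas, "daily_kud_areas.csv")
        self._record("utilization_distribution", t0, [path])

    def stage_habitat(self) -> None:
        t0 = time.perf_counter()
        n_map = {
            (r.species, r.day): int(r.n_tracked) for r in self.n_tracked.itertuples()
        }
        env_by_date = {}
        for env in self.env_by_year.values():
            env_by_date.update(fields_by_date(env))

        cell_frames = []
        proxy_rows = []
        for day, flds in sorted(env_by_date.items()):
            prox = eac_dominance(flds["eac_prob"])
            proxy_rows.append(
                {
                    "day": day,
                    "year": self._year_of_day(day),
                    "eac_dominance_pct": prox.eac_dominance_pct,
                    "log_eac_dominance": prox.log_eac_dominance,
                    "mean_sst_sd": daily_sst_sd(flds["sst_sd"]),
                    "mean_eac_prob": float(np.mean(flds["eac_prob"].valid_values())),
                }
            )
        proxies = pd.DataFrame(proxy_rows)
        for (sp, day), contour in sorted(self.contours.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            flds = env_by_date[day]
            cell_frames.append(
                mask_presence_absence(
                    contour, (flds["eac_prob"], flds["sst_sd"]), n_map[(sp, day)], sp, day
                )
            )
        cells = pd.concat(cell_frames, ignore_index=True)

        occ_fit = fit_occurrence_model(cells)
        pmap = proxies.set_index("day")
        area_df = self.daily_areas.copy()
        area_df["eac_prob"] = [pmap.loc[d, "mean_eac_prob"] for d in area_df["day"]]
        area_df["sst_sd"] = [pmap.loc[d, "mean_sst_sd"] for d in area_df["day"]]
        area_df["n_tracked"] = [n_map[(r.species, r.day)] for r in area_df.itertuples()]
        area_fit = fit_area_model(area_df)

        terms = pd.concat(
            [
                occ_fit.terms.assign(Model="Presence/absence"),
                area_fit.terms.assign(Model="95% KUD area"),
            ],
            ignore_index=True,
        )[["Model", "Variables", "Type", "Est", "SE", "t", "p"]]
        self.habitat_fits = {"occurrence": occ_fit, "area": area_fit}
        self.proxies = proxies

        anovas = []
        for metric in ("log_eac_dominance", "mean_sst_sd"):
            res = compare_years(proxies.rename(columns={metric: "value"})[["year", "value"]])
            anovas.append(
                {
                    "metric": metric,
                    "F": res["anova"]["F"],
                    "p": res["anova"]["p"],
                }
            )
        p1 = self._write_csv(cells, "habitat_cells.csv")
        p2 = self._write_csv(terms, "habitat_model_terms.csv")
        p3 = self._write_csv(proxies, "daily_env_proxies.csv")
        p4 = self._write_csv(pd.DataFrame(anovas), "proxy_year_anova.csv")
        dev = pd.DataFrame(
            {
                "model": ["occurrence", "kud_area"],
                "deviance_explained_pct": [
                    occ_fit.deviance_explained_pct,
                    area_fit.deviance_explained_pct,
                ],
                "random_variance": [occ_fit.random_variance, area_fit.random_variance],
            }
        )
        p5 = self._write_csv(dev, "habitat_model_summary.csv")
        self._record("habitat_models", t0, [p1, p2, p3, p4, p5])

    def stage_overlap(self) -> None:
        t0 = time.perf_counter()
        records = resample_overlaps(
            self.centroids,
            self.env_by_year,
            self.config.grid,
            n_sub=self.config.n_sub,
            iterations=self.config.iterations,
            kud_level=self.config.kud_level,
            seed=child_seed(self.config.seed, "resample"),
        )
        self.overlap_records = records
        summary = overlap_summary(records)
        p1 = self._write_csv(records, "overlap_records.csv")
        p2 = self._write_csv(summary, "overlap_summary.csv")
        outputs = [p1, p2]
        if records["iteration"].nunique() > 1:
            tables = sensitivity_anova(records)
            rows = []
            for metric, tab in tables.items():
                for factor in tab.index:
                    if factor == "Residual":
                        continue
                    rows.append(
                        {
                            "metric": metric,
                            "factor": factor,
                            "F": tab.loc[factor, "F"],
                            "p": tab.loc[factor, "PR(>F)"],
                        }
                    )
            p3 = self._write_csv(pd.DataFrame(rows), "overlap_sensitivity_anova.csv")
            outputs.append(p3)
        self._record("environmental_niche", t0, outputs)

    def stage_isotopes(self) -> None:
        t0 = time.perf_counter()
        samples = self.isotope_samples
        if samples is None or len(samples) == 0:
            self._record("isotope_niche", t0, [])
            return
        samples = samples.copy()
        samples["year"] = samples["year"].astype(str)
        tables = []
        fits = {}
        for element in ("13C", "15N"):
            fit = fit_isotope_model(samples, element)
            fits[element] = fit
            tables.append(fit.terms.assign(Isotope=element))
        terms = pd.concat(tables, ignore_index=True)[
            ["Isotope", "Variables", "Type", "Est", "SE", "t", "p"]
        ]
        self.isotope_fits = fits

        estimates = []
        for (sp, year), grp in sorted(samples.groupby(["species", "year"]).groups.items()):
            sub = samples.loc[grp]
            estimates.append(
                sea_bayes(
                    sub,
                    draws=self.config.posterior_draws,
                    seed=child_seed(self.config.seed, f"seab:{sp}:{year}"),
                    species=sp,
                    year=year,
                )
            )
        self.ellipses = estimates
        p1 = self._write_csv(terms, "isotope_model_terms.csv")
        p2 = self._write_csv(ellipse_summary_table(estimates), "ellipse_summary.csv")
        self._record("isotope_niche", t0, [p1, p2])

    # -- driver ------------------------------------------------------------

    STAGES = ("inputs", "tracks", "ud", "habitat", "overlap", "isotopes")

    def run(self) -> dict:
        try:
            for stage in self.STAGES:
                try:
                    getattr(self, f"stage_{stage}")()
                except Exception as exc:
                    self.manifest["status"] = "failed"
                    self.manifest["failed_stage"] = stage
                    self.manifest["error"] = f"{type(exc).__name__}: {exc}"
                    raise
            self.manifest["status"] = "ok"
        finally:
            (self.outdir / "manifest.json").write_text(
                json.dumps(self.manifest, indent=2, default=str)
            )
        return self.manifest


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to the outdir)."""
    return PipelineRun(config).run()
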