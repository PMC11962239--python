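"""Use-availability habitat selection against dynamic ocean covariates.

Cells inside a species' daily 95% KUD contour are "presence" (used habitat),
all other study-area cells are "absence" (available habitat).  Each cell-day
record carries that day's EAC-origin probability and SST-SD values.  Two
mixed models follow, both with the structure

    response ~ species * EAC_prob + species * SST_SD + (1 | day) + offset(log10 N)

where N is the number of individuals tracked that day: a binomial (logit)
model of cell presence/absence, and a Gaussian model of log10 daily 95% KUD
area.  Per-species slopes (species x covariate) are reported with Wald SEs
from linear combinations of the treatment-coded coefficients.

Daily environmental proxies -- EAC dominance (% of cells with EAC
probability > 0.5) and mean SST SD -- are compared between years by one-way
ANOVA with Tukey HSD post-hoc contrasts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, norm

from .fields import EnvField
from .glmm import (
    ModelFit,
    binomial_deviance_explained,
    fit_binomial_glmm,
    fit_gaussian_lmm,
    gaussian_deviance_explained,
)
from .ud import KUDContour

HABITAT_COLUMNS = [
    "day",
    "species",
    "cell_lat",
    "cell_lon",
    "presence",
    "eac_prob",
    "sst_sd",
    "n_tracked",
]

#: EAC-origin classification threshold: cells above this probability are
#: classed as EAC source water
EAC_THRESHOLD = 0.5


@dataclass(frozen=True)
class DailyEnvProxy:
    day: dt.date
    eac_dominance_pct: float
    log_eac_dominance: float
    mean_sst_sd: float


def mask_presence_absence(
    contour: KUDContour,
    env_pair: tuple[EnvField, EnvField],
    n_tracked: int,
    species: str,
    day=None,
) -> pd.DataFrame:
    """One record per grid cell: inside-contour presence plus covariates."""
    eac, ssd = env_pair
    if eac.variable != "eac_prob" or ssd.variable != "sst_sd":
        raise ValueError("env_pair must be (eac_prob, sst_sd) fields")
    if eac.grid != contour.grid or ssd.grid != contour.grid:
        raise ValueError("contour and env fields must share a grid")
    grid = contour.grid
    lat = np.repeat(grid.lat_centers, grid.n_lon)
    lon = np.tile(grid.lon_centers, grid.n_lat)
    return pd.DataFrame(
        {
            "day": day if day is not None else eac.date,
            "species": species,
            "cell_lat": lat,
            "cell_lon": lon,
            "presence": contour.cells.ravel().astype(int),
            "eac_prob": eac.values.ravel(),
            "sst_sd": ssd.values.ravel(),
            "n_tracked": int(n_tracked),
        }
    )


def eac_dominance(
    env: EnvField, threshold: float = EAC_THRESHOLD, log_eps: float | None = None
) -> DailyEnvProxy:
    """Percentage of cells strictly above the EAC threshold, and its log.

    The natural log uses a small-value guard epsilon equal to half the
    smallest nonzero observable percentage (half of 100/n_cells) so days
    with zero dominance remain finite and ordered below all others.
    """
    if env.variable != "eac_prob":
        raise ValueError("eac_dominance requires an eac_prob field")
    vals = env.valid_values()
    pct = 100.0 * float(np.mean(vals > threshold))
    if log_eps is None:
        log_eps = 0.5 * 100.0 / vals.size
    return DailyEnvProxy(
        day=env.date,
        eac_dominance_pct=pct,
        log_eac_dominance=float(np.log(pct + log_eps)),
        mean_sst_sd=np.nan,
    )


def daily_sst_sd(env: EnvField) -> float:
    """Arithmetic mean of the SST-SD field over valid cells."""
    if env.variable != "sst_sd":
        raise ValueError("daily_sst_sd requires an sst_sd field")
    vals = env.valid_values()
    if vals.size == 0:
        raise ValueError("all cells missing")
    return float(np.mean(vals))


def sst_sd_from_sst(sst: EnvField) -> EnvField:
    """Derive an SST-SD layer from an SST layer: |cell - daily spatial mean|.

    For real SST rasters without a precomputed variability product.  The
    alternative temporal-window interpretation is not the default.
    """
    if sst.variable != "sst":
        raise ValueError("expected an sst field")
    anom = np.abs(sst.values - np.nanmean(sst.valid_values()))
    return EnvField(date=sst.date, variable="sst_sd", grid=sst.grid, values=anom, mask=sst.mask)


# ---------------------------------------------------------------------------
# design matrix with species x covariate interactions


def _species_design(
    df: pd.DataFrame, covars: tuple[str, str] = ("eac_prob", "sst_sd")
) -> tuple[np.ndarray, list[str], list[str], list[tuple[str, str, np.ndarray]]]:
    """Treatment-coded design for species * covar1 + species * covar2.

    Returns (X, column_names, species_levels, slope_contrasts) where each
    slope contrast is (species, covar, vector l) such that l @ beta is that
    species' covariate slope.
    """
    species = sorted(df["species"].unique())
    if len(species) < 2:
        raise ValueError("need at least 2 species levels")
    ref = species[0]
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["Intercept"]
    for s in species[1:]:
        cols.append((df["species"] == s).to_numpy(float))
        names.append(f"species[{s}]")
    for c in covars:
        cols.append(df[c].to_numpy(float))
        names.append(c)
    for c in covars:
        for s in species[1:]:
            cols.append((df["species"] == s).to_numpy(float) * df[c].to_numpy(float))
            names.append(f"species[{s}]:{c}")
    X = np.column_stack(cols)
    p = X.shape[1]
    contrasts = []
    for c in covars:
        base = np.zeros(p)
        base[names.index(c)] = 1.0
        contrasts.append((ref, c, base.copy()))
        for s in species[1:]:
            l = base.copy()
            l[names.index(f"species[{s}]:{c}")] = 1.0
            contrasts.append((s, c, l))
    return X, names, species, contrasts


_COVAR_LABEL = {"eac_prob": "EAC probability", "sst_sd": "SST SD"}


def _slope_table(fit, contrasts) -> pd.DataFrame:
    rows = []
    for s, c, l in contrasts:
        est = float(l @ fit.params)
        se = float(np.sqrt(l @ fit.cov_params @ l))
        stat = est / se if se > 0 else np.nan
        rows.append(
            {
                "Variables": f"{s} x {_COVAR_LABEL.get(c, c)}",
                "Type": "Fixed",
                "Est": est,
                "SE": se,
                "t": stat,
                "p": 2.0 * norm.sf(abs(stat)) if np.isfinite(stat) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _check_model_input(cells: pd.DataFrame, covars=("eac_prob", "sst_sd")) -> None:
    if cells["species"].nunique() < 2:
        raise ValueError("need at least 2 species")
    if cells["day"].nunique() < 2:
        raise ValueError("need at least 2 days")
    for c in covars:
        if cells[c].isna().any():
            raise ValueError(f"missing values in covariate {c}")


def fit_occurrence_model(cells: pd.DataFrame, n_quad: int = 25) -> ModelFit:
    """Binomial mixed model of daily cell presence/absence.

    Fixed effects: species x EAC probability and species x SST SD
    interactions; random intercept on sampling day; offset log10 of the
    number of individuals tracked.  The term table reports per-species
    slopes; raw treatment-coded coefficients sit in ``metadata``.
    """
    _check_model_input(cells)
    X, names, _, contrasts = _species_design(cells)
    y = cells["presence"].to_numpy(float)
    offset = np.log10(cells["n_tracked"].to_numpy(float))
    fit = fit_binomial_glmm(
        X, y, cells["day"].to_numpy(), offset=offset, term_names=names, n_quad=n_quad
    )
    terms = _slope_table(fit, contrasts)
    terms.loc[len(terms)] = {
        "Variables": "Sampling day",
        "Type": "Random",
        "Est": np.nan,
        "SE": np.nan,
        "t": np.nan,
        "p": fit.random_p,
    }
    dev = binomial_deviance_explained(X, y, fit.params, offset)
    return ModelFit(
        terms=terms,
        random_variance=fit.random_sd**2,
        deviance_explained_pct=dev,
        model_type="binomial",
        loglik=fit.loglik,
        converged=fit.converged,
        metadata={
            "coefficients": dict(zip(names, fit.params)),
            "offset": "log10(n_tracked)",
            "deviance_explained_method": "fixed-part vs intercept-only deviance, random effects at zero",
        },
        raw=fit,
    )


def fit_area_model(daily_areas: pd.DataFrame) -> ModelFit:
    """Gaussian mixed model of log10 daily 95% KUD area (km**2).

    Same fixed/random/offset structure as the occurrence model; rejects
    non-positive areas (log-transformed response).
    """
    if (daily_areas["area_km2"] <= 0).any():
        raise ValueError("areas must be positive")
    _check_model_input(daily_areas)
    X, names, _, contrasts = _species_design(daily_areas)
    y = np.log10(daily_areas["area_km2"].to_numpy(float))
    offset = np.log10(daily_areas["n_tracked"].to_numpy(float))
    fit = fit_gaussian_lmm(
        X, y, daily_areas["day"].to_numpy(), offset=offset, term_names=names
    )
    terms = _slope_table(fit, contrasts)
    terms.loc[len(terms)] = {
        "Variables": "Sampling day",
        "Type": "Random",
        "Est": np.nan,
        "SE": np.nan,
        "t": np.nan,
        "p": fit.random_p,
    }
    dev = gaussian_deviance_explained(X, y, fit.params, offset)
    return ModelFit(
        terms=terms,
        random_variance=fit.random_sd**2,
        deviance_explained_pct=dev,
        model_type="gaussian",
        loglik=fit.loglik,
        converged=fit.converged,
        metadata={
            "coefficients": dict(zip(names, fit.params)),
            "response": "log10(area_km2)",
            "offset": "log10(n_tracked)",
        },
        raw=fit,
    )


def compare_years(daily_values: pd.DataFrame) -> dict:
    """One-way ANOVA across years plus Tukey HSD pairwise contrasts.

    ``daily_values`` needs columns ``year`` and ``value``; every year must
    contribute at least 2 values.  Returns ``{"anova": {F, p, df_between,
    df_within}, "tukey": DataFrame}``.
    """
    counts = daily_values.groupby("year")["value"].size()
    if len(counts) < 2:
        raise ValueError("need at least 2 years")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"years with fewer than 2 values: {bad}")
    groups = [g["value"].to_numpy(float) for _, g in daily_values.groupby("year")]
    F, p = f_oneway(*groups)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(
        daily_values["value"].to_numpy(float), daily_values["year"].astype(str).to_numpy()
    )
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return {
        "anova": {
            "F": float(F),
            "p": float(p),
            "df_between": len(groups) - 1,
            "df_within": int(sum(len(g) for g in groups) - len(groups)),
        },
        "tukey": tukey,
    }
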