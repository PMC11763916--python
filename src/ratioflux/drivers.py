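"""Screening environmental contributors to the daily RATIO.

Nine candidate factors are screened with a random forest: day length, LAI,
the day-night temperature difference, precipitation, soil water content,
CO2, the annual P/PET wetness index, VPD and wind speed. Importance is
permutation importance by default (comparable across predictor scales),
normalised to sum to one. A binned LAI-RATIO curve with a standard-deviation
envelope summarises the vegetation link.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from . import solar
from .errors import ParameterError, ValidationError

DRIVER_FACTORS = [
    "day_length", "lai", "delta_t", "precip", "swc", "co2",
    "wetness_index", "vpd", "ws",
]


def wetness_index(annual_precip: float, annual_pet: float) -> float:
    """Annual P/PET; values below 0.50 mark arid regions (with SWC < 10%)."""
    if annual_pet <= 0.0:
        raise ValidationError(f"annual PET must be positive, got {annual_pet}")
    return float(annual_precip / annual_pet)


def hargreaves_pet(ta_mean, ta_max, ta_min, latitude_deg, doy) -> np.ndarray:
    """Daily potential evapotranspiration (mm) by Hargreaves-Samani.

    PET = 0.0023 * Ra_mm * (T + 17.8) * sqrt(Tmax - Tmin), with Ra the daily
    extraterrestrial radiation converted to evaporation-equivalent mm.
    Negative temperature ranges are clipped to zero.
    """
    ra_mm = solar.extraterrestrial_radiation(latitude_deg, doy) * 0.408
    trange = np.maximum(np.asarray(ta_max, dtype=float) - np.asarray(ta_min, dtype=float), 0.0)
    pet = 0.0023 * ra_mm * (np.asarray(ta_mean, dtype=float) + 17.8) * np.sqrt(trange)
    return np.maximum(pet, 0.0)


def annual_wetness_index(summaries: pd.DataFrame, site_meta: pd.DataFrame) -> pd.DataFrame:
    """Per site-year P/PET from daily summaries.

    PET is Hargreaves with ta_day/ta_night standing in for the daily
    temperature extremes (the FULLSET daily extremes are not carried through
    the aggregation). Returns site_id, year, annual_precip, annual_pet, wetness_index.
    """
    lat = site_meta.set_index("site_id")["latitude"]
    df = summaries.assign(
        latitude=summaries["site_id"].map(lat),
        doy=summaries["date"].dt.dayofyear,
    )
    ta_mean = (df["ta_day"] + df["ta_night"]) / 2.0
    df["pet"] = hargreaves_pet(ta_mean, df["ta_day"], df["ta_night"], df["latitude"], df["doy"])
    g = df.groupby(["site_id", "year"]).agg(annual_precip=("precip", "sum"), annual_pet=("pet", "sum"))
    g = g.reset_index()
    g["wetness_index"] = g["annual_precip"] / g["annual_pet"].where(g["annual_pet"] > 0)
    return g


def build_driver_table(
    summaries: pd.DataFrame,
    site_lai: pd.DataFrame,
    site_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the nine-factor driver table, one row per site-day.

    ``site_lai`` carries site_id, year, lai (annual LAI joined to every
    site-day of that site-year; a site_id-only table is broadcast to all
    years). Rows missing the target ratio or any factor are dropped.
    """
    df = summaries.copy()
    if "year" in site_lai.columns:
        df = df.merge(site_lai[["site_id", "year", "lai"]], on=["site_id", "year"], how="left")
    else:
        df = df.merge(site_lai[["site_id", "lai"]], on="site_id", how="left")
    wet = annual_wetness_index(summaries, site_meta)
    df = df.merge(wet[["site_id", "year", "wetness_index"]], on=["site_id", "year"], how="left")
    cols = DRIVER_FACTORS + ["ratio"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParameterError(f"driver table missing columns: {missing}")
    return df[["site_id", "date"] + cols].dropna(subset=cols).reset_index(drop=True)


def screen_contributors(
    table: pd.DataFrame,
    seed: int = 0,
    method: str = "permutation",
    n_estimators: int = 300,
    n_repeats: int = 5,
    min_rows: int = 100,
) -> pd.DataFrame:
    """Rank the nine factors by random-forest importance for the daily RATIO.

    Returns a frame (factor, importance, rank) with importances clipped at
    zero and normalised to sum to one; deterministic given ``seed``.
    """
    if len(table) < min_rows:
        raise ParameterError(f"need at least {min_rows} complete rows, got {len(table)}")
    X = table[DRIVER_FACTORS].to_numpy(dtype=float)
    y = table["ratio"].to_numpy(dtype=float)
    forest = RandomForestRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    if method == "permutation":
        imp = permutation_importance(forest, X, y, n_repeats=n_repeats, random_state=seed)
        raw = imp.importances_mean
    elif method == "impurity":
        raw = forest.feature_importances_
    else:
        raise ParameterError(f"unknown importance method {method!r}")
    raw = np.clip(raw, 0.0, None)
    for j, f in enumerate(DRIVER_FACTORS):
        if np.std(X[:, j]) == 0.0 and raw[j] > 0:
            raw[j] = 0.0
    total = raw.sum()
    norm = raw / total if total > 0 else raw
    out = pd.DataFrame({"factor": DRIVER_FACTORS, "importance": norm})
    out["rank"] = out["importance"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("rank").reset_index(drop=True)


@dataclass
class LaiRatioCurve:
    """Binned LAI -> mean daily RATIO with a standard-deviation envelope."""

    lai_bin_centers: np.ndarray
    mean_ratio: np.ndarray
    sd_ratio: np.ndarray  # NaN where count < 2
    counts: np.ndarray
    trend_statistic: float  # Spearman rho of bin means vs centres


def lai_ratio_curve(lai, ratio, n_bins: int = 20) -> LaiRatioCurve:
    """Bin RATIO by LAI; report per-bin mean, SD and a monotone-trend statistic."""
    lai = np.asarray(lai, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if len(lai) == 0 or len(lai) != len(ratio):
        raise ParameterError("lai and ratio must be equal-length, non-empty")
    ok = np.isfinite(lai) & np.isfinite(ratio)
    lai, ratio = lai[ok], ratio[ok]
    lo, hi = lai.min(), lai.max()
    if lo == hi:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, lai, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=ratio, minlength=n_bins)
    means = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    sq = np.bincount(idx, weights=ratio**2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(counts > 1, (sq - counts * means**2) / (counts - 1), np.nan)
    sd = np.sqrt(np.maximum(var, 0.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    pop = counts > 0
    rho = float("nan")
    if pop.sum() >= 3:
        rho = float(stats.spearmanr(centers[pop], means[pop]).statistic)
    return LaiRatioCurve(centers, means, sd, counts, rho)
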