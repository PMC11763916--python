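"""Day/night partition, daily RATIO, and site-day aggregation.

The central statistic is the daily RATIO: the sum of half-hourly latent-heat
flux (LE) over the photosynthetic (daytime) period divided by the sum over the
whole day. Physically the ratio lies strictly inside (0, 1); measured days can
fall outside it (negative night-time LE under condensation, zero daytime flux
in polar night), and those days are discarded by the open-interval filter.

The 15 site-day variables carried through the analysis are listed in
``EC_VARIABLES``; per-period means are used for air temperature, daily means
for VPD/Rn/CO2/SWC, daily sums for precipitation, and period sums for the
carbon and energy fluxes (native half-hourly units, no unit conversion).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError

SLOTS_PER_DAY = 48

#: The 15 EC variables coupled with the daily RATIO.
EC_VARIABLES = [
    "ta_night", "ta_day", "vpd", "precip", "rn", "co2", "swc",
    "le", "nee", "nee_night", "nee_day", "reco_night", "reco_day",
    "gpp_day", "wuei_gpp",
]
FLUX_VARIABLES = ["le", "nee", "nee_night", "nee_day", "reco_day", "reco_night",
                  "gpp_day", "wuei_gpp"]
ENERGY_VARIABLES = ["ta_day", "ta_night", "rn", "vpd"]
MATTER_VARIABLES = ["precip", "co2", "swc"]


def label_daytime(df: pd.DataFrame, rule: str = "swinpot", sw_in_threshold: float = 20.0) -> np.ndarray:
    """Boolean daytime label per half-hourly record.

    rule="swinpot": potential incoming shortwave > 0 (astronomical daylight).
    rule="swin20": measured incoming shortwave above ``sw_in_threshold`` W m-2.
    """
    if rule == "swinpot":
        if "sw_in_pot" not in df.columns:
            raise ConfigurationError("daytime rule 'swinpot' requires an sw_in_pot column")
        return (df["sw_in_pot"].to_numpy(dtype=float) > 0.0)
    if rule == "swin20":
        if "sw_in" not in df.columns:
            raise ConfigurationError("daytime rule 'swin20' requires an sw_in column")
        return (df["sw_in"].to_numpy(dtype=float) > sw_in_threshold)
    raise ParameterError(f"unknown daytime rule {rule!r}")


def partition_day_night(df: pd.DataFrame, rule: str = "swinpot", sw_in_threshold: float = 20.0) -> pd.DataFrame:
    """Return a copy with a boolean ``day`` column (True = photosynthetic period)."""
    out = df.copy()
    out["day"] = label_daytime(df, rule=rule, sw_in_threshold=sw_in_threshold)
    return out


def compute_daily_ratio(le: np.ndarray, day: np.ndarray) -> float:
    """Daily RATIO = Σ daytime LE / Σ all-day LE for one site-day.

    NaN when the daily sum is zero (undefined; flagged for discard).
    May fall outside (0, 1) before filtering.
    """
    le = np.asarray(le, dtype=float)
    day = np.asarray(day, dtype=bool)
    total = np.nansum(le)
    if total == 0.0:
        return float("nan")
    return float(np.nansum(np.where(day, le, 0.0)) / total)


def _period_sum(values, mask):
    return np.where(mask & np.isfinite(values), values, 0.0)


def aggregate_daily(df: pd.DataFrame, min_coverage: float = 0.9) -> pd.DataFrame:
    """Aggregate labeled half-hourly records to one row per site-day.

    ``df`` needs canonical columns (``le``, ``ta``, ...) plus the boolean
    ``day`` label from :func:`partition_day_night`. Missing variables yield
    missing aggregates. Days whose LE coverage (non-missing slots out of 48)
    falls below ``min_coverage`` are marked ``valid=False``.
    """
    if "day" not in df.columns:
        raise ConfigurationError("records must be labeled; run partition_day_night first")
    day = df["day"].to_numpy(dtype=bool)
    night = ~day
    work = pd.DataFrame({
        "site_id": df["site_id"].to_numpy(),
        "date": df["timestamp"].dt.normalize().to_numpy(),
    })
    n = len(df)

    def col(name):
        if name in df.columns:
            return df[name].to_numpy(dtype=float)
        return np.full(n, np.nan)

    le = col("le")
    ta = col("ta")
    work["n_slots"] = 1
    work["day_slots"] = day.astype(np.int64)
    work["le_cov"] = np.isfinite(le).astype(np.int64)
    work["le_day"] = _period_sum(le, day)
    work["le_night"] = _period_sum(le, night)
    work["ta_day_s"] = _period_sum(ta, day)
    work["ta_day_c"] = (day & np.isfinite(ta)).astype(np.int64)
    work["ta_night_s"] = _period_sum(ta, night)
    work["ta_night_c"] = (night & np.isfinite(ta)).astype(np.int64)
    for name in ("vpd", "rn", "co2", "swc", "ws"):
        v = col(name)
        work[f"{name}_s"] = np.where(np.isfinite(v), v, 0.0)
        work[f"{name}_c"] = np.isfinite(v).astype(np.int64)
    p = col("precip")
    work["precip"] = np.where(np.isfinite(p), p, 0.0)
    nee = col("nee")
    reco = col("reco")
    gpp = col("gpp")
    work["nee_day"] = _period_sum(nee, day)
    work["nee_night"] = _period_sum(nee, night)
    work["reco_day"] = _period_sum(reco, day)
    work["reco_night"] = _period_sum(reco, night)
    work["gpp_day"] = _period_sum(gpp, day)

    g = work.groupby(["site_id", "date"], sort=True).sum(numeric_only=True).reset_index()

    out = pd.DataFrame({"site_id": g["site_id"], "date": g["date"]})
    le_total = g["le_day"] + g["le_night"]
    out["ratio"] = np.where(le_total != 0.0, g["le_day"] / le_total, np.nan)
    out["day_length"] = g["day_slots"] * 0.5
    out["coverage_fraction"] = g["le_cov"] / SLOTS_PER_DAY

    def mean(s, c):
        return np.where(g[c] > 0, g[s] / g[c].replace(0, 1), np.nan)

    out["ta_day"] = mean("ta_day_s", "ta_day_c")
    out["ta_night"] = mean("ta_night_s", "ta_night_c")
    out["delta_t"] = out["ta_day"] - out["ta_night"]
    for name in ("vpd", "rn", "co2", "swc", "ws"):
        out[name] = mean(f"{name}_s", f"{name}_c")
    out["precip"] = g["precip"]
    out["le"] = le_total
    out["le_day"] = g["le_day"]
    out["le_night"] = g["le_night"]
    for name in ("nee_day", "nee_night", "reco_day", "reco_night", "gpp_day"):
        out[name] = g[name]
    out["nee"] = out["nee_day"] + out["nee_night"]
    out["wuei_gpp"] = np.where(
        g["le_day"] > 0.0, out["gpp_day"] * out["vpd"] / g["le_day"], np.nan
    )
    out["year"] = out["date"].dt.year
    out["valid"] = out["coverage_fraction"] >= min_coverage
    return out


def daily_summaries(
    df: pd.DataFrame,
    rule: str = "swinpot",
    sw_in_threshold: float = 20.0,
    min_coverage: float = 0.9,
) -> pd.DataFrame:
    """partition + aggregate in one call (the usual entry point)."""
    labeled = partition_day_night(df, rule=rule, sw_in_threshold=sw_in_threshold)
    return aggregate_daily(labeled, min_coverage=min_coverage)


def filter_ratio(summaries: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Keep site-days with 0 < ratio < 1 strictly; report the discarded fraction.

    Days with an undefined ratio count as discarded. Coverage-invalid days are
    excluded from both numerator and denominator (they never had a usable
    ratio in the first place).
    """
    pool = summaries[summaries["valid"]] if "valid" in summaries.columns else summaries
    if len(pool) == 0:
        return pool.copy(), 0.0
    ratio = pool["ratio"].to_numpy(dtype=float)
    keep = np.isfinite(ratio) & (ratio > 0.0) & (ratio < 1.0)
    discarded_fraction = float(1.0 - keep.mean())
    return pool[keep].copy(), discarded_fraction


def aggregate_timescale(summaries: pd.DataFrame, scale: str = "monthly") -> pd.DataFrame:
    """Per-site monthly or annual means of the daily RATIO and the EC variables.

    The "mean daily RATIO" of a period is the arithmetic mean of the daily
    ratio values in the period, not the ratio of period sums.
    """
    if scale == "monthly":
        period = summaries["date"].dt.to_period("M").astype(str)
    elif scale == "annual":
        period = summaries["date"].dt.year
    else:
        raise ParameterError(f"unknown scale {scale!r}; use 'monthly' or 'annual'")
    cols = ["ratio"] + [c for c in EC_VARIABLES if c in summaries.columns]
    g = summaries.assign(period=period).groupby(["site_id", "period"])[cols]
    out = g.mean().reset_index()
    out["n_days"] = g.size().to_numpy()
    return out


def mean_daily_ratio(summaries: pd.DataFrame, sites=None) -> float:
    """Grand mean of daily RATIO values, optionally restricted to ``sites``.

    This is the "annual mean daily RATIO of all N sites" statistic used for
    the climate-zone comparisons.
    """
    pool = summaries if sites is None else summaries[summaries["site_id"].isin(list(sites))]
    return float(pool["ratio"].mean())
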