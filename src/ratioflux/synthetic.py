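"""Synthetic multi-site flux-network generator with known ground truth.

Emulates a FLUXNET2015-style network: per site, 30-min records of LE, NEE,
RECO, GPP, TA, VPD, NETRAD, P, CO2, SWC (plus SW_IN_POT and WS) over a span
of years, with latitude-driven day length from solar geometry. Each site-day
draws a latent daily RATIO from a Beta distribution whose mean is a monotone
function of the site's leaf area index; the half-hourly LE profile realises
that RATIO exactly (daytime flux proportional to potential shortwave,
night-time flux uniform). Every EC variable is a prescribed coupling
function of the latent RATIO plus a per-RATIO temporal trend, a site offset
and observation noise.

The prescribed couplings for flux/energy variables are unimodal degree-6
polynomials u with u'(x) proportional to x^4 (p - x), so the single interior
maximum sits exactly at the prescribed peak p in [0.93, 0.95]; matter
variables decrease linearly. Between-site offsets are small for flux/energy
variables — the network emulates a world in which, at equal RATIO, the same
variable has nearly the same magnitude in every ecosystem — and large
relative scatter for matter variables.

A configurable fraction of site-days is engineered to yield a computed RATIO
outside (0, 1) via negative night-time LE (condensation); polar night/day
days fall outside the interval naturally and are accounted for when the
injection probability is set, so the configured fraction is the expected
total out-of-range share.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import solar
from .errors import ConfigurationError
from .fluxnet_io import DEFAULT_COLUMN_MAP, MISSING_SENTINEL

LATENT_HEAT_VAPORIZATION = 2.45e6  # J kg-1, fixed constant for energy<->water
SECONDS_PER_SLOT = 1800.0
SWC_DEPTH_MM = 300.0  # soil column represented by the SWC percentage

#: Variables generated directly (wuei_gpp and nee are derived aggregates).
GENERATED_VARIABLES = [
    "ta_day", "ta_night", "vpd", "rn", "le", "nee_day", "nee_night",
    "reco_day", "reco_night", "gpp_day", "precip", "co2", "swc",
]

DEFAULT_COUPLINGS: dict[str, dict] = {
    "ta_day": {"kind": "unimodal", "lo": 2.0, "hi": 22.0, "peak": 0.94},
    "ta_night": {"kind": "unimodal", "lo": -2.0, "hi": 15.0, "peak": 0.94},
    "vpd": {"kind": "unimodal", "lo": 1.0, "hi": 13.0, "peak": 0.93},
    "rn": {"kind": "unimodal", "lo": 20.0, "hi": 170.0, "peak": 0.94},
    "le": {"kind": "unimodal", "lo": 400.0, "hi": 4200.0, "peak": 0.94},
    "nee_day": {"kind": "unimodal", "lo": 40.0, "hi": -480.0, "peak": 0.94},
    "nee_night": {"kind": "unimodal", "lo": 30.0, "hi": 200.0, "peak": 0.95},
    "reco_day": {"kind": "unimodal", "lo": 40.0, "hi": 230.0, "peak": 0.95},
    "reco_night": {"kind": "unimodal", "lo": 30.0, "hi": 200.0, "peak": 0.95},
    "gpp_day": {"kind": "unimodal", "lo": 30.0, "hi": 560.0, "peak": 0.94},
    "precip": {"kind": "linear", "intercept": 6.0, "slope": -3.0},
    "co2": {"kind": "linear", "intercept": 428.0, "slope": -14.0},
    "swc": {"kind": "linear", "intercept": 38.0, "slope": -16.0},
}

#: Ta-day trend profile (degrees C per year versus RATIO): negative below the
#: zero-crossing at 0.55, rising to its maximum at 0.90, declining toward 1.
#: The node placement is Monte-Carlo calibrated so the crossing and vertex are
#: identifiable from the default network at the trend analysis' bin width.
TA_DAY_TREND_PROFILE = [
    (0.0, -0.035), (0.45, -0.025), (0.55, 0.0), (0.65, 0.014),
    (0.75, 0.016), (0.85, 0.024), (0.90, 0.044), (1.0, -0.004),
]
_GPP_TREND_PROFILE = [(0.0, 0.0), (0.70, 0.0), (0.75, 2.5), (0.95, 2.5), (1.0, 0.0)]

DEFAULT_TRENDS: dict[str, object] = {
    "ta_day": TA_DAY_TREND_PROFILE,
    "ta_night": [(x, 0.8 * s) for x, s in TA_DAY_TREND_PROFILE],
    "co2": 2.1,
    "gpp_day": _GPP_TREND_PROFILE,
    "nee_day": [(x, -0.8 * s) for x, s in _GPP_TREND_PROFILE],
}

DEFAULT_NOISE_SD: dict[str, float] = {
    "ta_day": 1.2, "ta_night": 1.2, "vpd": 1.0, "rn": 10.0,
    "le": 160.0, "nee_day": 28.0, "nee_night": 12.0,
    "reco_day": 13.0, "reco_night": 12.0, "gpp_day": 30.0,
    "precip": 7.0, "co2": 8.0, "swc": 9.0,
}

DEFAULT_SITE_EFFECT_SD: dict[str, float] = {
    "ta_day": 0.6, "ta_night": 0.6, "vpd": 0.4, "rn": 5.0,
    "le": 80.0, "nee_day": 14.0, "nee_night": 6.0,
    "reco_day": 7.0, "reco_night": 6.0, "gpp_day": 15.0,
    "precip": 1.5, "co2": 3.0, "swc": 5.0,
}


def unimodal_curve(x, lo: float, hi: float, peak: float):
    """Degree-6 polynomial rising from lo at 0 to hi at the interior peak.

    u'(x) = x^4 (peak - x) / A with A chosen so u(peak) = 1; the only
    stationary point inside (0, 1) is the prescribed peak.
    """
    x = np.asarray(x, dtype=float)
    a = peak**6 / 30.0
    u = (peak * x**5 / 5.0 - x**6 / 6.0) / a
    return lo + (hi - lo) * u


def coupling_value(spec: dict, x):
    if spec["kind"] == "unimodal":
        return unimodal_curve(x, spec["lo"], spec["hi"], spec["peak"])
    if spec["kind"] == "linear":
        return spec["intercept"] + spec["slope"] * np.asarray(x, dtype=float)
    raise ConfigurationError(f"unknown coupling kind {spec['kind']!r}")


def trend_value(spec, x):
    """Per-year slope at RATIO x; scalar = constant, list of (x, slope) = interp."""
    x = np.asarray(x, dtype=float)
    if spec is None:
        return np.zeros_like(x)
    if np.isscalar(spec):
        return np.full_like(x, float(spec))
    pts = np.asarray(spec, dtype=float)
    return np.interp(x, pts[:, 0], pts[:, 1])


@dataclass
class SyntheticConfig:
    """Full parameterisation of the synthetic flux network."""

    n_sites: int = 30
    years: tuple[int, int] = (1997, 2014)
    latitudes: np.ndarray | None = None  # default linspace(-38, 70)
    longitudes: np.ndarray | None = None  # default alternating E/W
    lai: np.ndarray | None = None  # default 0.4..5.2 spread, seed-shuffled
    lai_link: tuple[float, float] = (0.30, 0.13)  # mean RATIO = a + b * LAI
    lai_link_bounds: tuple[float, float] = (0.05, 0.93)
    ratio_kappa: float = 25.0  # Beta concentration of the daily RATIO
    couplings: dict = field(default_factory=lambda: dict(DEFAULT_COUPLINGS))
    trends: dict = field(default_factory=lambda: dict(DEFAULT_TRENDS))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    site_effect_sd: dict = field(default_factory=lambda: dict(DEFAULT_SITE_EFFECT_SD))
    target_out_of_range_fraction: float = 0.234
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.target_out_of_range_fraction < 1.0:
            raise ConfigurationError("target_out_of_range_fraction must be in [0, 1)")
        if self.latitudes is None:
            self.latitudes = np.linspace(-38.0, 70.0, self.n_sites)
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        if len(self.latitudes) != self.n_sites:
            raise ConfigurationError("latitudes length must equal n_sites")
        if self.longitudes is None:
            lon = np.linspace(5.0, 150.0, self.n_sites)
            self.longitudes = np.where(np.arange(self.n_sites) % 2 == 0, lon, -lon)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        if self.lai is None:
            lai = np.linspace(0.4, 5.2, self.n_sites)
            rng = np.random.default_rng([self.seed, 7])
            self.lai = rng.permutation(lai)
        self.lai = np.asarray(self.lai, dtype=float)
        for sd in list(self.noise_sd.values()) + list(self.site_effect_sd.values()):
            if sd < 0:
                raise ConfigurationError("noise/site-effect sd must be >= 0")

    @property
    def site_ids(self) -> list[str]:
        return [f"SY-{i:03d}" for i in range(self.n_sites)]

    def site_mean_ratio(self, lai) -> np.ndarray:
        a, b = self.lai_link
        lo, hi = self.lai_link_bounds
        return np.clip(a + b * np.asarray(lai, dtype=float), lo, hi)


def _dates_and_daymask(cfg: SyntheticConfig, lat: float):
    y0, y1 = cfg.years
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    hour_mid = np.arange(48) * 0.5 + 0.25
    swp = solar.potential_shortwave(lat, doy[:, None], hour_mid[None, :])
    return dates, swp, swp > 0.0


def polar_day_fraction(cfg: SyntheticConfig) -> float:
    """Deterministic fraction of site-days with 0 h or 24 h of daylight."""
    total = polar = 0
    for lat in cfg.latitudes:
        _, _, mask = _dates_and_daymask(cfg, lat)
        n_day = mask.sum(axis=1)
        polar += int(((n_day == 0) | (n_day == 48)).sum())
        total += len(n_day)
    return polar / total


def _site_effects(cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng([cfg.seed, 1])
    return {
        v: rng.normal(0.0, cfg.site_effect_sd.get(v, 0.0), cfg.n_sites)
        for v in GENERATED_VARIABLES
    }


def _generate_site(cfg: SyntheticConfig, i: int, inject_q: float, site_effects):
    """One site's half-hourly frame plus per-day truth arrays."""
    lat = cfg.latitudes[i]
    rng = np.random.default_rng([cfg.seed, 1000 + i])
    dates, swp, daymask = _dates_and_daymask(cfg, lat)
    n_days = len(dates)
    n_day = daymask.sum(axis=1)
    n_night = 48 - n_day
    polar = (n_day == 0) | (n_day == 48)

    mu = cfg.site_mean_ratio(cfg.lai[i])
    kappa = cfg.ratio_kappa
    ratio = rng.beta(mu * kappa, (1.0 - mu) * kappa, n_days)
    injected = (~polar) & (rng.random(n_days) < inject_q)
    neg_strong = rng.random(n_days) < 0.5  # variant: ratio < 0 vs ratio > 1

    years = dates.year.to_numpy(dtype=float)
    t = years - years.mean()

    targets = {}
    for v in GENERATED_VARIABLES:
        val = coupling_value(cfg.couplings[v], ratio)
        val = val + trend_value(cfg.trends.get(v), ratio) * t
        val = val + site_effects[v][i]
        val = val + rng.normal(0.0, cfg.noise_sd.get(v, 0.0), n_days)
        targets[v] = val
    targets["precip"] = np.maximum(targets["precip"], 0.0)
    targets["swc"] = np.clip(targets["swc"], 2.0, 60.0)
    targets["le"] = np.maximum(targets["le"], 50.0)
    ws_day = 3.0 - 0.3 * ratio + rng.normal(0.0, 0.5, n_days)

    # --- half-hourly realisation -------------------------------------------
    day_w = np.where(daymask, swp, 0.0)
    day_w_sum = day_w.sum(axis=1)
    day_w = np.divide(day_w, day_w_sum[:, None], out=np.zeros_like(day_w),
                      where=day_w_sum[:, None] > 0)
    night_w = np.divide((~daymask).astype(float), n_night[:, None].astype(float),
                        out=np.zeros((n_days, 48)), where=n_night[:, None] > 0)

    L = targets["le"]
    day_total = np.where(polar & (n_day == 0), 0.0, np.where(injected, L, ratio * L))
    night_total = np.where(
        polar, np.where(n_day == 0, L, 0.0),
        np.where(injected, np.where(neg_strong, -1.4 * L, -0.3 * L), (1.0 - ratio) * L),
    )
    le_slots = day_total[:, None] * day_w + night_total[:, None] * night_w

    def per_period(day_vals, night_vals):
        return np.where(daymask, day_vals[:, None], night_vals[:, None])

    ta_slots = per_period(targets["ta_day"], targets["ta_night"]) + rng.normal(0, 0.3, (n_days, 48))
    nee_day_slot = np.divide(targets["nee_day"], n_day, out=np.zeros(n_days), where=n_day > 0)
    nee_night_slot = np.divide(targets["nee_night"], n_night, out=np.zeros(n_days), where=n_night > 0)
    nee_slots = per_period(nee_day_slot, nee_night_slot)
    reco_day_slot = np.divide(targets["reco_day"], n_day, out=np.zeros(n_days), where=n_day > 0)
    reco_night_slot = np.divide(targets["reco_night"], n_night, out=np.zeros(n_days), where=n_night > 0)
    reco_slots = per_period(reco_day_slot, reco_night_slot)
    gpp_slots = np.where(daymask, np.divide(targets["gpp_day"], n_day,
                                            out=np.zeros(n_days), where=n_day > 0)[:, None], 0.0)

    def flat_const(vals, jitter):
        return vals[:, None] + rng.normal(0, jitter, (n_days, 48))

    vpd_slots = np.maximum(flat_const(targets["vpd"], 0.1), 0.0)
    rn_slots = flat_const(targets["rn"], 2.0)
    co2_slots = flat_const(targets["co2"], 0.5)
    swc_slots = flat_const(targets["swc"], 0.2)
    ws_slots = np.maximum(flat_const(ws_day, 0.2), 0.0)
    p_slots = np.repeat(targets["precip"][:, None] / 48.0, 48, axis=1)
    sw_in_slots = swp * (0.55 + 0.3 * rng.random(n_days))[:, None]

    start = dates.values.astype("datetime64[m]")
    timestamps = (start[:, None] + (np.arange(48) * 30).astype("timedelta64[m]")).ravel()

    df = pd.DataFrame({
        "site_id": cfg.site_ids[i],
        "timestamp": timestamps,
        "le": le_slots.ravel(),
        "nee": nee_slots.ravel(),
        "reco": reco_slots.ravel(),
        "gpp": gpp_slots.ravel(),
        "ta": ta_slots.ravel(),
        "vpd": vpd_slots.ravel(),
        "rn": rn_slots.ravel(),
        "precip": p_slots.ravel(),
        "co2": co2_slots.ravel(),
        "swc": swc_slots.ravel(),
        "sw_in_pot": swp.ravel(),
        "sw_in": sw_in_slots.ravel(),
        "ws": ws_slots.ravel(),
    })

    # daily water balance, closed by a net runoff residual
    le_mm = le_slots.sum(axis=1) * SECONDS_PER_SLOT / LATENT_HEAT_VAPORIZATION
    dswc_mm = np.concatenate([[0.0], np.diff(targets["swc"])]) / 100.0 * SWC_DEPTH_MM
    runoff = targets["precip"] - dswc_mm - le_mm

    truth_site = {
        "dates": dates,
        "ratio": ratio,
        "injected": injected,
        "polar": polar,
        "day_length": n_day * 0.5,
        "water_balance": {
            "precip": targets["precip"], "dswc_mm": dswc_mm,
            "le_mm": le_mm, "runoff": runoff,
        },
    }
    return df, truth_site


def generate_network(cfg: SyntheticConfig):
    """Generate the full network.

    Returns ``(records, site_meta, truth)``: a dict of per-site half-hourly
    DataFrames in canonical columns, a site-metadata frame, and the
    machine-readable truth record (couplings, trends, LAI link, site
    effects, per-site latent ratios and water-balance terms).
    """
    p0 = polar_day_fraction(cfg)
    target = cfg.target_out_of_range_fraction
    if target > 0 and p0 >= target:
        raise ConfigurationError(
            f"polar day/night fraction {p0:.3f} already exceeds target "
            f"out-of-range fraction {target:.3f}"
        )
    inject_q = (target - p0) / (1.0 - p0) if target > 0 else 0.0
    site_effects = _site_effects(cfg)
    records: dict[str, pd.DataFrame] = {}
    truth_sites: dict[str, dict] = {}
    for i, site in enumerate(cfg.site_ids):
        df, tsite = _generate_site(cfg, i, inject_q, site_effects)
        records[site] = df
        truth_sites[site] = tsite
    igbp = ["EBF", "GRA", "CRO", "ENF", "DBF", "WET"]
    site_meta = pd.DataFrame({
        "site_id": cfg.site_ids,
        "latitude": cfg.latitudes,
        "longitude": cfg.longitudes,
        "igbp_class": [igbp[i % len(igbp)] for i in range(cfg.n_sites)],
    })
    from .fluxnet_io import SiteMetadata

    meta = pd.DataFrame([
        vars(SiteMetadata.from_row(r.site_id, r.latitude, r.longitude, r.igbp_class))
        for r in site_meta.itertuples()
    ])
    truth = {
        "run_id": f"ratioflux-{cfg.seed}-{cfg.n_sites}-{cfg.years[0]}-{cfg.years[1]}",
        "config": cfg,
        "couplings": cfg.couplings,
        "trends": cfg.trends,
        "lai": dict(zip(cfg.site_ids, cfg.lai)),
        "site_mean_ratio": dict(zip(cfg.site_ids, cfg.site_mean_ratio(cfg.lai))),
        "site_effects": site_effects,
        "polar_fraction": p0,
        "inject_q": inject_q,
        "expected_out_of_range_fraction": target,
        "latent_heat": LATENT_HEAT_VAPORIZATION,
        "sites": truth_sites,
    }
    return records, meta, truth


def truth_lai_table(truth: dict) -> pd.DataFrame:
    return pd.DataFrame({
        "site_id": list(truth["lai"].keys()),
        "lai": list(truth["lai"].values()),
    })


def truth_report(truth: dict, fitted_models: dict, trend_features: dict | None = None,
                 run_id: str | None = None) -> dict:
    """Recovery metrics of fitted artifacts against the generator truth.

    ``fitted_models`` maps variable -> CouplingModel fitted on the same run;
    reports RMSE between fitted and true curves (on a RATIO grid restricted
    to the fit domain) both absolute and as a fraction of the true curve's
    range, plus peak errors; ``trend_features`` (from curve_features) adds
    zero-crossing and vertex errors against the prescribed Ta-day profile.
    """
    from .errors import IntegrityError

    if run_id is not None and run_id != truth["run_id"]:
        raise IntegrityError(f"run id mismatch: {run_id} != {truth['run_id']}")
    report: dict = {"run_id": truth["run_id"], "couplings": {}}
    for var, model in fitted_models.items():
        spec = truth["couplings"].get(var)
        if spec is None:
            continue
        lo, hi = model.fit_domain
        grid = np.linspace(lo, hi, 501)
        true_vals = coupling_value(spec, grid)
        rmse = float(np.sqrt(np.mean((model.predict(grid) - true_vals) ** 2)))
        rng_span = float(np.ptp(true_vals))
        entry = {"rmse": rmse, "rmse_frac_of_range": rmse / rng_span if rng_span else np.nan}
        if spec["kind"] == "unimodal":
            from .coupling import peak_location

            est, flagged = peak_location(model)
            entry.update(true_peak=spec["peak"], est_peak=est,
                         peak_error=abs(est - spec["peak"]), boundary=flagged)
        report["couplings"][var] = entry
    if trend_features is not None:
        prof = np.asarray(truth["trends"]["ta_day"], dtype=float)
        xs = np.linspace(0, 1, 2001)
        slopes = np.interp(xs, prof[:, 0], prof[:, 1])
        sign_change = np.flatnonzero(np.sign(slopes[:-1]) * np.sign(slopes[1:]) < 0)
        true_cross = float(xs[sign_change[0]]) if len(sign_change) else np.nan
        true_vertex = float(xs[np.argmax(slopes)])
        crossings = trend_features.get("zero_crossings", [])
        est_cross = min(crossings, key=lambda c: abs(c - true_cross)) if crossings else np.nan
        report["trend"] = {
            "true_zero_crossing": true_cross,
            "est_zero_crossing": est_cross,
            "crossing_error": abs(est_cross - true_cross) if crossings else np.nan,
            "true_vertex": true_vertex,
            "est_vertex": trend_features.get("vertex", np.nan),
            "vertex_error": abs(trend_features.get("vertex", np.nan) - true_vertex),
        }
    return report


# --- FLUXNET-dialect serialisation ----------------------------------------

_CANON_TO_RAW = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}


def write_fluxnet_csv(df: pd.DataFrame, path) -> None:
    """Write a canonical half-hourly frame as a FLUXNET2015-dialect CSV."""
    out = df.drop(columns=["site_id"]).copy()
    ts = out.pop("timestamp")
    encoded = pd.DataFrame({
        "TIMESTAMP_START": ts.dt.strftime("%Y%m%d%H%M"),
    })
    for col in out.columns:
        raw = _CANON_TO_RAW.get(col)
        if raw is None:
            continue
        encoded[raw] = out[col].fillna(MISSING_SENTINEL)
    encoded.to_csv(path, index=False, float_format="%.4f")


def write_network(records: dict, site_meta: pd.DataFrame, truth: dict, outdir) -> None:
    """Write per-site CSVs, site metadata and a JSON truth file to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for site, df in records.items():
        write_fluxnet_csv(df, outdir / f"FLX_{site}_HH.csv")
    site_meta.to_csv(outdir / "site_metadata.csv", index=False)
    cfg = truth["config"]
    serializable = {
        "run_id": truth["run_id"],
        "config": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in asdict(cfg).items()},
        "couplings": truth["couplings"],
        "trends": truth["trends"],
        "lai": truth["lai"],
        "site_mean_ratio": truth["site_mean_ratio"],
        "site_effects": {k: v.tolist() for k, v in truth["site_effects"].items()},
        "polar_fraction": truth["polar_fraction"],
        "inject_q": truth["inject_q"],
        "expected_out_of_range_fraction": truth["expected_out_of_range_fraction"],
        "latent_heat": truth["latent_heat"],
    }
    (outdir / "truth.json").write_text(json.dumps(serializable, indent=1, default=float))
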