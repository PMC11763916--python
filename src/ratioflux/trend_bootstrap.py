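"""Bootstrap distributions of temporal-trend coefficients per RATIO bin.

For each RATIO sub-interval (50 by default) the site-days falling in the bin
are bootstrap-resampled (B samples of 4000 records, each required to contain
at least 10 distinct sites). Each sample is regressed against calendar year
and summarised by the signed coefficient r = sign(slope) * sqrt(R^2) — for a
straight-line fit this is the Pearson correlation with year. The per-bin
distribution of r across samples forms the trend curve, read against the
two-sided critical value of r for the number of years spanned (0.47 for 18
years at alpha = 0.05).

Default regression unit: within each bootstrap sample the records are
averaged per year and the annual means are regressed on year, so the fit has
one point per year and the n-year critical band applies directly.
``regression="records"`` regresses the raw sampled records instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coupling import assign_bins
from .errors import ConfigurationError, ParameterError, ValidationError


@dataclass(frozen=True)
class BootstrapSpec:
    """Parameters of the constrained bootstrap."""

    n_bins: int = 50
    B: int = 1000
    sample_size: int = 4000
    min_unique_sites: int = 10
    year_range: tuple[int, int] = (1997, 2014)
    alpha: float = 0.05
    seed: int = 0
    max_redraws: int = 100

    def __post_init__(self):
        if self.B < 1:
            raise ParameterError("B must be >= 1")
        if self.sample_size < self.min_unique_sites:
            raise ParameterError("sample_size must be >= min_unique_sites")


def critical_r(n_points: int, alpha: float = 0.05) -> float:
    """Two-sided critical Pearson r for a trend over ``n_points`` observations.

    r_crit = t_crit / sqrt(t_crit^2 + n - 2) with the t quantile at
    1 - alpha/2 on n - 2 degrees of freedom. For 18 years at alpha = 0.05
    this is 0.468, the +-0.47 significance band.
    """
    if n_points < 3:
        raise ParameterError(f"need at least 3 points, got {n_points}")
    t = stats.t.ppf(1.0 - alpha / 2.0, n_points - 2)
    return float(t / np.sqrt(t * t + n_points - 2))


def signed_r(slope: float, r_squared: float) -> float:
    """Signed trend coefficient r = sign(slope) * sqrt(R^2); 0 when slope is 0."""
    if not 0.0 <= r_squared <= 1.0 + 1e-12:
        raise ValidationError(f"r_squared {r_squared} outside [0, 1]")
    if slope == 0.0:
        return 0.0
    return float(np.sign(slope) * np.sqrt(min(r_squared, 1.0)))


@dataclass
class TrendCurve:
    """Per-bin bootstrap distribution of signed trend coefficients."""

    variable: str
    bin_centers: np.ndarray  # all n_bins centres
    r_samples: np.ndarray  # (n_bins, B), NaN rows for skipped bins
    critical_r: float
    spec: BootstrapSpec
    skipped_bins: list[int] = field(default_factory=list)

    @property
    def populated(self) -> np.ndarray:
        return ~np.all(np.isnan(self.r_samples), axis=1)

    def summary(self, statistic=np.nanmedian) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return statistic(self.r_samples, axis=1)

    def quantiles(self, qs=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
        import warnings

        out = pd.DataFrame({"bin_center": self.bin_centers})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for q in qs:
                out[f"q{int(q * 100):02d}"] = np.nanquantile(self.r_samples, q, axis=1)
            ok = self.populated
            pos = np.full(len(self.bin_centers), np.nan)
            neg = np.full(len(self.bin_centers), np.nan)
            pos[ok] = np.nanmean(self.r_samples[ok] > self.critical_r, axis=1)
            neg[ok] = np.nanmean(self.r_samples[ok] < -self.critical_r, axis=1)
        out["frac_sig_pos"] = pos
        out["frac_sig_neg"] = neg
        return out


def _unique_counts_per_row(codes: np.ndarray) -> np.ndarray:
    """Distinct values per row of an integer matrix."""
    s = np.sort(codes, axis=1)
    return 1 + (np.diff(s, axis=1) != 0).sum(axis=1)


def _sample_r(values, year_idx, idx, n_years, regression):
    """Signed r per bootstrap sample (rows of ``idx``)."""
    B = idx.shape[0]
    v = values[idx]
    if regression == "records":
        y = year_idx[idx].astype(float)
        vy_mean = (v * y).mean(axis=1)
        v_mean = v.mean(axis=1)
        y_mean = y.mean(axis=1)
        cov = vy_mean - v_mean * y_mean
        sv = v.std(axis=1)
        sy = y.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where((sv > 0) & (sy > 0), cov / (sv * sy), 0.0)
        return r
    # annual-mean regression: scatter-add sampled records into (B, n_years)
    yk = year_idx[idx]
    rows = np.repeat(np.arange(B), idx.shape[1])
    sums = np.zeros((B, n_years))
    counts = np.zeros((B, n_years))
    np.add.at(sums, (rows, yk.ravel()), v.ravel())
    np.add.at(counts, (rows, yk.ravel()), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    years = np.arange(n_years, dtype=float)
    ok = counts > 0
    n_ok = ok.sum(axis=1)
    ym = np.where(ok, means, 0.0)
    yr = np.where(ok, years, 0.0)
    mean_v = ym.sum(axis=1) / n_ok
    mean_y = yr.sum(axis=1) / n_ok
    cov = (ym * yr).sum(axis=1) / n_ok - mean_v * mean_y
    var_v = (ym * ym).sum(axis=1) / n_ok - mean_v**2
    var_y = (yr * yr).sum(axis=1) / n_ok - mean_y**2
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((var_v > 0) & (var_y > 0), cov / np.sqrt(var_v * var_y), 0.0)
    return r


def bootstrap_trends(
    summaries: pd.DataFrame,
    variable: str,
    spec: BootstrapSpec | None = None,
    regression: str = "annual_mean",
) -> TrendCurve:
    """Bootstrap the temporal trend of ``variable`` in each RATIO bin.

    Bins whose records come from fewer than ``min_unique_sites`` distinct
    sites are skipped. Within processed bins, samples are redrawn (up to
    ``max_redraws`` rounds) until every sample contains at least that many
    distinct sites. Per-bin RNG streams are derived from (seed, bin index)
    so bins are independently reproducible and row order is irrelevant.
    """
    spec = spec or BootstrapSpec()
    if variable not in summaries.columns:
        raise ConfigurationError(f"variable {variable!r} not in summaries")
    if regression not in ("annual_mean", "records"):
        raise ParameterError(f"unknown regression unit {regression!r}")
    y0, y1 = spec.year_range
    pool = summaries.dropna(subset=[variable, "ratio"])
    pool = pool[(pool["year"] >= y0) & (pool["year"] <= y1)]
    if pool["year"].nunique() < 3:
        raise ParameterError("summaries must span at least 3 distinct years")
    # canonical row order so results do not depend on how rows arrive
    pool = pool.sort_values(["site_id", "date", "ratio", variable]).reset_index(drop=True)

    bins = assign_bins(pool["ratio"].to_numpy(), spec.n_bins)
    values = pool[variable].to_numpy(dtype=float)
    year_idx = (pool["year"].to_numpy(dtype=np.int64) - y0)
    n_years = y1 - y0 + 1
    site_codes = pd.factorize(pool["site_id"].to_numpy(), sort=True)[0]

    centers = (np.arange(spec.n_bins) + 0.5) / spec.n_bins
    r_all = np.full((spec.n_bins, spec.B), np.nan)
    skipped: list[int] = []
    for b in range(spec.n_bins):
        mask = bins == b
        n = int(mask.sum())
        if n == 0 or len(np.unique(site_codes[mask])) < spec.min_unique_sites:
            skipped.append(b)
            continue
        rng = np.random.default_rng([spec.seed, b])
        idx_local = rng.integers(0, n, size=(spec.B, spec.sample_size))
        loc = np.flatnonzero(mask)
        sites_b = site_codes[loc]
        bad = _unique_counts_per_row(sites_b[idx_local]) < spec.min_unique_sites
        redraws = 0
        while bad.any() and redraws < spec.max_redraws:
            idx_local[bad] = rng.integers(0, n, size=(int(bad.sum()), spec.sample_size))
            bad = _unique_counts_per_row(sites_b[idx_local]) < spec.min_unique_sites
            redraws += 1
        idx = loc[idx_local]
        r = _sample_r(values, year_idx, idx, n_years, regression)
        if bad.any():
            r[bad] = np.nan  # unsatisfiable samples after the redraw cap
        r_all[b] = r
    if len(skipped) == spec.n_bins:
        raise ParameterError("no bin satisfies the unique-site constraint")
    n_year_points = n_years if regression == "annual_mean" else spec.sample_size
    return TrendCurve(
        variable=variable,
        bin_centers=centers,
        r_samples=r_all,
        critical_r=critical_r(n_year_points, spec.alpha),
        spec=spec,
        skipped_bins=skipped,
    )


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks symmetrically at the edges
    so a parabola's vertex (and any symmetric feature) is preserved."""
    if window <= 1:
        return y
    half = window // 2
    out = np.empty_like(y)
    for i in range(len(y)):
        k = min(i, len(y) - 1 - i, half)
        out[i] = y[i - k:i + k + 1].mean()
    return out


def curve_features(
    curve: TrendCurve,
    statistic=np.nanmedian,
    smooth_window: int = 3,
    vertex_delta: float = 0.10,
) -> dict:
    """Zero-crossings, vertex and slope-regime breakpoints of the trend curve.

    The per-bin summary (median by default) is lightly smoothed (centred
    moving average over ``smooth_window`` bins) before feature extraction,
    damping bin-level bootstrap noise. Crossings come from linear
    interpolation between adjacent bin centres. The vertex is the apex of a
    quadratic fitted to the top region of the curve — the bins whose
    smoothed summary lies within ``vertex_delta`` of the maximum (at least
    five bins) — which is robust to bin noise and preserves a parabolic
    apex to within a small fraction of a bin; the argmax bin centre is
    used when the local fit is not
    concave or its apex leaves the region. Breakpoints are bin centres
    where the curvature of the smoothed summary changes sign, reported
    descriptively.
    """
    s = curve.summary(statistic)
    ok = curve.populated & np.isfinite(s)
    if ok.sum() < 5:
        raise ParameterError("need at least 5 populated bins")
    x = curve.bin_centers[ok]
    y = _moving_average(s[ok], smooth_window)
    crossings = []
    for i in range(len(y) - 1):
        if y[i] == 0.0:
            crossings.append(float(x[i]))
        elif y[i] * y[i + 1] < 0.0:
            frac = y[i] / (y[i] - y[i + 1])
            crossings.append(float(x[i] + frac * (x[i + 1] - x[i])))
    vertex = float(x[int(np.argmax(y))])
    top = y >= y.max() - vertex_delta
    if top.sum() < 5:
        top = np.zeros(len(y), dtype=bool)
        top[np.argsort(y)[-min(5, len(y)):]] = True
    if top.sum() >= 3:
        c2, c1, _ = np.polyfit(x[top], y[top], 2)
        if c2 < 0:
            apex = -c1 / (2.0 * c2)
            if x[top].min() <= apex <= x[top].max():
                vertex = float(apex)
    d2 = np.diff(y, 2)
    sign_change = np.flatnonzero(np.sign(d2[:-1]) * np.sign(d2[1:]) < 0)
    breakpoints = [float(x[i + 2]) for i in sign_change]
    return {"zero_crossings": crossings, "vertex": vertex, "breakpoints": breakpoints}


def null_rejection_rate(
    n_years: int = 18,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo type-I-error rate of the |r| > critical_r band.

    Each replicate draws ``n_years`` independent annual means from a
    zero-trend Gaussian and regresses them on year; the rejection fraction
    across B independent replicates is Binomial(B, alpha)/B by construction,
    so this calibrates the significance band. (Bootstrap resampling within a
    fixed bin pool cannot be used for this check: its rejection rate is
    conditional on the pool's own empirical trend.)
    """
    rng = np.random.default_rng(seed)
    years = np.arange(n_years, dtype=float)
    y = rng.standard_normal((B, n_years))
    yc = y - y.mean(axis=1, keepdims=True)
    xc = years - years.mean()
    r = (yc @ xc) / (np.sqrt((yc**2).sum(axis=1)) * np.sqrt((xc**2).sum()))
    return float(np.mean(np.abs(r) > critical_r(n_years, alpha)))
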