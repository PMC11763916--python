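"""Coupling curves between EC variables and the daily RATIO.

The RATIO axis is divided into uniform sub-intervals (200 by default), the
variable is averaged per bin, and a curve is fitted to the (bin centre, bin
mean) pairs weighted by bin counts — either a polynomial (default degree 6)
or a random forest. Fitting on bin means rather than raw site-days follows
the binning-first protocol; ``fit_raw`` switches to raw-data fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from sklearn.ensemble import RandomForestRegressor

from .errors import FitError, ParameterError

#: Variables whose coupling curve has an interior minimum rather than maximum.
MINIMUM_VARIABLES = {"nee", "nee_day"}


@dataclass
class BinnedSeries:
    """Per-RATIO-bin means of one variable for one group."""

    variable: str
    group: str
    bin_edges: np.ndarray
    bin_means: np.ndarray  # NaN where the bin is empty
    bin_counts: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def populated(self) -> np.ndarray:
        return self.bin_counts > 0


def assign_bins(ratio: np.ndarray, n_bins: int) -> np.ndarray:
    """Uniform half-open bins [k/n, (k+1)/n) over [0, 1], last bin closed."""
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    ratio = np.asarray(ratio, dtype=float)
    idx = np.floor(ratio * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def bin_by_ratio(
    summaries: pd.DataFrame,
    variable: str,
    n_bins: int = 200,
    group_by: str | None = None,
) -> dict[str, BinnedSeries]:
    """Bin one variable by the daily RATIO, optionally per group column.

    Returns a dict keyed by group label ("all" when ``group_by`` is None).
    Rows with a missing variable value are dropped before binning.
    """
    if variable not in summaries.columns:
        raise ParameterError(f"variable {variable!r} not in summaries")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    pool = summaries.dropna(subset=[variable, "ratio"])
    groups = {"all": pool} if group_by is None else dict(tuple(pool.groupby(group_by)))
    out: dict[str, BinnedSeries] = {}
    for label, sub in groups.items():
        idx = assign_bins(sub["ratio"].to_numpy(), n_bins)
        vals = sub[variable].to_numpy(dtype=float)
        counts = np.bincount(idx, minlength=n_bins)
        sums = np.bincount(idx, weights=vals, minlength=n_bins)
        means = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
        out[str(label)] = BinnedSeries(variable, str(label), edges, means, counts)
    return out


@dataclass
class CouplingModel:
    """Fitted curve of one EC variable versus the daily RATIO."""

    variable: str
    group: str
    family: str  # "polynomial" | "random_forest"
    fit_domain: tuple[float, float]
    goodness: float  # count-weighted R^2 on training bins
    _poly: Polynomial | None = field(default=None, repr=False)
    _forest: RandomForestRegressor | None = field(default=None, repr=False)

    def predict(self, ratio) -> np.ndarray:
        x = np.asarray(ratio, dtype=float)
        if self.family == "polynomial":
            return self._poly(x)
        return self._forest.predict(x.reshape(-1, 1))

    def in_domain(self, ratio) -> np.ndarray:
        x = np.asarray(ratio, dtype=float)
        lo, hi = self.fit_domain
        return (x >= lo) & (x <= hi)

    @property
    def coefficients(self) -> np.ndarray | None:
        """Power-basis polynomial coefficients (ascending), if polynomial."""
        if self._poly is None:
            return None
        return self._poly.convert().coef


def _weighted_r2(y, yhat, w):
    w = w / w.sum()
    resid = np.sum(w * (y - yhat) ** 2)
    total = np.sum(w * (y - np.sum(w * y)) ** 2)
    if total == 0.0:
        return 1.0 if resid == 0.0 else 0.0
    return float(1.0 - resid / total)


def fit_coupling_curve(
    binned: BinnedSeries,
    family: str = "polynomial",
    degree: int = 6,
    n_estimators: int = 500,
    seed: int = 0,
) -> CouplingModel:
    """Fit a coupling curve to populated bins, count-weighted.

    Polynomial fits use weighted least squares on (bin centre, bin mean);
    random forests use sklearn with a fixed ``random_state`` so refits are
    reproducible. Requires at least max(degree + 1, 5) populated bins.
    """
    ok = binned.populated & np.isfinite(binned.bin_means)
    x = binned.bin_centers[ok]
    y = binned.bin_means[ok]
    w = binned.bin_counts[ok].astype(float)
    needed = max(degree + 1, 5) if family == "polynomial" else 5
    if ok.sum() < needed:
        raise FitError(
            f"{binned.variable}/{binned.group}: {int(ok.sum())} populated bins < {needed} required"
        )
    domain = (float(x.min()), float(x.max()))
    if family == "polynomial":
        # numpy applies weights to residuals, so pass sqrt of counts
        poly = Polynomial.fit(x, y, deg=degree, w=np.sqrt(w))
        model = CouplingModel(binned.variable, binned.group, family, domain, 0.0, _poly=poly)
    elif family == "random_forest":
        forest = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
        forest.fit(x.reshape(-1, 1), y, sample_weight=w)
        model = CouplingModel(binned.variable, binned.group, family, domain, 0.0, _forest=forest)
    else:
        raise ParameterError(f"unknown family {family!r}")
    model.goodness = _weighted_r2(y, model.predict(x), w)
    return model


def peak_location(
    model: CouplingModel,
    search_grid: Sequence[float] | None = None,
    mode: str | None = None,
) -> tuple[float, bool]:
    """RATIO of the fitted curve's extremum on a grid.

    ``mode`` defaults to "min" for NEE/NEE-day and "max" otherwise. Returns
    (ratio, boundary_flag); the flag is True when the extremum sits on the
    grid boundary, i.e. the curve is monotone over the domain.
    """
    if search_grid is None:
        lo, hi = model.fit_domain
        search_grid = np.linspace(lo, hi, 2001)
    grid = np.asarray(search_grid, dtype=float)
    pred = model.predict(grid)
    if mode is None:
        mode = "min" if model.variable in MINIMUM_VARIABLES else "max"
    i = int(np.argmin(pred)) if mode == "min" else int(np.argmax(pred))
    boundary = i in (0, len(grid) - 1)
    return float(grid[i]), boundary


def between_group_discrepancy(
    binned_j: BinnedSeries,
    binned_k: BinnedSeries,
    low_ratio_cutoff: float = 0.7,
) -> pd.DataFrame:
    """Per-bin |mean_j - mean_k| profile for two groups binned on equal edges.

    The returned frame carries an ``abs_diff`` column over jointly populated
    bins; ``.attrs["mean_below_cutoff"]`` summarises bins with centre below
    ``low_ratio_cutoff`` (the regime where flux magnitudes across ecosystems
    are expected to be nearly equal).
    """
    if (len(binned_j.bin_edges) != len(binned_k.bin_edges)
            or not np.allclose(binned_j.bin_edges, binned_k.bin_edges)):
        raise ParameterError("groups must be binned on identical edges")
    both = binned_j.populated & binned_k.populated
    centers = binned_j.bin_centers[both]
    diff = np.abs(binned_j.bin_means[both] - binned_k.bin_means[both])
    out = pd.DataFrame({"bin_center": centers, "abs_diff": diff})
    low = centers < low_ratio_cutoff
    out.attrs["mean_below_cutoff"] = float(diff[low].mean()) if low.any() else float("nan")
    if len(out) == 0:
        import logging

        logging.getLogger(__name__).warning(
            "%s: groups %s and %s share no populated bins",
            binned_j.variable, binned_j.group, binned_k.group,
        )
    return out
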