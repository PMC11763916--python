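"""Mapping EC observations across places via the daily RATIO.

At equal daily RATIO the magnitude of an EC variable is approximately the
same in any two ecosystems, so a coupling curve fitted in a source region
(e.g. the Western Hemisphere) evaluated at a target region's observed daily
RATIOs predicts the target's daily values. Quality is summarised per
land-cover group as Pearson r, its two-sided p-value, RMSE and n.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .coupling import CouplingModel
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


def map_observations(
    source_models: dict[str, CouplingModel],
    target_summaries: pd.DataFrame,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Predict target site-day values from source coupling curves.

    Returns a long frame (site_id, date, ratio, variable, predicted,
    observed). Target ratios outside a model's fit domain are excluded and
    counted in ``.attrs["n_out_of_domain"]``.
    """
    if variables is None:
        variables = [v for v in source_models if v in target_summaries.columns]
    missing = [v for v in variables if v not in source_models]
    if missing:
        raise ConfigurationError(f"no source model for variables: {missing}")
    ratio = target_summaries["ratio"].to_numpy(dtype=float)
    pieces = []
    n_out = 0
    for var in variables:
        model = source_models[var]
        ok = model.in_domain(ratio) & np.isfinite(target_summaries[var].to_numpy(dtype=float))
        n_out += int((~model.in_domain(ratio)).sum())
        sub = target_summaries.loc[ok, ["site_id", "date", "ratio", var]].copy()
        sub = sub.rename(columns={var: "observed"})
        sub["variable"] = var
        sub["predicted"] = model.predict(sub["ratio"].to_numpy())
        pieces.append(sub)
    out = pd.concat(pieces, ignore_index=True)
    out.attrs["n_out_of_domain"] = n_out
    if n_out:
        logger.info("excluded %d out-of-domain target ratios", n_out)
    return out


def evaluate_mapping(
    mapped: pd.DataFrame,
    site_groups: pd.DataFrame | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-variable, per-group prediction quality.

    ``site_groups`` maps site_id -> group (land-cover); an "all" group is
    always included. Groups with fewer than ``min_pairs`` pairs, or with zero
    variance in either vector, are reported with r/p absent and a reason.
    """
    df = mapped
    if site_groups is not None:
        lookup = site_groups.set_index("site_id")["group"]
        df = df.assign(group=df["site_id"].map(lookup))
    rows = []
    for var, sub in df.groupby("variable"):
        blocks = [("all", sub)]
        if "group" in sub.columns:
            blocks += list(sub.groupby("group"))
        for label, block in blocks:
            pred = block["predicted"].to_numpy(dtype=float)
            obs = block["observed"].to_numpy(dtype=float)
            n = len(block)
            row = {"variable": var, "group": str(label), "n": n,
                   "r": np.nan, "p_value": np.nan, "rmse": np.nan, "reason": ""}
            if n < min_pairs:
                row["reason"] = f"fewer than {min_pairs} pairs"
            elif np.std(pred) == 0.0 or np.std(obs) == 0.0:
                row["reason"] = "zero variance"
                row["rmse"] = float(np.sqrt(np.mean((pred - obs) ** 2)))
            else:
                r, p = stats.pearsonr(pred, obs)
                row.update(r=float(r), p_value=float(p),
                           rmse=float(np.sqrt(np.mean((pred - obs) ** 2))))
            rows.append(row)
    return pd.DataFrame(rows)
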