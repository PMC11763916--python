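"""Shared fixtures: synthetic networks at two scales and a hand-built day.

The small network (8 sites, 4 years) backs most unit tests; the default-size
network (30 sites, 18 years) is generated once per session and shared by the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ratioflux import pipeline, ratio_core, synthetic, trend_bootstrap


@pytest.fixture(scope="session")
def small_net():
    cfg = synthetic.SyntheticConfig(n_sites=8, years=(2001, 2004), seed=11)
    summaries, meta, truth = pipeline.simulate_summaries(cfg)
    return summaries, meta, truth


@pytest.fixture(scope="session")
def small_kept(small_net):
    summaries, meta, truth = small_net
    kept, discarded = ratio_core.filter_ratio(summaries)
    return kept


@pytest.fixture(scope="session")
def default_net():
    cfg = synthetic.SyntheticConfig(seed=7)
    summaries, meta, truth = pipeline.simulate_summaries(cfg)
    return summaries, meta, truth


@pytest.fixture(scope="session")
def default_kept(default_net):
    summaries, meta, truth = default_net
    kept, discarded = ratio_core.filter_ratio(summaries)
    return kept, discarded, len(summaries[summaries["valid"]])


@pytest.fixture(scope="session")
def tady_curve(default_kept):
    kept, _, _ = default_kept
    spec = trend_bootstrap.BootstrapSpec(B=200, seed=7)
    return trend_bootstrap.bootstrap_trends(kept, "ta_day", spec)


def make_day(le_day=10.0, le_night=2.0, n_day=24, site_id="XX-Tst", date="2005-06-01",
             extra: dict | None = None) -> pd.DataFrame:
    """One hand-built site-day of 48 half-hourly records.

    ``le_day``/``le_night`` are per-period totals spread uniformly over the
    period's slots; sw_in_pot marks the first ``n_day`` afternoon-centred
    slots as day. ``extra`` maps column -> per-slot array.
    """
    ts = pd.date_range(date, periods=48, freq="30min")
    day = np.zeros(48, dtype=bool)
    start = (48 - n_day) // 2
    day[start:start + n_day] = True
    le = np.where(day, le_day / max(n_day, 1), 0.0)
    if n_day < 48:
        le = np.where(~day, le_night / (48 - n_day), le)
    df = pd.DataFrame({
        "site_id": site_id,
        "timestamp": ts,
        "le": le,
        "sw_in_pot": np.where(day, 400.0, 0.0),
    })
    for col, vals in (extra or {}).items():
        df[col] = vals
    return df
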