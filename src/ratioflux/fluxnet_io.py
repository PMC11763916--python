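"""Reading and validating FLUXNET2015-dialect tables.

The FLUXNET2015 FULLSET product ships one CSV per site and resolution, with
``TIMESTAMP_START``-style time columns (``YYYYMMDDHHMM`` integers), ``-9999``
missing sentinels and product-specific variable names (``LE_F_MDS``,
``NEE_VUT_REF``, ...). This module maps those names onto the 15 canonical
variable roles used throughout the package and decodes the sentinels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ValidationError

logger = logging.getLogger(__name__)

MISSING_SENTINEL = -9999.0

#: Default FLUXNET2015 FULLSET column names -> canonical roles. VUT reference
#: NEE and night-time (NT) partitioned GPP/RECO; users can override any entry.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "TIMESTAMP_START": "timestamp",
    "LE_F_MDS": "le",
    "NEE_VUT_REF": "nee",
    "RECO_NT_VUT_REF": "reco",
    "GPP_NT_VUT_REF": "gpp",
    "TA_F": "ta",
    "VPD_F": "vpd",
    "NETRAD": "rn",
    "P_F": "precip",
    "CO2_F_MDS": "co2",
    "SWC_F_MDS_1": "swc",
    "SW_IN_POT": "sw_in_pot",
    "SW_IN_F": "sw_in",
    "WS_F": "ws",
}

#: IGBP land-cover code -> analysis group. Forests collapse to "forest",
#: croplands to "cropland", everything else (shrubland, savanna, grassland,
#: wetland, ...) to "other".
IGBP_GROUP: dict[str, str] = {
    "ENF": "forest",
    "EBF": "forest",
    "DNF": "forest",
    "DBF": "forest",
    "MF": "forest",
    "CRO": "cropland",
    "CSH": "other",
    "OSH": "other",
    "WSA": "other",
    "SAV": "other",
    "GRA": "other",
    "WET": "other",
    "SNO": "other",
    "BSV": "other",
    "URB": "other",
    "WAT": "other",
}


def climate_zone(latitude: float) -> str:
    """Climate zone from the absolute-latitude bands 0-23 / 23-35 / 35-60 / >60."""
    a = abs(latitude)
    if a > 90.0:
        raise ValidationError(f"latitude {latitude} out of [-90, 90]")
    if a < 23.0:
        return "tropical"
    if a < 35.0:
        return "subtropical"
    if a <= 60.0:
        return "temperate"
    return "boreal"


@dataclass(frozen=True)
class SiteMetadata:
    """Static description of one flux-tower site."""

    site_id: str
    latitude: float
    longitude: float
    igbp_class: str
    group: str
    hemisphere: str
    climate_zone: str

    @classmethod
    def from_row(cls, site_id, latitude, longitude, igbp_class) -> "SiteMetadata":
        latitude = float(latitude)
        longitude = float(longitude)
        if not -90.0 <= latitude <= 90.0:
            raise ValidationError(f"{site_id}: latitude {latitude} out of [-90, 90]")
        if not -180.0 <= longitude <= 180.0:
            raise ValidationError(f"{site_id}: longitude {longitude} out of [-180, 180]")
        igbp = str(igbp_class).upper()
        return cls(
            site_id=str(site_id),
            latitude=latitude,
            longitude=longitude,
            igbp_class=igbp,
            group=IGBP_GROUP.get(igbp, "other"),
            hemisphere="eastern" if longitude >= 0.0 else "western",
            climate_zone=climate_zone(latitude),
        )


def read_site_metadata(path) -> pd.DataFrame:
    """Read a site-metadata CSV (site_id, latitude, longitude, igbp_class).

    Returns a DataFrame with derived ``group``, ``hemisphere`` and
    ``climate_zone`` columns, one row per site.
    """
    raw = pd.read_csv(path)
    required = {"site_id", "latitude", "longitude", "igbp_class"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"site metadata missing columns: {sorted(missing)}")
    rows = [
        SiteMetadata.from_row(r.site_id, r.latitude, r.longitude, r.igbp_class)
        for r in raw.itertuples()
    ]
    return pd.DataFrame([vars(m) for m in rows])


def site_metadata_frame(sites: list[SiteMetadata]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in sites])


def _decode_missing(df: pd.DataFrame) -> pd.DataFrame:
    numeric = df.select_dtypes(include=[np.number]).columns
    df[numeric] = df[numeric].mask(df[numeric] <= MISSING_SENTINEL + 0.5)
    return df


def read_half_hourly(
    path,
    column_map: Mapping[str, str] | None = None,
    site_id: str | None = None,
    min_qc: int | None = None,
) -> pd.DataFrame:
    """Read one site's half-hourly FULLSET CSV into canonical columns.

    Parameters
    ----------
    path
        CSV file with a ``TIMESTAMP_START`` column at 30-min resolution.
    column_map
        Raw-name -> canonical-name mapping; defaults to the FULLSET dialect.
        Unmapped columns are dropped with a logged warning.
    site_id
        Site code attached to every record; defaults to the file stem's first
        dash-separated tokens (``FLX_AT-Neu_...`` -> ``AT-Neu``) or the stem.
    min_qc
        If given, values whose ``*_QC`` companion column exceeds this level
        are set missing. Default keeps all non-missing values.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    raw = pd.read_csv(path)
    ts_col = next((k for k, v in cmap.items() if v == "timestamp"), "TIMESTAMP_START")
    if ts_col not in raw.columns:
        raise FormatError(f"{path}: timestamp column {ts_col!r} absent")
    if not any(raw.columns.isin([k for k, v in cmap.items() if v == "le"])):
        raise FormatError(f"{path}: no LE column found")

    if min_qc is not None:
        for rawname, canon in cmap.items():
            qc = f"{rawname}_QC"
            if rawname in raw.columns and qc in raw.columns:
                bad = pd.to_numeric(raw[qc], errors="coerce") > min_qc
                raw.loc[bad, rawname] = np.nan

    known = [c for c in raw.columns if c in cmap]
    ignored = [c for c in raw.columns if c not in cmap and not c.endswith("_QC")]
    if ignored:
        logger.warning("%s: ignoring unmapped columns %s", path, ignored)
    df = raw[known].rename(columns=cmap)
    df["timestamp"] = pd.to_datetime(df["timestamp"].astype("int64").astype(str), format="%Y%m%d%H%M")
    if df["timestamp"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate timestamps")
    if not df["timestamp"].is_monotonic_increasing:
        raise IntegrityError(f"{path}: timestamps not increasing")
    df = _decode_missing(df)
    if site_id is None:
        stem = Path(path).stem
        parts = stem.split("_")
        site_id = parts[1] if len(parts) > 1 and "-" in parts[1] else stem
    df.insert(0, "site_id", site_id)
    return df


def read_daily(path, column_map: Mapping[str, str] | None = None, site_id: str | None = None) -> pd.DataFrame:
    """Read a FLUXNET daily CSV (TIMESTAMP column, one row per day)."""
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    cmap.pop("TIMESTAMP_START", None)
    cmap["TIMESTAMP"] = "date"
    raw = pd.read_csv(path)
    if "TIMESTAMP" not in raw.columns:
        raise FormatError(f"{path}: TIMESTAMP column absent")
    df = raw[[c for c in raw.columns if c in cmap]].rename(columns=cmap)
    df["date"] = pd.to_datetime(df["date"].astype("int64").astype(str), format="%Y%m%d")
    if df["date"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate dates")
    df = _decode_missing(df)
    if site_id is not None:
        df.insert(0, "site_id", site_id)
    return df


def to_long_format(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize a canonical wide table to (site_id, timestamp, variable, value)."""
    value_cols = [c for c in df.columns if c not in ("site_id", "timestamp")]
    return df.melt(id_vars=["site_id", "timestamp"], value_vars=value_cols,
                   var_name="variable", value_name="value")


def check_orphans(records: pd.DataFrame, metadata: pd.DataFrame) -> list[str]:
    """Return (and log) record site_ids with no metadata entry."""
    known = set(metadata["site_id"])
    orphans = sorted(set(records["site_id"]) - known)
    for site in orphans:
        logger.warning("records for %s have no site metadata entry", site)
    return orphans
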