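"""Solar geometry helpers: declination, day length, potential shortwave.

Standard astronomical approximations (Cooper declination, FAO-56 extraterrestrial
radiation) shared by the synthetic generator and the PET calculation. All angles
internal to the module are radians; public signatures take degrees latitude and
day-of-year.
"""

from __future__ import annotations

import numpy as np

SOLAR_CONSTANT = 1361.0  # W m-2
_GSC_FAO = 0.0820  # MJ m-2 min-1, FAO-56 solar constant


def solar_declination(doy):
    """Solar declination in radians for day-of-year ``doy`` (Cooper 1969)."""
    doy = np.asarray(doy, dtype=float)
    return np.deg2rad(23.44) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)


def sunset_hour_angle(latitude_deg, doy):
    """Sunset hour angle (radians), clipped for polar day/night."""
    phi = np.deg2rad(np.asarray(latitude_deg, dtype=float))
    dec = solar_declination(doy)
    cos_w = -np.tan(phi) * np.tan(dec)
    return np.arccos(np.clip(cos_w, -1.0, 1.0))


def day_length_hours(latitude_deg, doy):
    """Astronomical day length in hours (0 during polar night, 24 polar day)."""
    return sunset_hour_angle(latitude_deg, doy) * 24.0 / np.pi


def potential_shortwave(latitude_deg, doy, hour):
    """Top-of-atmosphere shortwave on a horizontal plane, W m-2.

    ``hour`` is local solar time in hours (fractional). Zero whenever the sun
    is below the horizon, which makes this the daytime indicator used by the
    ``sw_in_pot > 0`` partition rule.
    """
    phi = np.deg2rad(np.asarray(latitude_deg, dtype=float))
    dec = solar_declination(doy)
    hour_angle = np.pi * (np.asarray(hour, dtype=float) - 12.0) / 12.0
    cos_zenith = np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(hour_angle)
    doy = np.asarray(doy, dtype=float)
    s0 = SOLAR_CONSTANT * (1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0))
    return np.maximum(0.0, s0 * cos_zenith)


def extraterrestrial_radiation(latitude_deg, doy):
    """Daily extraterrestrial radiation Ra, MJ m-2 day-1 (FAO-56 eq. 21)."""
    phi = np.deg2rad(np.asarray(latitude_deg, dtype=float))
    doy = np.asarray(doy, dtype=float)
    dec = solar_declination(doy)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    ws = sunset_hour_angle(latitude_deg, doy)
    return (
        (24.0 * 60.0 / np.pi)
        * _GSC_FAO
        * dr
        * (ws * np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.sin(ws))
    )
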