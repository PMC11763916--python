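"""Classifying the surface-temperature effect of a vegetation change.

The Ta-day trend coefficient r rises with the daily RATIO below ~0.90
(rapidly over 0.55-0.75, slowly over 0.75-0.90) and falls above 0.90, so a
vegetation increase (greening), which raises the mean daily RATIO, warms the
surface where the curve rises and cools it where the curve falls. The static
rule table encodes those regimes; browning flips the sign. The classifier
can also read the regimes off a fitted trend curve directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError
from .trend_bootstrap import TrendCurve

#: Regime boundaries of the Ta-day trend curve on the RATIO axis.
REGIME_BOUNDARIES = (0.55, 0.75, 0.90)

_FLIP = {
    "strong warming": "strong cooling",
    "weak warming": "weak cooling",
    "weak cooling": "weak warming",
    "strong cooling": "strong warming",
    "≈ no change": "≈ no change",
}


@dataclass(frozen=True)
class EffectRule:
    """One RATIO interval [lower, upper) and its greening effect label."""

    lower: float
    upper: float
    greening_effect: str
    rationale: str

    def contains(self, ratio: float) -> bool:
        return self.lower <= ratio < self.upper


def default_rules(split_cooling: bool = False) -> list[EffectRule]:
    """The rule table applied zone by zone.

    Intervals are half-open [lower, upper): 0.75 falls in the weak-warming
    regime and 0.90 in the cooling regime. Below 0.75 greening warms
    strongly (0.55 is where the Ta-day trend itself changes sign, recorded
    in the rationale); 0.75-0.90 is the minimal-effect / weak-warming
    plateau; above 0.90 greening cools. ``split_cooling`` separates a weak
    0.90-0.93 from a strong >0.93 cooling band (default off).
    """
    rules = [
        EffectRule(0.0, 0.55, "strong warming",
                   "rising limb of the Ta-day trend curve; trend itself negative below 0.55"),
        EffectRule(0.55, 0.75, "strong warming", "r rises rapidly over 0.55-0.75"),
        EffectRule(0.75, 0.90, "weak warming",
                   "r rises very slowly over 0.75-0.90; minimal effect"),
    ]
    if split_cooling:
        rules += [
            EffectRule(0.90, 0.93, "weak cooling", "early accelerating-cooling limb"),
            EffectRule(0.93, 1.0, "strong cooling", "steep cooling limb above 0.93"),
        ]
    else:
        rules += [
            EffectRule(0.90, 1.0, "strong cooling",
                       "gradually accelerating cooling above 0.90"),
        ]
    return rules


@dataclass(frozen=True)
class EffectLabel:
    """Predicted surface-temperature effect of a vegetation change."""

    mean_ratio: float
    change_sign: str  # greening | browning | none
    effect: str
    rationale: str
    flagged: bool = False


def classify_effect(
    mean_ratio: float,
    change_sign: str,
    rules: list[EffectRule] | None = None,
    split_cooling: bool = False,
) -> EffectLabel:
    """Look up the effect of greening/browning at a given mean daily RATIO."""
    if not 0.0 < mean_ratio < 1.0:
        raise ValidationError(f"mean_ratio {mean_ratio} outside (0, 1)")
    if change_sign not in ("greening", "browning", "none"):
        raise ParameterError(f"change_sign must be greening/browning/none, got {change_sign!r}")
    if change_sign == "none":
        return EffectLabel(mean_ratio, change_sign, "no predicted change", "no vegetation change")
    rules = rules if rules is not None else default_rules(split_cooling=split_cooling)
    rule = next(r for r in rules if r.contains(mean_ratio))
    effect = rule.greening_effect if change_sign == "greening" else _FLIP[rule.greening_effect]
    return EffectLabel(mean_ratio, change_sign, effect, rule.rationale)


def classify_from_trend_curve(
    curve: TrendCurve,
    mean_ratio: float,
    change_sign: str,
    zero_band: float = 0.05,
) -> EffectLabel:
    """Classify from the local slope of a fitted Ta-day trend curve.

    The effect sign is the sign of the curve's local derivative at
    ``mean_ratio`` (times the change sign); the strength label comes from
    terciles of |derivative| over populated bins. Derivatives within
    ``zero_band`` of the curve's near-vertex slope magnitude floor are
    labelled "~ no change" and flagged. Falls back to the static table,
    flagged, when the curve has no interior vertex (monotone summary).
    """
    if not 0.0 < mean_ratio < 1.0:
        raise ValidationError(f"mean_ratio {mean_ratio} outside (0, 1)")
    if change_sign == "none":
        return EffectLabel(mean_ratio, change_sign, "no predicted change", "no vegetation change")
    s = curve.summary()
    ok = curve.populated & np.isfinite(s)
    x = curve.bin_centers[ok]
    y = s[ok]
    if mean_ratio < x.min() or mean_ratio > x.max():
        raise ParameterError(f"mean_ratio {mean_ratio} outside populated bins [{x.min():.2f}, {x.max():.2f}]")
    imax = int(np.argmax(y))
    if imax in (0, len(y) - 1):
        static = classify_effect(mean_ratio, change_sign)
        return EffectLabel(mean_ratio, change_sign, static.effect,
                           "monotone trend curve; static rule table used", flagged=True)
    grad = np.gradient(y, x)
    local = float(np.interp(mean_ratio, x, grad))
    abs_terciles = np.quantile(np.abs(grad), [1.0 / 3.0, 2.0 / 3.0])
    scale = float(np.max(np.abs(grad)))
    if abs(local) < zero_band * scale:
        return EffectLabel(mean_ratio, change_sign, "≈ no change",
                           "query at/near the trend-curve vertex", flagged=True)
    direction = "warming" if local > 0 else "cooling"
    strength = "weak" if abs(local) < abs_terciles[1] else "strong"
    effect = f"{strength} {direction}"
    if change_sign == "browning":
        effect = _FLIP[effect]
    return EffectLabel(mean_ratio, change_sign, effect,
                       f"local trend-curve slope {local:+.2f} per unit RATIO")
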