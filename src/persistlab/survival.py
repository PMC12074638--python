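"""Two-subpopulation survival model: f = s * Pn.

If persisters arise only from the non-growing subpopulation and each
non-growing cell survives exposure with a condition-independent probability
``s``, the persister frequency ``f`` in a population is ``s`` times the
non-growing fraction ``Pn`` at exposure onset. The model is anchored on one
condition (by default the one with the largest Pn), ``s`` is estimated as
``f / Pn`` there with propagated errors, and other conditions are compared
against the predicted band ``[s_lower * Pn, s_upper * Pn]``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from persistlab.dilution import SurvivingFraction
from persistlab.lineage import FractionWithSE

__all__ = [
    "SEstimate",
    "PredictedBand",
    "ConditionRecord",
    "ConditionAssessment",
    "SurvivalModeModel",
    "estimate_s",
    "predict_f",
    "classify_scenario",
    "fit_survival_model",
    "CONSISTENT",
    "BELOW",
    "ABOVE",
]

CONSISTENT = "consistent_with_constant_s"
BELOW = "below_prediction"
ABOVE = "above_prediction"


@dataclass(frozen=True)
class SEstimate:
    """Per-non-growing-cell survival probability with an error range."""

    s: float
    se: float
    lower: float
    upper: float
    method: str
    clamped: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.s <= self.upper):
            raise ValueError("require 0 <= lower <= s <= upper")


def estimate_s(
    f_late: SurvivingFraction,
    pn_late: FractionWithSE,
    method: str = "linear",
) -> SEstimate:
    """Estimate s = f / Pn at the anchoring condition, with propagated error.

    ``method="linear"``: symmetric first-order propagation,
    ``ds = s * sqrt((df/f)^2 + (dPn/Pn)^2)`` with ``df`` half the width of
    the surviving-fraction range.

    ``method="log"``: the range of f is treated as symmetric on the log10
    scale and the Pn error mapped to log scale; the band on s is then
    multiplicative. The convention behind published ranges varies, so both
    variants are exposed.

    The point estimate is clamped to [0, 1] (with a warning) if noise pushes
    the ratio above 1.
    """
    if pn_late.fraction <= 0:
        raise ValueError("Pn must be > 0 to estimate s")
    if f_late.fraction < 0:
        raise ValueError("f must be >= 0")
    s = f_late.fraction / pn_late.fraction
    clamped = False
    if s > 1.0:
        warnings.warn(f"s = {s:.3g} exceeds 1; clamped to 1", stacklevel=2)
        s = 1.0
        clamped = True
    if s == 0.0:
        return SEstimate(s=0.0, se=0.0, lower=0.0, upper=0.0, method=method)

    if method == "linear":
        df = f_late.half_width
        rel = math.sqrt(
            (df / f_late.fraction) ** 2 + (pn_late.se / pn_late.fraction) ** 2
        )
        ds = s * rel
        return SEstimate(
            s=s,
            se=ds,
            lower=max(s - ds, 0.0),
            upper=min(s + ds, 1.0) if clamped else s + ds,
            method=method,
            clamped=clamped,
        )
    if method == "log":
        if f_late.lower <= 0:
            raise ValueError("log method requires a positive lower bound on f")
        se_log_f = math.log10(f_late.upper / f_late.lower) / 2.0
        se_log_pn = pn_late.se / (pn_late.fraction * math.log(10.0))
        se_log = math.sqrt(se_log_f**2 + se_log_pn**2)
        lower = s * 10.0 ** (-se_log)
        upper = s * 10.0**se_log
        return SEstimate(
            s=s,
            se=(upper - lower) / 2.0,
            lower=lower,
            upper=upper,
            method=method,
            clamped=clamped,
        )
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class PredictedBand:
    """Predicted persister frequency with the band induced by the s range."""

    f: float
    lower: float
    upper: float


def predict_f(
    s: SEstimate, pn: float, pn_se: float = 0.0, pn_se_multiplier: float = 1.0
) -> PredictedBand:
    """Predicted persister frequency f = s * Pn with its error band.

    With ``pn_se == 0`` the band is ``[s_lower * Pn, s_upper * Pn]``. When the
    non-growing fraction itself is an estimate, passing its standard error
    widens the band to ``[s_lower * (Pn - m*se), s_upper * (Pn + m*se)]``
    (clipped to [0, 1]) with ``m = pn_se_multiplier``, so that comparisons
    against observed frequencies account for the horizontal error bar as
    well. The default ``m = 1`` mirrors plotted one-SE error bars; use 1.96
    when the observed ranges are 95% intervals.
    """
    if not (0.0 <= pn <= 1.0):
        raise ValueError(f"Pn must be in [0, 1], got {pn}")
    if pn_se < 0:
        raise ValueError("pn_se must be >= 0")
    pn_lo = max(pn - pn_se_multiplier * pn_se, 0.0)
    pn_hi = min(pn + pn_se_multiplier * pn_se, 1.0)
    return PredictedBand(f=s.s * pn, lower=s.lower * pn_lo, upper=s.upper * pn_hi)


def classify_scenario(observed: SurvivingFraction, band: PredictedBand) -> str:
    """Compare an observed frequency range against the predicted band.

    ``below_prediction`` iff the observed upper bound lies strictly below
    the band; ``above_prediction`` iff the observed lower bound lies
    strictly above it; otherwise consistent with constant s.
    """
    if observed.upper < band.lower:
        return BELOW
    if observed.lower > band.upper:
        return ABOVE
    return CONSISTENT


@dataclass(frozen=True)
class ConditionRecord:
    """Observed inputs for one growth-history condition."""

    name: str
    pn: FractionWithSE
    observed_f: SurvivingFraction
    growing_persisters_present: bool = False


@dataclass(frozen=True)
class ConditionAssessment:
    condition: ConditionRecord
    predicted: PredictedBand
    classification: str
    note: str = ""


@dataclass(frozen=True)
class SurvivalModeModel:
    """Fitted model: the s estimate, its anchor and per-condition verdicts."""

    s: SEstimate
    anchor: str
    assessments: tuple[ConditionAssessment, ...]


def fit_survival_model(
    conditions: Sequence[ConditionRecord],
    anchor: str | None = None,
    method: str = "linear",
    pn_se_multiplier: float = 1.0,
) -> SurvivalModeModel:
    """Anchor s on one condition and classify all conditions against f = s*Pn.

    ``anchor`` names the condition used to estimate s; by default the one
    with the largest non-growing fraction is used.
    """
    if not conditions:
        raise ValueError("at least one condition is required")
    by_name = {c.name: c for c in conditions}
    if len(by_name) != len(conditions):
        raise ValueError("condition names must be unique")
    if anchor is None:
        anchor_rec = max(conditions, key=lambda c: c.pn.fraction)
    else:
        if anchor not in by_name:
            raise KeyError(f"unknown anchor condition {anchor!r}")
        anchor_rec = by_name[anchor]
    s = estimate_s(anchor_rec.observed_f, anchor_rec.pn, method=method)
    assessments = []
    for cond in conditions:
        band = predict_f(
            s, cond.pn.fraction, pn_se=cond.pn.se,
            pn_se_multiplier=pn_se_multiplier,
        )
        label = classify_scenario(cond.observed_f, band)
        note = ""
        if cond.growing_persisters_present:
            note = (
                "observed frequency includes growing persisters and is an "
                "upper bound for non-growing persisters"
            )
        assessments.append(
            ConditionAssessment(
                condition=cond, predicted=band, classification=label, note=note
            )
        )
    return SurvivalModeModel(s=s, anchor=anchor_rec.name, assessments=tuple(assessments))
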