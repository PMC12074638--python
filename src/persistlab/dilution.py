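"""Limiting-dilution (most-probable-number) viable-count estimation.

A sample is serially diluted and dispensed into wells; after incubation each
well is scored turbid (at least one viable cell was seeded) or non-turbid.
Under Poisson allocation the probability that a well stays non-turbid is
``exp(-d * y * Nv)`` where ``d`` is the dilution, ``y`` the well volume in mL
and ``Nv`` the viable density in cells/mL, so the density is estimated from
the observed non-turbid fraction ``k/W`` as ``Nv = ln(W/k) / (y * d)``.

The module also assembles replicate killing curves (mean and standard error
of log10 density per time point), computes surviving fractions with
log-scale error propagation, and applies the OD-based MIC decision rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = [
    "WellPlate",
    "KillingCurve",
    "SurvivingFraction",
    "AllWellsTurbidError",
    "MIC_ABOVE_RANGE",
    "estimate_viable_density",
    "combine_mixed_dilutions",
    "build_killing_curve",
    "surviving_fraction",
    "mic_from_od",
]

#: Sentinel returned by :func:`mic_from_od` when no tested concentration
#: suppresses growth.
MIC_ABOVE_RANGE = math.inf


class AllWellsTurbidError(ValueError):
    """Raised when every well is turbid (k = 0): the density estimate is
    unbounded and a higher dilution is needed."""


@dataclass(frozen=True)
class WellPlate:
    """One limiting-dilution observation.

    Parameters
    ----------
    dilution
        Dilution factor ``d`` in (0, 1] applied to the sample.
    wells
        Total number of wells ``W`` dispensed at this dilution.
    non_turbid
        Number of non-turbid wells ``k`` (no growth).
    volume_ml
        Volume ``y`` dispensed per well, in mL (default 0.2).
    time_h
        Sampling time in hours since exposure onset.
    replicate
        Replicate experiment identifier.
    """

    dilution: float
    wells: int
    non_turbid: int
    volume_ml: float = 0.2
    time_h: float = 0.0
    replicate: int | str = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.dilution <= 1.0):
            raise ValueError(f"dilution must be in (0, 1], got {self.dilution}")
        if self.wells < 1:
            raise ValueError(f"wells must be >= 1, got {self.wells}")
        if not (0 <= self.non_turbid <= self.wells):
            raise ValueError(
                f"non_turbid must be in [0, wells={self.wells}], got {self.non_turbid}"
            )
        if self.volume_ml <= 0:
            raise ValueError(f"volume_ml must be > 0, got {self.volume_ml}")
        if self.time_h < 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h}")

    @property
    def non_turbid_fraction(self) -> float:
        """Observed fraction of non-turbid wells, x0 = k/W."""
        return self.non_turbid / self.wells

    @property
    def is_mixed(self) -> bool:
        """True when turbid and non-turbid wells coexist (0 < k < W)."""
        return 0 < self.non_turbid < self.wells


def estimate_viable_density(plate: WellPlate) -> float:
    """Most-probable-number estimate of viable density, in cells/mL.

    Returns ``ln(W/k) / (y * d)``; with the default 0.2 mL wells this equals
    ``(5/d) * ln(W/k)``.

    Raises
    ------
    AllWellsTurbidError
        If ``k == 0`` (estimate unbounded; use a higher dilution).

    Warns and returns 0.0 when ``k == W`` (no growth anywhere).
    """
    if plate.non_turbid == 0:
        raise AllWellsTurbidError(
            "all wells turbid: the viable-density estimate is unbounded; "
            "use a higher dilution"
        )
    if plate.non_turbid == plate.wells:
        warnings.warn(
            "all wells non-turbid: estimated density is 0 cells/mL",
            stacklevel=2,
        )
        return 0.0
    return math.log(plate.wells / plate.non_turbid) / (plate.volume_ml * plate.dilution)


def combine_mixed_dilutions(estimates: Sequence[float]) -> float:
    """Reconcile density estimates from dilutions showing mixed wells.

    A single estimate is returned unchanged; two estimates are combined by
    their geometric mean.
    """
    vals = list(estimates)
    if len(vals) not in (1, 2):
        raise ValueError(f"expected 1 or 2 estimates, got {len(vals)}")
    if any(v <= 0 for v in vals):
        raise ValueError(f"estimates must be positive, got {vals}")
    if len(vals) == 1:
        return vals[0]
    return math.sqrt(vals[0] * vals[1])


@dataclass
class KillingCurve:
    """Replicate viable-density measurements over antibiotic exposure time.

    Attributes
    ----------
    densities
        DataFrame with columns ``replicate``, ``time_h``, ``density``
        (cells/mL); one row per (replicate, time).
    summary
        DataFrame with columns ``time_h``, ``mean_log10``, ``se_log10``,
        ``n_replicates``; times sorted ascending. Zero or missing densities
        are excluded (see ``flags``).
    flags
        Diagnostics: ``zero_density`` lists (replicate, time) pairs with an
        estimated density of 0 excluded from the log summary;
        ``missing_times`` lists times with no usable estimate;
        ``single_replicate_times`` lists times where SE was set to 0 because
        only one replicate was available.
    """

    densities: pd.DataFrame
    summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.summary is None:
            self._summarize()

    def _summarize(self) -> None:
        df = self.densities.copy()
        flags = dict(self.flags)
        zero = df[~(df["density"] > 0)]
        flags.setdefault("zero_density", []).extend(
            [(r.replicate, r.time_h) for r in zero.itertuples()]
        )
        usable = df[df["density"] > 0].copy()
        usable["log10_density"] = np.log10(usable["density"].to_numpy(dtype=float))
        rows = []
        single = []
        for t, grp in usable.groupby("time_h"):
            vals = grp["log10_density"].to_numpy()
            n = len(vals)
            if n > 1:
                se = float(np.std(vals, ddof=1) / math.sqrt(n))
            else:
                se = 0.0
                single.append(float(t))
            rows.append((float(t), float(np.mean(vals)), se, n))
        self.summary = pd.DataFrame(
            rows, columns=["time_h", "mean_log10", "se_log10", "n_replicates"]
        ).sort_values("time_h", ignore_index=True)
        if single:
            flags["single_replicate_times"] = single
        self.flags = flags

    @property
    def times(self) -> np.ndarray:
        return self.summary["time_h"].to_numpy()

    def _row(self, t: float) -> pd.Series:
        match = self.summary[np.isclose(self.summary["time_h"], t)]
        if match.empty:
            raise KeyError(f"no entry at time {t} h")
        return match.iloc[0]

    def mean_log10(self, t: float) -> float:
        return float(self._row(t)["mean_log10"])

    def se_log10(self, t: float) -> float:
        return float(self._row(t)["se_log10"])

    def mean_densities(self) -> pd.DataFrame:
        """Per-time geometric-mean density (10**mean_log10), for fitting."""
        out = self.summary.copy()
        out["density"] = 10.0 ** out["mean_log10"]
        return out[["time_h", "density"]]


def build_killing_curve(plates: Iterable[WellPlate]) -> KillingCurve:
    """Assemble a killing curve from limiting-dilution plates.

    For each (replicate, time): the dilutions showing mixed wells are
    converted to density estimates and reconciled by geometric mean. When
    more than two dilutions are mixed the two with ``k`` closest to ``W/2``
    are used (maximal information per Poisson theory; logged as a warning).
    A (replicate, time) where every plate shows no growth contributes a
    density of 0, flagged and excluded from the log-scale summary.
    """
    plates = list(plates)
    if not plates:
        raise ValueError("no plates provided")
    groups: dict[tuple, list[WellPlate]] = {}
    for p in plates:
        groups.setdefault((p.replicate, p.time_h), []).append(p)

    records = []
    flags: dict = {"missing_times": [], "zero_density": []}
    for (rep, t), group in sorted(groups.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        mixed = [p for p in group if p.is_mixed]
        if len(mixed) > 2:
            mixed = sorted(mixed, key=lambda p: abs(p.non_turbid - p.wells / 2))[:2]
            warnings.warn(
                f"replicate {rep!r} t={t} h: more than two dilutions show mixed "
                "wells; using the two with k closest to W/2",
                stacklevel=2,
            )
        if mixed:
            density = combine_mixed_dilutions(
                [estimate_viable_density(p) for p in mixed]
            )
        elif any(p.non_turbid == p.wells for p in group):
            density = 0.0
            flags["zero_density"].append((rep, t))
        else:
            # every plate fully turbid: no usable estimate at this point
            flags["missing_times"].append((rep, t))
            warnings.warn(
                f"replicate {rep!r} t={t} h: all plates fully turbid, "
                "no usable density estimate (flagged missing)",
                stacklevel=2,
            )
            continue
        records.append((rep, t, density))

    densities = pd.DataFrame(records, columns=["replicate", "time_h", "density"])
    return KillingCurve(densities=densities, flags=flags)


@dataclass(frozen=True)
class SurvivingFraction:
    """Surviving-cell frequency at a time point, with a log-scale range.

    ``lower``/``upper`` come from propagating the standard errors of the two
    log10 densities: ``f * 10**(-/+ sqrt(SE(t)^2 + SE(0)^2))``. A fraction of
    exactly 0 (no survivors counted) is representable with ``lower == 0`` and
    a positive ``upper`` confidence bound.
    """

    time_h: float
    fraction: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.fraction <= self.upper):
            raise ValueError(
                f"require 0 <= lower <= fraction <= upper, got "
                f"({self.lower}, {self.fraction}, {self.upper})"
            )

    @property
    def half_width(self) -> float:
        """Half the linear-scale range width, used as a symmetric error."""
        return (self.upper - self.lower) / 2.0


def surviving_fraction(curve: KillingCurve, t: float, t0: float = 0.0) -> SurvivingFraction:
    """Surviving fraction at ``t`` relative to ``t0`` with propagated errors.

    ``f = 10**(mean_log10(t) - mean_log10(t0))``; the range is
    ``f * 10**(±sqrt(SE(t)^2 + SE(t0)^2))``.
    """
    m0, s0 = curve.mean_log10(t0), curve.se_log10(t0)
    mt, st = curve.mean_log10(t), curve.se_log10(t)
    f = 10.0 ** (mt - m0)
    se = math.sqrt(st**2 + s0**2)
    return SurvivingFraction(
        time_h=t, fraction=f, lower=f * 10.0 ** (-se), upper=f * 10.0**se
    )


def mic_from_od(
    table: Mapping[float, Sequence[float]] | pd.DataFrame,
    threshold: float = 0.001,
) -> float:
    """Minimum inhibitory concentration from an OD-vs-concentration table.

    ``table`` maps concentration to replicate OD readings (or a DataFrame
    with columns ``concentration`` and ``od``). Returns the smallest tested
    concentration such that the geometric-mean OD of it and of every higher
    tested concentration is below ``threshold``; :data:`MIC_ABOVE_RANGE`
    (infinity) if no concentration qualifies.
    """
    if isinstance(table, pd.DataFrame):
        if table.empty:
            raise ValueError("empty OD table")
        grouped = {
            float(c): grp["od"].to_list() for c, grp in table.groupby("concentration")
        }
    else:
        grouped = {float(c): list(v) for c, v in table.items()}
    if not grouped:
        raise ValueError("empty OD table")

    concs = sorted(grouped)
    mic = MIC_ABOVE_RANGE
    for c in reversed(concs):
        if gmean(np.asarray(grouped[c], dtype=float)) < threshold:
            mic = c
        else:
            break
    return mic
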