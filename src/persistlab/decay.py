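"""Multi-exponential decay fitting of killing curves with AIC phase selection.

The viable density under antibiotic exposure is modelled as a sum of ``n``
exponentially decaying subpopulations, ``f_n(t) = sum_j a_j * exp(-d_j * t)``
with ``a_j, d_j > 0``. Fits minimise the sum of squared natural-log residuals
(Levenberg-Marquardt on a log-parameterisation, multi-start), and the number
of phases is chosen by the Gaussian-residual AIC

    AIC = N ln(2 pi) + N + N ln(SSR / N) + 2 k,

with ``k = 2n`` free parameters (amplitudes and rates).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.special import logsumexp

__all__ = [
    "MultiExpModel",
    "FitResult",
    "SelectionResult",
    "multiexp_eval",
    "aic",
    "fit_fixed_n",
    "select_n",
    "SSR_FLOOR",
]

#: SSR below this floor is clamped before the log in the AIC so a perfect
#: fit keeps the criterion finite.
SSR_FLOOR = 1e-12

#: Decay-rate grid (1/h) from which multi-start initial rate sets are drawn.
RATE_GRID = (1e-2, 1e-1, 1.0, 1e1, 1e2)

#: Two rates within this relative distance are flagged as a merged phase.
MERGE_RTOL = 1e-3


@dataclass(frozen=True)
class MultiExpModel:
    """Sum of decaying exponentials; phases stored fastest-first.

    Amplitudes are in cells/mL, rates in 1/h; all must be strictly positive.
    """

    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in self.amplitudes)
        rates = tuple(float(d) for d in self.rates)
        if len(amps) != len(rates) or not amps:
            raise ValueError("amplitudes and rates must be non-empty, same length")
        if any(a <= 0 for a in amps):
            raise ValueError(f"amplitudes must be > 0, got {amps}")
        if any(d <= 0 for d in rates):
            raise ValueError(f"rates must be > 0, got {rates}")
        order = np.argsort(rates)[::-1]
        object.__setattr__(self, "amplitudes", tuple(amps[i] for i in order))
        object.__setattr__(self, "rates", tuple(rates[i] for i in order))

    @property
    def n(self) -> int:
        """Number of phases."""
        return len(self.amplitudes)

    def evaluate(self, t: float | np.ndarray) -> float | np.ndarray:
        """Viable density at time(s) ``t`` (hours, >= 0)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("t must be >= 0")
        a = np.asarray(self.amplitudes)
        d = np.asarray(self.rates)
        out = np.sum(a * np.exp(-np.multiply.outer(t_arr, d)), axis=-1)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def multiexp_eval(model: MultiExpModel, t: float | np.ndarray) -> float | np.ndarray:
    """Functional alias for :meth:`MultiExpModel.evaluate`."""
    return model.evaluate(t)


def aic(n_points: int, ssr: float, k_params: int) -> float:
    """Gaussian-residual Akaike Information Criterion.

    ``N ln(2 pi) + N + N ln(SSR/N) + 2k``. SSR below :data:`SSR_FLOOR` is
    clamped (with a warning) to keep the value finite on perfect fits.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if ssr < 0:
        raise ValueError("SSR must be >= 0")
    if k_params < 1:
        raise ValueError("k_params must be >= 1")
    if ssr < SSR_FLOOR:
        warnings.warn(
            f"SSR={ssr:.3g} below floor {SSR_FLOOR:g}; clamped for AIC",
            stacklevel=2,
        )
        ssr = SSR_FLOOR
    n = float(n_points)
    return n * math.log(2 * math.pi) + n + n * math.log(ssr / n) + 2 * k_params


@dataclass(frozen=True)
class FitResult:
    """Outcome of a fixed-phase-count fit."""

    model: MultiExpModel
    ssr: float
    n_points: int
    k_params: int
    aic: float
    converged: bool
    n_starts_used: int
    flags: tuple[str, ...] = field(default=())

    @property
    def n(self) -> int:
        return self.model.n


@dataclass(frozen=True)
class SelectionResult:
    """All candidate fits for n = 1..n_max plus the AIC-selected one."""

    fits: tuple[FitResult, ...]
    chosen_index: int

    @property
    def chosen(self) -> FitResult:
        return self.fits[self.chosen_index]

    @property
    def chosen_n(self) -> int:
        return self.chosen.n


def _log_residuals(theta: np.ndarray, t: np.ndarray, ln_y: np.ndarray, n: int) -> np.ndarray:
    ln_a = theta[:n]
    d = np.exp(np.clip(theta[n:], -60.0, 60.0))  # keep exp finite for LM probes
    ln_f = logsumexp(ln_a[None, :] - t[:, None] * d[None, :], axis=1)
    return ln_y - ln_f


def _amplitudes_for_rates(
    t: np.ndarray, y: np.ndarray, rates: np.ndarray
) -> np.ndarray:
    """Non-negative least-squares back-solve of amplitudes for fixed rates."""
    design = np.exp(-np.outer(t, rates))
    try:
        a, _ = nnls(design, y)
    except Exception:  # pragma: no cover - nnls is robust, but stay safe
        a = np.zeros(len(rates))
    floor = max(y.max(), 1.0) * 1e-8
    return np.where(a > floor, a, floor)


def _candidate_rates(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Decade grid augmented with rates suggested by local log-slopes."""
    cand = list(RATE_GRID)
    ln_y = np.log(y)
    order = np.argsort(t)
    dt = np.diff(t[order])
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = -np.diff(ln_y[order]) / np.where(dt > 0, dt, np.nan)
    slopes = slopes[np.isfinite(slopes) & (slopes > 0)]
    if slopes.size:
        lo, hi = slopes.min(), slopes.max()
        cand.extend(np.geomspace(max(lo, 1e-4), max(hi, lo * 1.001), 5))
    return np.unique(np.asarray(cand, dtype=float))


def _initial_points(
    t: np.ndarray, y: np.ndarray, n: int, starts: int, seed: int | None
) -> list[np.ndarray]:
    """Multi-start initial points for the log-parameterised fit.

    Candidate rate n-sets come from a deterministic grid (decades plus
    log-slope-derived rates); amplitudes are back-solved by NNLS. Candidates
    are ranked by their initial SSR and the best ``starts`` kept, topped up
    with seeded +/-20% jitter copies if the grid is smaller than ``starts``.
    """
    ln_y = np.log(y)
    scored: list[tuple[float, np.ndarray]] = []
    for rates in itertools.combinations(_candidate_rates(t, y), n):
        rates_arr = np.asarray(rates, dtype=float)
        amps = _amplitudes_for_rates(t, y, rates_arr)
        x0 = np.concatenate([np.log(amps), np.log(rates_arr)])
        ssr0 = float(np.sum(_log_residuals(x0, t, ln_y, n) ** 2))
        scored.append((ssr0, x0))
    scored.sort(key=lambda p: p[0])
    points = [x for _, x in scored[:starts]]
    rng = np.random.default_rng(seed)
    i = 0
    while len(points) < starts:
        jitter = rng.uniform(math.log(0.8), math.log(1.2), size=2 * n)
        points.append(points[i % max(len(scored), 1)] + jitter)
        i += 1
    return points


def fit_fixed_n(
    times: Sequence[float],
    densities: Sequence[float],
    n: int,
    starts: int = 20,
    seed: int | None = 0,
) -> FitResult:
    """Fit an ``n``-phase decay model by log-space least squares.

    Minimises ``sum_i (ln N_i - ln f_n(t_i))^2`` over ``a_j, d_j > 0`` by
    optimising ``(ln a_j, ln d_j)`` unconstrained with Levenberg-Marquardt,
    keeping the best of ``starts`` initial points (decade-spaced rate grid
    with amplitude back-solve, plus seeded jitter).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(densities, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and densities must be 1-D and the same length")
    if len(t) < 2 * n + 1:
        raise ValueError(f"need at least {2 * n + 1} points to fit n={n} phases")
    if np.any(y <= 0):
        raise ValueError("densities must be > 0")
    ln_y = np.log(y)

    best = None
    converged = False
    points = _initial_points(t, y, n, starts, seed)
    for x0 in points:
        try:
            res = least_squares(
                _log_residuals,
                x0,
                args=(t, ln_y, n),
                method="lm",
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=500 * len(x0),
            )
        except Exception:
            continue
        ssr = float(np.sum(res.fun**2))
        if best is None or ssr < best[0]:
            best = (ssr, res.x)
        converged = converged or res.status > 0
    if best is None:  # pragma: no cover - LM never raises on finite input
        raise RuntimeError("all starts failed")

    ssr, x = best
    # clamp so that a phase optimised out of the model (ln a -> -inf) stays
    # representable as a vanishingly small but positive amplitude
    model = MultiExpModel(
        amplitudes=tuple(np.exp(np.clip(x[:n], -700.0, 700.0))),
        rates=tuple(np.exp(np.clip(x[n:], -60.0, 60.0))),
    )
    flags = []
    if np.any(x[:n] < -650.0):
        flags.append("vanishing_amplitude")
    rates = np.asarray(model.rates)
    if n > 1 and np.any(np.abs(np.diff(rates)) / rates[:-1] < MERGE_RTOL):
        flags.append("merged_phases")
    if np.any(rates < 1e-6):
        flags.append("near_zero_rate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        crit = aic(len(t), ssr, 2 * n)
    return FitResult(
        model=model,
        ssr=ssr,
        n_points=len(t),
        k_params=2 * n,
        aic=crit,
        converged=converged,
        n_starts_used=len(points),
        flags=tuple(flags),
    )


def select_n(
    times: Sequence[float],
    densities: Sequence[float],
    n_max: int = 3,
    starts: int = 20,
    seed: int | None = 0,
) -> SelectionResult:
    """Fit 1..n_max phases and pick the minimum-AIC model.

    Ties are broken toward the smaller phase count. Raises if the selected
    model did not converge.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    fits = []
    for n in range(1, n_max + 1):
        if len(times) < 2 * n + 1:
            warnings.warn(
                f"skipping n={n}: only {len(times)} points (< {2 * n + 1})",
                stacklevel=2,
            )
            break
        fits.append(fit_fixed_n(times, densities, n, starts=starts, seed=seed))
    if not fits:
        raise ValueError("no candidate phase count could be fitted")
    aics = [f.aic for f in fits]
    chosen = int(np.argmin(aics))  # argmin returns the first (smallest n) on ties
    if not fits[chosen].converged:
        raise RuntimeError(f"selected model (n={fits[chosen].n}) did not converge")
    return SelectionResult(fits=tuple(fits), chosen_index=chosen)
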