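"""Synthetic-data generators for every input the analysis pipeline consumes.

Three generators mirror the experimental records:

- replicate killing curves with lognormal noise around a multi-exponential
  mean (:func:`simulate_multiexp_samples`);
- limiting-dilution well plates under Poisson allocation of viable cells
  (:func:`simulate_limiting_dilution`);
- chamber lineage forests from a two-state (growing / non-growing)
  switching process with state-dependent persister probabilities
  (:func:`simulate_chamber_lineages`), including per-frame cell areas so the
  downstream classification is exercised end to end.

Division waiting times are exponential with rate ``division_rate`` so the
expected number of divisions per hour along any single lineage equals
``division_rate`` (the doublings/h measured by D(sigma)/T(sigma)); cell areas
grow at rate ``division_rate * ln 2`` so the area doubles over one mean
interdivision time. All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from persistlab.decay import MultiExpModel
from persistlab.dilution import KillingCurve, WellPlate
from persistlab.lineage import LineageTable

__all__ = [
    "PopulationSimConfig",
    "SimulatedLineageSet",
    "CellOutline",
    "simulate_multiexp_samples",
    "simulate_limiting_dilution",
    "simulate_chamber_lineages",
    "simulate_cell_outline",
    "simulate_condition_counts",
]

GROWING = "growing"
NON_GROWING = "non_growing"


def simulate_multiexp_samples(
    model: MultiExpModel,
    times: Sequence[float],
    noise_sd_log10: float,
    replicates: int,
    seed: int | None = 0,
) -> KillingCurve:
    """Replicate killing-curve samples around a multi-exponential mean.

    Each replicate's log10 density at time t is
    ``log10 f(t) + Normal(0, noise_sd_log10)``.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if noise_sd_log10 < 0:
        raise ValueError("noise_sd_log10 must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    log10_mean = np.log10(model.evaluate(t))
    records = []
    for rep in range(replicates):
        noise = rng.normal(0.0, noise_sd_log10, size=t.size) if noise_sd_log10 > 0 else 0.0
        log10_vals = log10_mean + noise
        for ti, lv in zip(t, np.atleast_1d(log10_vals + np.zeros(t.size))):
            records.append((rep, float(ti), float(10.0**lv)))
    densities = pd.DataFrame(records, columns=["replicate", "time_h", "density"])
    return KillingCurve(densities=densities)


def simulate_limiting_dilution(
    true_density: float,
    dilutions: Sequence[float],
    wells_per_dilution: int,
    well_volume: float = 0.2,
    seed: int | None = 0,
    time_h: float = 0.0,
    replicate: int | str = 0,
) -> list[WellPlate]:
    """Simulate limiting-dilution plates under Poisson allocation.

    A well stays non-turbid with probability ``exp(-d * y * Nv)``; the
    non-turbid count per dilution is binomial.
    """
    if true_density < 0:
        raise ValueError("true_density must be >= 0")
    if well_volume <= 0:
        raise ValueError("well_volume must be > 0")
    if wells_per_dilution < 1:
        raise ValueError("wells_per_dilution must be >= 1")
    rng = np.random.default_rng(seed)
    plates = []
    for d in dilutions:
        if not (0.0 < d <= 1.0):
            raise ValueError(f"dilution must be in (0, 1], got {d}")
        p_non_turbid = math.exp(-d * well_volume * true_density)
        k = int(rng.binomial(wells_per_dilution, p_non_turbid))
        plates.append(
            WellPlate(
                dilution=d,
                wells=wells_per_dilution,
                non_turbid=k,
                volume_ml=well_volume,
                time_h=time_h,
                replicate=replicate,
            )
        )
    return plates


@dataclass(frozen=True)
class PopulationSimConfig:
    """Parameters of the two-state chamber-population simulation.

    Rates are per hour; ``division_rate`` is in doublings/h (division waiting
    times along a lineage are exponential with rate ``division_rate``, and
    areas grow at ``division_rate * ln 2`` per hour). ``s_growing``
    and ``s_nongrowing`` are the probabilities that a cell in that state at
    exposure onset survives the drug and regrows afterwards; non-survivors
    lyse at the state-specific kill rate during exposure.
    """

    n_founders: int
    p_nongrowing: float
    division_rate: float
    switch_gn: float = 0.0
    switch_ng: float = 0.0
    kill_growing: float = 2.0
    kill_nongrowing: float = 0.1
    s_growing: float = 0.0
    s_nongrowing: float = 0.0
    t_pre: float = 1.5
    t_exposure: float = 6.0
    t_post: float = 4.0
    seed: int = 0
    frame_interval_h: float = 0.05
    emit_frames: bool = True
    birth_area_um2: float = 1.0

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        for name in ("division_rate", "switch_gn", "switch_ng", "kill_growing", "kill_nongrowing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_nongrowing", "s_growing", "s_nongrowing"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("t_pre", "t_exposure", "t_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be > 0")
        if self.birth_area_um2 <= 0:
            raise ValueError("birth_area_um2 must be > 0")


@dataclass
class SimulatedLineageSet:
    """Simulated lineages plus ground truth for recovery tests.

    ``cell_truth`` has one row per cell alive at exposure onset
    (``cell_id``, ``state_at_exposure``, ``persister``); ``founder_truth``
    one row per founder (``founder_id``, ``true_state_at_exposure`` — the
    majority state among its exposed descendants, ties toward growing —
    and ``true_persister``: any descendant survived and regrew).
    """

    table: LineageTable
    cell_truth: pd.DataFrame
    founder_truth: pd.DataFrame
    config: PopulationSimConfig

    @property
    def persister_frequency_per_founder(self) -> float:
        return float(self.founder_truth["true_persister"].mean())

    @property
    def persister_frequency_per_cell(self) -> float:
        return float(self.cell_truth["persister"].mean())


def _grown_time(segments: list[tuple[float, float]], t: np.ndarray) -> np.ndarray:
    total = np.zeros_like(t)
    for s0, s1 in segments:
        total += np.clip(np.minimum(t, s1) - s0, 0.0, None)
    return total


def simulate_chamber_lineages(config: PopulationSimConfig) -> SimulatedLineageSet:
    """Event-driven simulation of chamber lineage forests.

    Founders start growing or non-growing; growing cells divide (children
    inherit the growing state) and may switch to non-growing, non-growing
    cells may switch back. At exposure onset each live cell draws a persister
    fate from the state-specific survival probability; non-persisters lyse at
    the state kill rate during exposure (or are censored intact), persisters
    resume growth and division after the drug is removed. Cell areas grow
    exponentially while a cell is in the growing state and halve at division.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lam = cfg.division_rate  # division events per hour along a lineage
    g = cfg.division_rate * math.log(2.0)  # exponential area-growth rate
    t_exp_on = cfg.t_pre
    t_exp_off = cfg.t_pre + cfg.t_exposure
    t_end = t_exp_off + cfg.t_post
    inf = math.inf

    cells: list[tuple] = []  # cell_id,parent_id,chamber,birth,end,fate
    grow_segments: list[list[tuple[float, float]]] = []
    birth_areas: list[float] = []
    truth_rows: list[tuple] = []  # cell_id, state_at_exposure, persister
    founder_state_counts: dict[int, list[int]] = {}  # founder -> [n_growing, n_nongrowing]
    founder_persister: dict[int, bool] = {}

    next_id = 0
    # stack items: (parent_id, chamber, birth, state, birth_area, phase)
    # phase: "pre" (subject to exposure) or "post" (regrowth progeny)
    stack: list[tuple] = []
    founder_states = np.where(
        rng.random(cfg.n_founders) < cfg.p_nongrowing, NON_GROWING, GROWING
    )
    for i in range(cfg.n_founders):
        stack.append((None, i, 0.0, founder_states[i], cfg.birth_area_um2, "pre"))
        founder_state_counts[i] = [0, 0]
        founder_persister[i] = False

    while stack:
        parent_id, chamber, birth, state, area0, phase = stack.pop()
        cid = next_id
        next_id += 1
        segs: list[tuple[float, float]] = []
        t = birth
        seg_start = t if state == GROWING else None
        end = None
        fate = None

        if phase == "post":
            # regrowth progeny: always growing, divides until observation end
            td = rng.exponential(1.0 / lam) if lam > 0 else inf
            if t + td < t_end:
                end, fate = t + td, "division"
            else:
                end, fate = t_end, "censored"
            segs.append((t, end))
            area_end = area0 * math.exp(g * (end - t))
            if fate == "division":
                stack.append((cid, chamber, end, GROWING, area_end / 2.0, "post"))
                stack.append((cid, chamber, end, GROWING, area_end / 2.0, "post"))
        else:
            # pre-exposure dynamics: division / switching race
            while True:
                if state == GROWING:
                    rd, rs = lam, cfg.switch_gn
                else:
                    rd, rs = 0.0, cfg.switch_ng
                td = rng.exponential(1.0 / rd) if rd > 0 else inf
                ts = rng.exponential(1.0 / rs) if rs > 0 else inf
                te = t + min(td, ts)
                if te >= t_exp_on:
                    # alive at exposure onset
                    if state == GROWING:
                        segs.append((seg_start, t_exp_on))
                    s_prob = cfg.s_growing if state == GROWING else cfg.s_nongrowing
                    kill = cfg.kill_growing if state == GROWING else cfg.kill_nongrowing
                    is_persister = bool(rng.random() < s_prob)
                    truth_rows.append((cid, state, is_persister))
                    idx = 0 if state == GROWING else 1
                    founder_state_counts[chamber][idx] += 1
                    if is_persister:
                        founder_persister[chamber] = True
                        td_post = rng.exponential(1.0 / lam) if lam > 0 else inf
                        if t_exp_off + td_post < t_end:
                            end, fate = t_exp_off + td_post, "division"
                        else:
                            end, fate = t_end, "censored"
                        segs.append((t_exp_off, end))
                        if fate == "division":
                            grown = _grown_time(segs, np.array([end]))[0]
                            area_end = area0 * math.exp(g * grown)
                            stack.append((cid, chamber, end, GROWING, area_end / 2.0, "post"))
                            stack.append((cid, chamber, end, GROWING, area_end / 2.0, "post"))
                    else:
                        lt = rng.exponential(1.0 / kill) if kill > 0 else inf
                        if t_exp_on + lt < t_exp_off:
                            end, fate = t_exp_on + lt, "lysis"
                        else:
                            end, fate = t_end, "censored"
                    break
                if td <= ts:
                    # division before exposure
                    segs.append((seg_start, te))
                    end, fate = te, "division"
                    area_end = area0 * math.exp(g * _grown_time(segs, np.array([te]))[0])
                    stack.append((cid, chamber, te, GROWING, area_end / 2.0, "pre"))
                    stack.append((cid, chamber, te, GROWING, area_end / 2.0, "pre"))
                    break
                # state switch
                if state == GROWING:
                    segs.append((seg_start, te))
                    seg_start = None
                    state = NON_GROWING
                else:
                    state = GROWING
                    seg_start = te
                t = te

        cells.append((cid, parent_id, chamber, birth, end, fate))
        grow_segments.append(segs)
        birth_areas.append(area0)

    cells_df = pd.DataFrame(
        cells, columns=["cell_id", "parent_id", "chamber_id", "birth_h", "end_h", "fate"]
    )
    persister_col = cells_df["chamber_id"].map(founder_persister)
    cells_df["persister"] = persister_col.astype(bool)
    cells_df["parent_id"] = cells_df["parent_id"].astype("Int64")

    frames_df = None
    if cfg.emit_frames:
        dt = cfg.frame_interval_h
        ids_out, t_out, a_out = [], [], []
        births = cells_df["birth_h"].to_numpy()
        ends = cells_df["end_h"].to_numpy()
        for i in range(len(cells_df)):
            k0 = math.ceil(births[i] / dt - 1e-9)
            k1 = math.floor(min(ends[i], t_end) / dt + 1e-9)
            if k1 < k0:
                continue
            ft = np.arange(k0, k1 + 1) * dt
            areas = birth_areas[i] * np.exp(g * _grown_time(grow_segments[i], ft))
            ids_out.append(np.full(ft.size, i))
            t_out.append(ft)
            a_out.append(areas)
        if ids_out:
            frames_df = pd.DataFrame(
                {
                    "cell_id": np.concatenate(ids_out),
                    "t_h": np.concatenate(t_out),
                    "area_um2": np.concatenate(a_out),
                }
            )
        else:  # pragma: no cover - degenerate frame interval
            frames_df = pd.DataFrame(columns=["cell_id", "t_h", "area_um2"])

    table = LineageTable(cells=cells_df, frames=frames_df)
    cell_truth = pd.DataFrame(
        truth_rows, columns=["cell_id", "state_at_exposure", "persister"]
    )
    founder_rows = []
    for fid in range(cfg.n_founders):
        n_g, n_n = founder_state_counts[fid]
        state = NON_GROWING if n_n > n_g else GROWING
        founder_rows.append((fid, state, founder_persister[fid]))
    founder_truth = pd.DataFrame(
        founder_rows, columns=["founder_id", "true_state_at_exposure", "true_persister"]
    )
    return SimulatedLineageSet(
        table=table, cell_truth=cell_truth, founder_truth=founder_truth, config=cfg
    )


@dataclass(frozen=True)
class CellOutline:
    """Spherocylinder outline with closed-form area and perimeter oracles."""

    vertices: np.ndarray  # (n, 2), counter-clockwise, not closed
    analytic_area: float
    analytic_perimeter: float

    @property
    def analytic_circularity(self) -> float:
        return 4.0 * math.pi * self.analytic_area / self.analytic_perimeter**2


def simulate_cell_outline(length: float, width: float, n_vertices: int = 64) -> CellOutline:
    """Polygon approximating a rod-shaped cell (rectangle with semicircular caps).

    The analytic area ``(length - width) * width + pi * (width/2)^2`` and
    perimeter ``2 * (length - width) + pi * width`` are attached as oracle
    values. For ``length == width`` the outline is a circle.
    """
    if not (length >= width > 0):
        raise ValueError("require length >= width > 0")
    if n_vertices < 8:
        raise ValueError("n_vertices must be >= 8")
    r = width / 2.0
    area = (length - width) * width + math.pi * r**2
    perim = 2.0 * (length - width) + math.pi * width

    if length == width:
        ang = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
        verts = np.column_stack([r + r * np.cos(ang), r * np.sin(ang)])
        return CellOutline(vertices=verts, analytic_area=area, analytic_perimeter=perim)

    n_right = n_vertices // 2
    n_left = n_vertices - n_right
    ang_r = np.linspace(-math.pi / 2, math.pi / 2, n_right)
    right = np.column_stack(
        [(length - r) + r * np.cos(ang_r), r * np.sin(ang_r)]
    )
    ang_l = np.linspace(math.pi / 2, 3 * math.pi / 2, n_left)
    left = np.column_stack([r + r * np.cos(ang_l), r * np.sin(ang_l)])
    verts = np.vstack([right, left])
    return CellOutline(vertices=verts, analytic_area=area, analytic_perimeter=perim)


def simulate_condition_counts(
    true_s: float,
    pn_values: Sequence[float],
    n_observed: Sequence[int],
    n_exposed: Sequence[int],
    seed: int | None = 0,
    names: Sequence[str] | None = None,
):
    """Draw condition-level counts from the constant-s survival model.

    For each condition, the number of non-growing cells among ``n_observed``
    classified cells is binomial with probability Pn, and the number of
    persisters among ``n_exposed`` drug-exposed cells is binomial with
    probability ``true_s * Pn``. Returns a list of
    :class:`~persistlab.survival.ConditionRecord`; a zero persister count
    yields a frequency of 0 with a rule-of-three upper bound.
    """
    from persistlab.dilution import SurvivingFraction
    from persistlab.lineage import FractionWithSE
    from persistlab.survival import ConditionRecord

    if not (0.0 <= true_s <= 1.0):
        raise ValueError("true_s must be in [0, 1]")
    if not (len(pn_values) == len(n_observed) == len(n_exposed)):
        raise ValueError("pn_values, n_observed and n_exposed must align")
    rng = np.random.default_rng(seed)
    records = []
    for i, (pn, n_obs, n_exp) in enumerate(zip(pn_values, n_observed, n_exposed)):
        if not (0.0 <= pn <= 1.0):
            raise ValueError("Pn values must be in [0, 1]")
        k_nongrow = int(rng.binomial(n_obs, pn))
        pn_hat = FractionWithSE.from_counts(k_nongrow, n_obs)
        k_pers = int(rng.binomial(n_exp, true_s * pn))
        f_hat = k_pers / n_exp
        if k_pers > 0:
            # 95% Wald range so that downstream band comparisons behave like
            # confidence-interval overlap checks
            half = 1.96 * math.sqrt(f_hat * (1.0 - f_hat) / n_exp)
            obs = SurvivingFraction(
                time_h=0.0,
                fraction=f_hat,
                lower=max(f_hat - half, 0.0),
                upper=f_hat + half,
            )
        else:
            obs = SurvivingFraction(time_h=0.0, fraction=0.0, lower=0.0, upper=3.0 / n_exp)
        name = names[i] if names is not None else f"condition_{i}"
        records.append(ConditionRecord(name=name, pn=pn_hat, observed_f=obs))
    return records
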