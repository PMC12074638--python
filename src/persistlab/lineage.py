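"""Single-cell lineage statistics from time-lapse tracking tables.

Works on rooted lineage forests exported by image analysis: one row per
tracked cell with birth/end times and an end fate, plus per-frame areas and
optional polygon outlines. Provides division rates D(sigma)/T(sigma),
random-sister lineage sampling, growing/non-growing classification over a
pre-exposure window, binomial fractions with Wald standard errors, persister
frequency from chamber counts, shape metrics (area, perimeter, circularity)
and Wilcoxon rank-sum comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from shapely.geometry import Polygon

__all__ = [
    "FATES",
    "LABELS",
    "LineageTable",
    "FractionWithSE",
    "ShapeMetrics",
    "DivisionRateComparison",
    "division_rate",
    "path_division_rate",
    "sample_independent_lineages",
    "classify_pre_exposure",
    "classify_population",
    "non_growing_fraction",
    "persister_frequency_from_chambers",
    "shape_metrics",
    "rank_sum_test",
    "compare_division_rates",
]

FATES = frozenset({"division", "lysis", "tracking_lost", "censored"})
LABELS = ("growing", "non_growing", "indeterminate")

_CELL_COLUMNS = ["cell_id", "parent_id", "chamber_id", "birth_h", "end_h", "fate", "persister"]
_FRAME_COLUMNS = ["cell_id", "t_h", "area_um2"]

_TOL = 1e-9


@dataclass
class LineageTable:
    """Rooted lineage forest plus per-frame sizes.

    Attributes
    ----------
    cells
        One row per cell: ``cell_id``, ``parent_id`` (NA for founders),
        ``chamber_id``, ``birth_h``, ``end_h``, ``fate`` (one of
        :data:`FATES`), ``persister`` (founder-level flag: the founder's
        lineage survived exposure and regrew).
    frames
        Optional per-frame observations: ``cell_id``, ``t_h``, ``area_um2``
        and optionally ``outline_wkt``.
    """

    cells: pd.DataFrame
    frames: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in _CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cells table missing columns: {missing}")
        cells = self.cells.reset_index(drop=True)
        if cells["cell_id"].duplicated().any():
            dupes = cells.loc[cells["cell_id"].duplicated(), "cell_id"].tolist()
            raise ValueError(f"duplicate cell ids: {dupes}")
        bad_fate = set(cells["fate"].unique()) - FATES
        if bad_fate:
            raise ValueError(f"unknown fates: {sorted(bad_fate)}")
        if (cells["end_h"] < cells["birth_h"] - _TOL).any():
            raise ValueError("end_h must be >= birth_h for every cell")
        self.cells = cells
        self._by_id = cells.set_index("cell_id")
        self._children: dict = {}
        for row in cells.itertuples():
            if pd.notna(row.parent_id):
                self._children.setdefault(row.parent_id, []).append(row.cell_id)
        self._validate_forest()
        if self.frames is not None:
            missing = [c for c in _FRAME_COLUMNS if c not in self.frames.columns]
            if missing:
                raise ValueError(f"frames table missing columns: {missing}")
            if not (self.frames["area_um2"] > 0).all():
                raise ValueError("frame areas must be > 0")

    def _validate_forest(self) -> None:
        cells = self.cells
        n = len(cells)
        if n == 0:
            return
        pos = {cid: i for i, cid in enumerate(cells["cell_id"])}
        has_parent = cells["parent_id"].notna().to_numpy()
        parent_idx = np.arange(n)
        for i in np.flatnonzero(has_parent):
            p = cells["parent_id"].iat[i]
            j = pos.get(p)
            if j is None:
                raise ValueError(
                    f"cell {cells['cell_id'].iat[i]!r} references unknown parent {p!r}"
                )
            parent_idx[i] = j
        # pointer doubling: after ceil(log2 n)+1 squarings every acyclic chain
        # has reached its founder (founders point to themselves)
        ptr = parent_idx.copy()
        for _ in range(int(math.ceil(math.log2(max(n, 2)))) + 1):
            ptr = ptr[ptr]
        if has_parent[ptr].any():
            bad = cells["cell_id"].iat[int(np.flatnonzero(has_parent[ptr])[0])]
            raise ValueError(f"lineage cycle detected involving cell {bad!r}")
        # divisions must hand off time consistently
        child_rows = np.flatnonzero(has_parent)
        if child_rows.size:
            p_rows = parent_idx[child_rows]
            p_fate = cells["fate"].to_numpy()[p_rows]
            if (p_fate != "division").any():
                i = child_rows[np.flatnonzero(p_fate != "division")[0]]
                raise ValueError(
                    f"cell {cells['cell_id'].iat[int(i)]!r} has parent "
                    f"{cells['parent_id'].iat[int(i)]!r} with non-division fate"
                )
            dt = np.abs(
                cells["birth_h"].to_numpy()[child_rows]
                - cells["end_h"].to_numpy()[p_rows]
            )
            if (dt > 1e-6).any():
                i = child_rows[np.flatnonzero(dt > 1e-6)[0]]
                raise ValueError(
                    f"cell {cells['cell_id'].iat[int(i)]!r} birth does not "
                    "match its parent's division time"
                )

    @property
    def founders(self) -> pd.DataFrame:
        return self.cells[self.cells["parent_id"].isna()]

    def children(self, cell_id) -> list:
        return list(self._children.get(cell_id, []))

    def cell(self, cell_id) -> pd.Series:
        return self._by_id.loc[cell_id]

    def ancestors(self, cell_id) -> list:
        """Cell ids from ``cell_id`` back to its founder (inclusive)."""
        chain = [cell_id]
        cur = cell_id
        while True:
            p = self._by_id.at[cur, "parent_id"]
            if pd.isna(p):
                return chain
            chain.append(p)
            cur = p

    def alive_at(self, t: float) -> pd.DataFrame:
        """Cells alive at time ``t``: born by ``t`` and not yet ended
        (a cell ending exactly at ``t`` by division has already been
        replaced by its children)."""
        c = self.cells
        born = c["birth_h"] <= t + _TOL
        not_ended = (c["end_h"] > t + _TOL) | (
            (np.abs(c["end_h"] - t) <= _TOL) & (c["fate"] != "division")
        )
        return c[born & not_ended]


@dataclass(frozen=True)
class FractionWithSE:
    """A proportion with its Wald binomial standard error.

    Constructed from counts (:meth:`from_counts`) or directly from a
    proportion and SE (:meth:`from_proportion`, which backs out an effective
    denominator). ``excluded`` reports observations dropped before counting
    (e.g. indeterminate classifications).
    """

    fraction: float
    se: float
    numerator: float | None = None
    denominator: float | None = None
    excluded: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")
        if self.se < 0:
            raise ValueError(f"se must be >= 0, got {self.se}")

    @classmethod
    def from_counts(cls, k: float, n: float, excluded: int = 0) -> "FractionWithSE":
        if n <= 0:
            raise ValueError("denominator must be > 0")
        if not (0 <= k <= n):
            raise ValueError(f"numerator must be in [0, n={n}], got {k}")
        p = k / n
        return cls(
            fraction=p,
            se=math.sqrt(p * (1.0 - p) / n),
            numerator=k,
            denominator=n,
            excluded=excluded,
        )

    @classmethod
    def from_proportion(cls, p: float, se: float) -> "FractionWithSE":
        n = p * (1.0 - p) / se**2 if se > 0 and 0 < p < 1 else None
        return cls(fraction=p, se=se, numerator=None, denominator=n)


def division_rate(n_divisions: int, duration_h: float) -> float:
    """Division rate D(sigma)/T(sigma) in doublings/h."""
    if duration_h <= 0:
        raise ValueError("duration must be > 0")
    if n_divisions < 0:
        raise ValueError("n_divisions must be >= 0")
    return n_divisions / duration_h


def path_division_rate(
    table: LineageTable,
    path: Sequence,
    t_start: float,
    t_end: float,
) -> float:
    """Division rate along a lineage path within [t_start, t_end].

    Counts division events (a path cell ending by division) with
    ``t_start < end <= t_end``; the duration is measured from the later of
    ``t_start`` and the path's first birth.
    """
    first_birth = float(table.cell(path[0])["birth_h"])
    start = max(t_start, first_birth)
    if t_end <= start:
        raise ValueError("empty observation window for this lineage")
    n_div = 0
    for cid in path:
        row = table.cell(cid)
        if row["fate"] == "division" and start < row["end_h"] <= t_end + _TOL:
            n_div += 1
    return division_rate(n_div, t_end - start)


def sample_independent_lineages(
    table: LineageTable,
    t_exposure: float,
    seed: int | None = 0,
    founders: Iterable | None = None,
) -> list[list]:
    """One lineage path per founder, choosing a random sister at each
    division up to exposure onset. Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    if founders is None:
        founder_ids = table.founders["cell_id"].tolist()
    else:
        founder_ids = list(founders)
    paths = []
    for fid in founder_ids:
        path = [fid]
        cur = fid
        while True:
            row = table.cell(cur)
            if row["fate"] != "division" or row["end_h"] > t_exposure + _TOL:
                break
            kids = table.children(cur)
            if not kids:
                break
            cur = kids[rng.integers(len(kids))]
            path.append(cur)
        paths.append(path)
    return paths


def _window_areas(
    frames: pd.DataFrame, cell_id, t0: float, t1: float
) -> tuple[float, float] | None:
    """First and last observed area of a cell within [t0, t1]."""
    sub = frames[
        (frames["cell_id"] == cell_id)
        & (frames["t_h"] >= t0 - _TOL)
        & (frames["t_h"] <= t1 + _TOL)
    ].sort_values("t_h")
    if sub.empty:
        return None
    areas = sub["area_um2"].to_numpy()
    return float(areas[0]), float(areas[-1])


def classify_pre_exposure(
    table: LineageTable,
    cell_id,
    t_exposure: float,
    window: float = 1.5,
    elongation_threshold: float = 0.10,
) -> str:
    """Classify one exposure-onset cell as growing / non_growing / indeterminate.

    A cell is non-growing iff no division occurred on its ancestry during the
    ``window`` hours before ``t_exposure`` AND its relative area increase over
    that window is below ``elongation_threshold``. A lineage lost to tracking
    inside the window is indeterminate, as is a cell without frame data.
    """
    ws = t_exposure - window
    row = table.cell(cell_id)
    root = table.cell(table.ancestors(cell_id)[-1])
    if ws < root["birth_h"] - _TOL:
        raise ValueError(
            f"window start {ws} h precedes observation start {root['birth_h']} h"
        )
    if row["fate"] == "tracking_lost" and row["end_h"] <= t_exposure + _TOL:
        return "indeterminate"
    # born inside the window by a division => the lineage divided in-window
    if row["birth_h"] > ws + _TOL and pd.notna(row["parent_id"]):
        return "growing"
    if table.frames is None:
        return "indeterminate"
    areas = _window_areas(table.frames, cell_id, ws, t_exposure)
    if areas is None:
        return "indeterminate"
    a0, a1 = areas
    if (a1 - a0) / a0 >= elongation_threshold:
        return "growing"
    return "non_growing"


def classify_population(
    table: LineageTable,
    t_exposure: float,
    window: float = 1.5,
    elongation_threshold: float = 0.10,
) -> pd.DataFrame:
    """Vectorised classification of every cell alive at exposure onset.

    Returns a DataFrame with columns ``cell_id`` and ``label``. Semantics
    match :func:`classify_pre_exposure`.
    """
    alive = table.alive_at(t_exposure)
    ws = t_exposure - window
    ids = alive["cell_id"].to_numpy()
    labels = np.full(len(alive), "", dtype=object)

    born_in_window = (alive["birth_h"].to_numpy() > ws + _TOL) & alive[
        "parent_id"
    ].notna().to_numpy()
    labels[born_in_window] = "growing"

    rest = ~born_in_window
    if table.frames is None:
        labels[rest] = "indeterminate"
    else:
        rest_ids = set(ids[rest])
        fr = table.frames[
            table.frames["cell_id"].isin(rest_ids)
            & (table.frames["t_h"] >= ws - _TOL)
            & (table.frames["t_h"] <= t_exposure + _TOL)
        ].sort_values(["cell_id", "t_h"])
        g = fr.groupby("cell_id")["area_um2"]
        first = g.first()
        last = g.last()
        rel = ((last - first) / first).to_dict()
        for i in np.flatnonzero(rest):
            r = rel.get(ids[i])
            if r is None:
                labels[i] = "indeterminate"
            else:
                labels[i] = "growing" if r >= elongation_threshold else "non_growing"
    return pd.DataFrame({"cell_id": ids, "label": labels})


def non_growing_fraction(labels: Iterable[str]) -> FractionWithSE:
    """Non-growing fraction with binomial SE; indeterminate labels are
    excluded from numerator and denominator, with the count reported."""
    counts = {lab: 0 for lab in LABELS}
    for lab in labels:
        if lab not in counts:
            raise ValueError(f"unknown label {lab!r}")
        counts[lab] += 1
    n = counts["growing"] + counts["non_growing"]
    if n == 0:
        raise ValueError("no determinate labels")
    return FractionWithSE.from_counts(
        counts["non_growing"], n, excluded=counts["indeterminate"]
    )


def persister_frequency_from_chambers(
    persister_count: int,
    sampled_chamber_cell_counts: Sequence[float],
    n_chambers: int,
) -> FractionWithSE:
    """Persister frequency among drug-exposed cells.

    The exposed-cell total is the mean cell count over the sampled chambers
    multiplied by the number of chambers tracked; the frequency carries a
    Wald binomial SE.
    """
    counts = np.asarray(sampled_chamber_cell_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("sampled chamber counts must be non-empty")
    if persister_count < 0:
        raise ValueError("persister_count must be >= 0")
    mean_count = float(counts.mean())
    if mean_count <= 0:
        raise ValueError("mean chamber cell count must be > 0")
    total = mean_count * n_chambers
    return FractionWithSE.from_counts(persister_count, total)


@dataclass(frozen=True)
class ShapeMetrics:
    area_um2: float
    perimeter_um: float
    circularity: float


def shape_metrics(polygon) -> ShapeMetrics:
    """Area (shoelace), perimeter and circularity 4*pi*A/P^2 of a cell outline.

    Accepts a shapely Polygon or a vertex sequence. Duplicate consecutive
    vertices are dropped; self-intersecting outlines are rejected.
    """
    if isinstance(polygon, Polygon):
        poly = polygon
    else:
        verts = np.asarray(polygon, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
            raise ValueError("polygon must be a sequence of >= 3 (x, y) vertices")
        keep = [0]
        for i in range(1, len(verts)):
            if not np.allclose(verts[i], verts[keep[-1]]):
                keep.append(i)
        verts = verts[keep]
        if np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        if len(verts) < 3:
            raise ValueError("fewer than 3 distinct vertices")
        poly = Polygon(verts)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("self-intersecting or otherwise invalid polygon")
    area = poly.area
    perim = poly.length
    if area <= 0 or perim <= 0:
        raise ValueError("degenerate polygon")
    circ = 4.0 * math.pi * area / perim**2
    return ShapeMetrics(area_um2=area, perimeter_um=perim, circularity=min(circ, 1.0))


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when the smaller sample has at most 10
    observations and there are no ties, otherwise the normal approximation
    with tie and continuity corrections. Returns ``(U, p)`` with U counted
    for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if min(x.size, y.size) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class DivisionRateComparison:
    """Group summary of pre-exposure division rates plus rank-sum p-value."""

    n_persisters: int
    n_non_persisters: int
    mean_persisters: float
    se_persisters: float
    mean_non_persisters: float
    se_non_persisters: float
    u_statistic: float
    p_value: float
    rates_persisters: tuple[float, ...] = field(repr=False, default=())
    rates_non_persisters: tuple[float, ...] = field(repr=False, default=())


def _mean_se(vals: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return mean, se


def compare_division_rates(
    table: LineageTable,
    t_exposure: float,
    seed: int | None = 0,
    t_start: float = 0.0,
) -> DivisionRateComparison:
    """Compare pre-exposure division rates of persister vs non-persister founders.

    One independent lineage is sampled per founder (random sister at each
    division); rates are D(sigma)/T(sigma) over [t_start, t_exposure].
    """
    founders = table.founders
    pers_ids = founders.loc[founders["persister"].astype(bool), "cell_id"].tolist()
    non_ids = founders.loc[~founders["persister"].astype(bool), "cell_id"].tolist()
    if not pers_ids or not non_ids:
        raise ValueError("both persister and non-persister founders are required")
    rng = np.random.default_rng(seed)
    pers_paths = sample_independent_lineages(
        table, t_exposure, seed=int(rng.integers(2**31)), founders=pers_ids
    )
    non_paths = sample_independent_lineages(
        table, t_exposure, seed=int(rng.integers(2**31)), founders=non_ids
    )
    r_pers = np.array(
        [path_division_rate(table, p, t_start, t_exposure) for p in pers_paths]
    )
    r_non = np.array(
        [path_division_rate(table, p, t_start, t_exposure) for p in non_paths]
    )
    u, p = rank_sum_test(r_pers, r_non)
    m_p, se_p = _mean_se(r_pers)
    m_n, se_n = _mean_se(r_non)
    return DivisionRateComparison(
        n_persisters=len(r_pers),
        n_non_persisters=len(r_non),
        mean_persisters=m_p,
        se_persisters=se_p,
        mean_non_persisters=m_n,
        se_non_persisters=se_n,
        u_statistic=u,
        p_value=p,
        rates_persisters=tuple(r_pers),
        rates_non_persisters=tuple(r_non),
    )
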