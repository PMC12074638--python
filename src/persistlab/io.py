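"""Table schemas, run configuration and the end-to-end report generator.

All tables are plain UTF-8 CSV/TSV with '.' decimals and a required header.
Times are in hours, areas in square micrometres, densities in cells/mL.
Polygon outlines, when present, are well-known-text strings in a single
column so the frames table stays flat.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from persistlab import __version__
from persistlab.decay import SelectionResult, select_n
from persistlab.dilution import (
    KillingCurve,
    SurvivingFraction,
    WellPlate,
    build_killing_curve,
    surviving_fraction,
)
from persistlab.lineage import (
    FractionWithSE,
    LineageTable,
    classify_population,
    compare_division_rates,
    non_growing_fraction,
)
from persistlab.survival import ConditionRecord, fit_survival_model

__all__ = [
    "SchemaError",
    "REPORT_SCHEMA_VERSION",
    "read_plates",
    "write_plates",
    "read_curve",
    "write_curve",
    "read_lineage",
    "write_lineage",
    "read_conditions",
    "write_conditions",
    "RunConfig",
    "run_report",
    "validate_report",
    "write_json",
]

logger = logging.getLogger("persistlab")

REPORT_SCHEMA_VERSION = 1

PLATE_COLUMNS = ["replicate", "time_h", "dilution", "wells", "non_turbid", "volume_ml"]
CURVE_COLUMNS = ["replicate", "time_h", "density"]
CELL_COLUMNS = ["cell_id", "parent_id", "chamber_id", "birth_h", "end_h", "fate", "persister"]
FRAME_COLUMNS = ["cell_id", "t_h", "area_um2"]
CONDITION_COLUMNS = ["condition", "Pn", "Pn_se", "f", "f_lower", "f_upper"]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _read_table(path, required: Sequence[str], sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _require_numeric(df: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header line and 1-based
            raise SchemaError(
                f"{path}: non-numeric values in column {col!r} at line(s) {lines}"
            )
        df[col] = coerced
    return df


def read_plates(path) -> list[WellPlate]:
    """Load limiting-dilution plates from CSV (see PLATE_COLUMNS)."""
    df = _read_table(path, PLATE_COLUMNS, sep=",")
    df = _require_numeric(df, ["time_h", "dilution", "wells", "non_turbid", "volume_ml"], path)
    plates = []
    for i, row in df.iterrows():
        try:
            plates.append(
                WellPlate(
                    dilution=float(row["dilution"]),
                    wells=int(row["wells"]),
                    non_turbid=int(row["non_turbid"]),
                    volume_ml=float(row["volume_ml"]),
                    time_h=float(row["time_h"]),
                    replicate=row["replicate"],
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: line {int(i) + 2}: {exc}") from exc
    return plates


def write_plates(plates: Sequence[WellPlate], path) -> None:
    pd.DataFrame(
        [
            {
                "replicate": p.replicate,
                "time_h": p.time_h,
                "dilution": p.dilution,
                "wells": p.wells,
                "non_turbid": p.non_turbid,
                "volume_ml": p.volume_ml,
            }
            for p in plates
        ],
        columns=PLATE_COLUMNS,
    ).to_csv(path, index=False)


def read_curve(path) -> KillingCurve:
    """Load a killing curve (replicate densities) from CSV."""
    df = _read_table(path, CURVE_COLUMNS, sep=",")
    df = _require_numeric(df, ["time_h", "density"], path)
    return KillingCurve(densities=df[CURVE_COLUMNS])


def write_curve(curve: KillingCurve, path) -> None:
    curve.densities[CURVE_COLUMNS].to_csv(path, index=False)


def read_lineage(cells_path, frames_path=None) -> LineageTable:
    """Load a lineage forest from TSV file(s).

    The frames table is optional; without it, classification that relies on
    cell areas reports indeterminate labels.
    """
    cells = _read_table(cells_path, CELL_COLUMNS, sep="\t")
    cells = _require_numeric(cells, ["birth_h", "end_h"], cells_path)
    cells["persister"] = cells["persister"].astype(bool)
    frames = None
    if frames_path is not None:
        frames = _read_table(frames_path, FRAME_COLUMNS, sep="\t")
        frames = _require_numeric(frames, ["t_h", "area_um2"], frames_path)
        if "outline_wkt" not in frames.columns:
            logger.info("%s: no outline_wkt column; circularity unavailable", frames_path)
    try:
        return LineageTable(cells=cells, frames=frames)
    except ValueError as exc:
        raise SchemaError(f"{cells_path}: {exc}") from exc


def write_lineage(table: LineageTable, cells_path, frames_path=None) -> None:
    table.cells[CELL_COLUMNS].to_csv(cells_path, sep="\t", index=False)
    if frames_path is not None and table.frames is not None:
        cols = [c for c in [*FRAME_COLUMNS, "outline_wkt"] if c in table.frames.columns]
        table.frames[cols].to_csv(frames_path, sep="\t", index=False)


def read_conditions(path) -> list[ConditionRecord]:
    """Load per-condition (Pn, f) observations from CSV."""
    df = _read_table(path, CONDITION_COLUMNS, sep=",")
    df = _require_numeric(df, ["Pn", "Pn_se", "f", "f_lower", "f_upper"], path)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ConditionRecord(
                    name=str(row["condition"]),
                    pn=FractionWithSE.from_proportion(float(row["Pn"]), float(row["Pn_se"])),
                    observed_f=SurvivingFraction(
                        time_h=float(row.get("time_h", 0.0)) if "time_h" in df.columns else 0.0,
                        fraction=float(row["f"]),
                        lower=float(row["f_lower"]),
                        upper=float(row["f_upper"]),
                    ),
                    growing_persisters_present=bool(row.get("growing_persisters", False))
                    if "growing_persisters" in df.columns
                    else False,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: line {int(i) + 2}: {exc}") from exc
    return records


def write_conditions(conditions: Sequence[ConditionRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "condition": c.name,
                "Pn": c.pn.fraction,
                "Pn_se": c.pn.se,
                "f": c.observed_f.fraction,
                "f_lower": c.observed_f.lower,
                "f_upper": c.observed_f.upper,
            }
            for c in conditions
        ],
        columns=CONDITION_COLUMNS,
    ).to_csv(path, index=False)


class ProtocolConfig(BaseModel):
    pre_exposure_h: float = Field(1.5, gt=0)
    exposure_h: float = Field(6.0, gt=0)
    frame_interval_h: float = Field(0.05, gt=0)
    antibiotic: str = "Amp"


class AnalysisConfig(BaseModel):
    n_max: int = Field(3, ge=1)
    starts: int = Field(20, ge=1)
    elongation_threshold: float = Field(0.10, ge=0)
    window_h: float = Field(1.5, gt=0)
    anchor: str | None = None
    s_method: str = "linear"
    surviving_fraction_time_h: float | None = None

    @field_validator("s_method")
    @classmethod
    def _check_method(cls, v: str) -> str:
        if v not in ("linear", "log"):
            raise ValueError("s_method must be 'linear' or 'log'")
        return v


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    plates_csv: str
    lineage_cells_tsv: str
    lineage_frames_tsv: str | None = None
    conditions_csv: str | None = None
    output_dir: str = "persistlab_report"
    protocol: ProtocolConfig = ProtocolConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    seed: int = 0
    make_plots: bool = True

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = cls.model_validate_json(fh.read())
        cfg.check_paths()
        return cfg

    def check_paths(self) -> None:
        for attr in ("plates_csv", "lineage_cells_tsv", "lineage_frames_tsv", "conditions_csv"):
            val = getattr(self, attr)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{attr}: {val} does not exist")


def _selection_to_dict(sel: SelectionResult) -> dict:
    return {
        "chosen_n": sel.chosen_n,
        "candidates": [
            {
                "n": f.n,
                "amplitudes": list(f.model.amplitudes),
                "rates": list(f.model.rates),
                "ssr": f.ssr,
                "n_points": f.n_points,
                "k_params": f.k_params,
                "aic": f.aic,
                "converged": f.converged,
                "n_starts_used": f.n_starts_used,
                "flags": list(f.flags),
            }
            for f in sel.fits
        ],
    }


def validate_report(report: dict) -> None:
    """Check the report dictionary against the versioned schema."""
    required = {"schema_version", "package_version", "seed", "killing_curve", "lineage"}
    missing = required - set(report)
    if missing:
        raise SchemaError(f"report missing keys: {sorted(missing)}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise SchemaError(f"unsupported report schema version {report['schema_version']}")


def write_json(obj: dict, path) -> None:
    """Deterministic JSON: sorted keys, no trailing whitespace variance."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _plot_killcurve(curve: KillingCurve, sel: SelectionResult, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    s = curve.summary
    ax.errorbar(
        s["time_h"], s["mean_log10"], yerr=s["se_log10"], fmt="o", capsize=3, label="data"
    )
    tt = np.linspace(s["time_h"].min(), s["time_h"].max(), 200)
    ax.plot(tt, np.log10(sel.chosen.model.evaluate(tt)), "-", label=f"n={sel.chosen_n} fit")
    ax.set_xlabel("time under exposure (h)")
    ax.set_ylabel("log10 viable density (cells/mL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_survival(model, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    pn_grid = np.logspace(-5, 0, 100)
    ax.fill_between(
        pn_grid, model.s.lower * pn_grid, model.s.upper * pn_grid, alpha=0.3, label="prediction band"
    )
    ax.plot(pn_grid, model.s.s * pn_grid, "--", label="f = s*Pn")
    for a in model.assessments:
        c = a.condition
        ax.errorbar(
            c.pn.fraction,
            max(c.observed_f.fraction, 1e-12),
            xerr=c.pn.se,
            yerr=[
                [max(c.observed_f.fraction - c.observed_f.lower, 0.0)],
                [max(c.observed_f.upper - c.observed_f.fraction, 0.0)],
            ],
            fmt="o",
            label=c.name,
        )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("non-growing fraction Pn")
    ax.set_ylabel("persister frequency f")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_report(config: RunConfig) -> dict:
    """Run the full pipeline and write a machine-readable report.

    Stages: plate MPN -> killing curve -> decay fit and phase selection ->
    lineage classification and statistics -> survival model. Any stage
    failure aborts with the stage name attached. Deterministic given the
    configured seed.
    """
    config.check_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("persistlab %s, seed=%d", __version__, config.seed)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
    }

    stage = "killing curve assembly"
    try:
        plates = read_plates(config.plates_csv)
        curve = build_killing_curve(plates)
        t_end = config.analysis.surviving_fraction_time_h or config.protocol.exposure_h
        frac = surviving_fraction(curve, t_end)
        report["killing_curve"] = {
            "summary": curve.summary.to_dict(orient="list"),
            "surviving_fraction": {
                "time_h": frac.time_h,
                "fraction": frac.fraction,
                "lower": frac.lower,
                "upper": frac.upper,
            },
        }

        stage = "decay fitting"
        mean = curve.mean_densities()
        mean = mean[mean["density"] > 0]
        sel = select_n(
            mean["time_h"].to_numpy(),
            mean["density"].to_numpy(),
            n_max=config.analysis.n_max,
            starts=config.analysis.starts,
            seed=config.seed,
        )
        report["decay_fit"] = _selection_to_dict(sel)

        stage = "lineage statistics"
        table = read_lineage(config.lineage_cells_tsv, config.lineage_frames_tsv)
        t_exp = config.protocol.pre_exposure_h
        labels = classify_population(
            table,
            t_exposure=t_exp,
            window=config.analysis.window_h,
            elongation_threshold=config.analysis.elongation_threshold,
        )
        pn = non_growing_fraction(labels["label"])
        lineage_section: dict = {
            "n_classified": int(pn.denominator),
            "n_indeterminate": pn.excluded,
            "non_growing_fraction": pn.fraction,
            "non_growing_se": pn.se,
        }
        founders = table.founders
        n_persisters = int(founders["persister"].astype(bool).sum())
        lineage_section["n_founders"] = int(len(founders))
        lineage_section["n_persister_founders"] = n_persisters
        if n_persisters == 0:
            # no persisters observed: report 0 with a rule-of-three upper bound
            n_f = len(founders)
            lineage_section["persister_frequency"] = 0.0
            lineage_section["persister_frequency_upper_bound"] = 3.0 / n_f if n_f else None
        elif n_persisters < len(founders):
            cmp_res = compare_division_rates(table, t_exposure=t_exp, seed=config.seed)
            lineage_section["division_rate_comparison"] = {
                "n_persisters": cmp_res.n_persisters,
                "n_non_persisters": cmp_res.n_non_persisters,
                "mean_persisters": cmp_res.mean_persisters,
                "se_persisters": cmp_res.se_persisters,
                "mean_non_persisters": cmp_res.mean_non_persisters,
                "se_non_persisters": cmp_res.se_non_persisters,
                "u_statistic": cmp_res.u_statistic,
                "p_value": cmp_res.p_value,
            }
        report["lineage"] = lineage_section

        stage = "survival model"
        if config.conditions_csv is not None:
            conditions = read_conditions(config.conditions_csv)
        else:
            conditions = [
                ConditionRecord(name="this_run", pn=pn, observed_f=frac)
            ]
        model = fit_survival_model(
            conditions, anchor=config.analysis.anchor, method=config.analysis.s_method
        )
        report["survival_model"] = {
            "anchor": model.anchor,
            "s": model.s.s,
            "s_se": model.s.se,
            "s_lower": model.s.lower,
            "s_upper": model.s.upper,
            "method": model.s.method,
            "conditions": [
                {
                    "name": a.condition.name,
                    "Pn": a.condition.pn.fraction,
                    "observed_f": a.condition.observed_f.fraction,
                    "predicted_f": a.predicted.f,
                    "band": [a.predicted.lower, a.predicted.upper],
                    "classification": a.classification,
                    "note": a.note,
                }
                for a in model.assessments
            ],
        }

        stage = "report output"
        validate_report(report)
        write_json(report, outdir / "report.json")
        if config.make_plots:
            _plot_killcurve(curve, sel, outdir / "killing_curve.png")
            _plot_survival(model, outdir / "observed_vs_predicted.png")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during stage: {stage}") from exc
    return report
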