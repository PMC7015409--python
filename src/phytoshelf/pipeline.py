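"""End-to-end orchestration: data -> transform -> fit -> shelf-life -> report.

``run_pipeline`` takes assay data (from CSV or the synthetic generator), and
per treatment cell classifies the storage-time relation, derives the
shelf-life where the positive-quadratic construction applies, runs the
Arrhenius conformity check on the per-time mean series in real weeks, and the
one-way storage-time ANOVA on replicates. The result is a JSON-serialisable
report; single-cell failures are contained in that cell's record.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import anova_by_time, significance_label
from .exceptions import InsufficientDataError, ParseError, PhytoshelfError
from .fitting import ClassifierConfig, classify_relation
from .kinetics import conformity_test
from .shelflife import estimate
from .simulate import (
    ASSAY_COLUMNS,
    FLAT,
    NEGATIVE_LINEAR,
    POSITIVE_QUADRATIC,
    StudyDesign,
    TrajectorySpec,
    default_trajectories,
    generate,
)
from .timegrid import PER_TIME_MEANS, REPLICATE_LEVEL, to_series

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run depends on; hashable into the report metadata."""

    input_csv: str | None = None  # None: generate synthetic data
    design: StudyDesign = field(default_factory=StudyDesign)
    trajectories: dict | None = None  # cell -> TrajectorySpec overrides
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    conformity_r2_threshold: float = 0.8
    alpha: float = 0.05


def load_config(path, seed: int | None = None) -> PipelineConfig:
    """Read a flat TOML config mirroring the study-design fields."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    design_kwargs = {}
    for key in ("time_frames_weeks", "n_replicates", "compounds", "drying_temps_C",
                "conditions", "noise_sd", "ph_jitter_sd", "seed"):
        if key in raw:
            val = raw[key]
            design_kwargs[key] = tuple(val) if isinstance(val, list) else val
    if seed is not None:
        design_kwargs["seed"] = seed
    cls_kwargs = {
        k: raw[k]
        for k in ("quad_margin", "min_r2", "flat_sst", "alpha", "aggregation")
        if k in raw
    }
    trajectories = None
    if "trajectories" in raw:
        trajectories = dict(default_trajectories())
        for key, spec in raw["trajectories"].items():
            compound, temp, condition = key.split("/")
            trajectories[(compound, int(temp), condition)] = TrajectorySpec(
                shape=spec["shape"],
                coefficients=tuple(spec["coefficients"]),
                ph_level=spec.get("ph_level", 3.7),
            )
    return PipelineConfig(
        input_csv=raw.get("input_csv"),
        design=StudyDesign(**design_kwargs),
        trajectories=trajectories,
        classifier=ClassifierConfig(**cls_kwargs),
        conformity_r2_threshold=raw.get("conformity_r2_threshold", 0.8),
        alpha=raw.get("alpha", 0.05),
    )


def read_samples(path) -> pd.DataFrame:
    """Read and validate an assay CSV into the tidy sample table.

    Malformed rows are rejected with an error naming the first offending row
    (1-based, counting the header as line 1) and field. A header-only file
    yields an empty table with a warning.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise ParseError(f"{path}: empty file, no header") from err
    missing = [c for c in ASSAY_COLUMNS if c != "ph" and c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if "ph" not in df.columns:
        df["ph"] = np.nan
    if df.empty:
        logger.warning("%s contains a header but no data rows", path)
        return df[ASSAY_COLUMNS]

    for col in ("time_weeks", "concentration_ug_per_ml", "ph"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col, ok in (
        ("time_weeks", lambda s: s.notna() & (s >= 0)),
        ("concentration_ug_per_ml", lambda s: s.notna() & (s >= 0)),
    ):
        bad = ~ok(df[col])
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header + 1-based
            raise ParseError(
                f"{path}: line {row}: invalid value {df.loc[df.index[bad][0], col]!r} "
                f"in field '{col}'"
            )
    df["drying_temp_C"] = df["drying_temp_C"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    return df[ASSAY_COLUMNS]


def _cell_record(cell, cell_df, config: PipelineConfig) -> dict:
    compound, temp, condition = cell
    record: dict = {
        "compound": compound,
        "drying_temp_C": int(temp),
        "condition": condition,
        "n_samples": int(len(cell_df)),
    }
    series = to_series(cell_df, cell, aggregation=REPLICATE_LEVEL)
    relation = classify_relation(series, config.classifier)
    record["relation"] = {
        "label": relation.label,
        "reason": relation.reason,
        "anova_p": relation.anova_p,
    }
    if relation.quadratic is not None:
        q = relation.quadratic
        record["quadratic"] = dataclasses.asdict(q) | {
            "r_squared_display": round(q.r_squared, 2)
        }
    if relation.linear is not None:
        lin = relation.linear
        record["linear"] = dataclasses.asdict(lin) | {
            "r_squared_display": round(lin.r_squared, 2)
        }

    sl = estimate(relation)
    sl_dict = {"predictable": sl.predictable, "reason": sl.reason}
    if sl.predictable:
        sl_dict.update(
            extremum_x=sl.extremum_x, root_neg=sl.root_neg, root_pos=sl.root_pos,
            x3=sl.x3, shelf_life_weeks=sl.shelf_life_weeks,
            shelf_life_weeks_display=sl.shelf_life_weeks_rounded,
            y_at_x3=sl.y_at_x3, extrapolated=sl.extrapolated,
        )
        if sl.extrapolated:
            logger.warning("cell %s: shelf-life x3 = %.3f extrapolates beyond the design grid",
                           cell, sl.x3)
    record["shelf_life"] = sl_dict

    means = to_series(cell_df, cell, aggregation=PER_TIME_MEANS)
    verdict = conformity_test(
        means.time_weeks, means.y, r2_threshold=config.conformity_r2_threshold
    )
    record["arrhenius_conformity"] = {
        "conforms": verdict.conforms,
        "reason": verdict.reason,
        "best_order": dataclasses.asdict(verdict.best_order) if verdict.best_order else None,
    }

    table = anova_by_time(cell_df)
    record["anova"] = dataclasses.asdict(table) | {
        "significance": significance_label(table.p_value, config.alpha)
    }
    record["ph_mean"] = float(cell_df["ph"].mean()) if cell_df["ph"].notna().any() else None
    return record


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run the full analysis; returns the report as a plain dict.

    Deterministic given (input data, config): the only randomness is the
    generator's, driven by ``config.design.seed``.
    """
    config = config or PipelineConfig()
    if config.input_csv is not None:
        samples = read_samples(config.input_csv)
        source = str(config.input_csv)
    else:
        samples = generate(config.design, config.trajectories)
        source = "synthetic"

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "seed": config.design.seed,
        "config_hash": _config_hash(config),
        "data_source": source,
        "n_samples": int(len(samples)),
        "cells": [],
    }
    if samples.empty:
        logger.warning("no samples; report has zero cells")
        return report

    cells = sorted(
        samples[["compound", "drying_temp_C", "condition"]]
        .drop_duplicates()
        .itertuples(index=False, name=None)
    )
    for cell in cells:
        compound, temp, condition = cell
        cell_df = samples[
            (samples["compound"] == compound)
            & (samples["drying_temp_C"] == temp)
            & (samples["condition"] == condition)
        ]
        try:
            record = _cell_record(cell, cell_df, config)
        except PhytoshelfError as err:
            record = {
                "compound": compound, "drying_temp_C": int(temp),
                "condition": condition, "error": str(err),
            }
            logger.warning("cell %s failed: %s", cell, err)
        report["cells"].append(record)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else repr(f)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_report(report: dict, path) -> None:
    """Serialise the report to JSON (full precision, stable key order)."""
    Path(path).write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
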