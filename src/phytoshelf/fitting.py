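"""OLS fits of storage trajectories on the log3-time axis and relation typing.

A cell's mean structure is fitted with a quadratic (a x^2 + b x + c) and a
straight line by ordinary least squares (closed-form normal equations via a
Vandermonde design). ``classify_relation`` then assigns one of four relation
labels:

* ``positive_quadratic`` — downward-opening parabola rising then falling
  (a < 0, b > 0), the non-Arrhenius signature that admits a shelf-life;
* ``negative_linear`` — monotone linear decline;
* ``flat`` — no credible storage-time signal;
* ``other`` — anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anova import one_way_anova
from .exceptions import InsufficientDataError, RankDeficiencyError
from .timegrid import PER_TIME_MEANS, REPLICATE_LEVEL, TransformedSeries

POSITIVE_QUADRATIC = "positive_quadratic"
NEGATIVE_LINEAR = "negative_linear"
FLAT = "flat"
OTHER = "other"


@dataclass(frozen=True)
class QuadraticModel:
    a: float
    b: float
    c: float
    r_squared: float
    n_points: int
    sse: float
    sst: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.a * x * x + self.b * x + self.c


@dataclass(frozen=True)
class LinearModel:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    sse: float
    sst: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds for relation typing (all configurable, none canonical)."""

    quad_margin: float = 0.05  # R^2 edge the quadratic needs over the line
    min_r2: float = 0.5  # below this for both models the cell is flat
    flat_sst: float = 1e-6  # (ug/ml)^2; zero-variance guard
    alpha: float = 0.05  # ANOVA gate on the storage-time effect
    aggregation: str = PER_TIME_MEANS  # axis the models are fitted on


@dataclass(frozen=True)
class RelationClass:
    label: str
    chosen_model: QuadraticModel | LinearModel | None
    quadratic: QuadraticModel | None = None
    linear: LinearModel | None = None
    anova_p: float | None = None
    x_min: float = 0.0
    x_max: float = 0.0
    reason: str = ""


def _ols(x: np.ndarray, y: np.ndarray, degree: int):
    """Least-squares polynomial fit; returns (coef ascending, sse, sst, r2)."""
    V = np.vander(x, degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(V, y, rcond=None)
    if rank < degree + 1:
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {degree + 1}; x values collapse the fit"
        )
    resid = y - V @ coef
    sse = float(resid @ resid)
    dev = y - y.mean()
    sst = float(dev @ dev)
    r2 = 1.0 - sse / sst if sst > 0 else 0.0  # SST = 0 convention: R^2 = 0
    r2 = min(max(r2, 0.0), 1.0)
    return coef, sse, sst, r2


def fit_quadratic(series: TransformedSeries) -> QuadraticModel:
    """OLS quadratic fit; needs >= 3 distinct x (exact interpolation at 3)."""
    x, y = series.x, series.y
    if np.unique(x).size < 3:
        raise InsufficientDataError(
            f"quadratic fit needs >= 3 distinct x values, got {np.unique(x).size}"
        )
    coef, sse, sst, r2 = _ols(x, y, 2)
    return QuadraticModel(
        a=float(coef[2]), b=float(coef[1]), c=float(coef[0]),
        r_squared=r2, n_points=x.size, sse=sse, sst=sst,
    )


def fit_linear(series: TransformedSeries) -> LinearModel:
    """OLS straight-line fit; needs >= 2 distinct x."""
    x, y = series.x, series.y
    if np.unique(x).size < 2:
        raise InsufficientDataError(
            f"linear fit needs >= 2 distinct x values, got {np.unique(x).size}"
        )
    coef, sse, sst, r2 = _ols(x, y, 1)
    return LinearModel(
        slope=float(coef[1]), intercept=float(coef[0]),
        r_squared=r2, n_points=x.size, sse=sse, sst=sst,
    )


def _per_time_means(series: TransformedSeries) -> TransformedSeries:
    xs = np.unique(series.x)
    ys = np.array([series.y[series.x == xv].mean() for xv in xs])
    weeks = None
    if series.time_weeks is not None:
        weeks = np.array([series.time_weeks[series.x == xv][0] for xv in xs])
    return TransformedSeries(
        x=xs, y=ys, label=series.label, aggregation=PER_TIME_MEANS, time_weeks=weeks
    )


def _time_anova_p(series: TransformedSeries) -> float | None:
    """One-way ANOVA p for the storage-time effect, if replicates exist."""
    groups = [series.y[series.x == xv] for xv in np.unique(series.x)]
    if len(groups) < 2 or min(g.size for g in groups) < 2:
        return None
    return one_way_anova(groups).p_value


def classify_relation(
    series: TransformedSeries, config: ClassifierConfig | None = None
) -> RelationClass:
    """Assign a relation label to one treatment cell.

    Decision order: (1) a replicate-level one-way ANOVA gate — no significant
    storage-time effect means ``flat`` (cells the emulated study reports as
    "not significant" and leaves unmodelled); (2) zero-variance / weak-fit
    guards; (3) the quadratic is preferred over the line when its R^2 edge
    reaches ``quad_margin`` and its signs are the rise-then-fall pattern;
    (4) otherwise a declining line is ``negative_linear``; anything left is
    ``other``. Fits use per-time means by default.
    """
    cfg = config or ClassifierConfig()
    anova_p = _time_anova_p(series) if series.aggregation == REPLICATE_LEVEL else None

    fit_series = series
    if cfg.aggregation == PER_TIME_MEANS and series.aggregation == REPLICATE_LEVEL:
        fit_series = _per_time_means(series)
    x_min, x_max = float(fit_series.x.min()), float(fit_series.x.max())

    base = dict(anova_p=anova_p, x_min=x_min, x_max=x_max)

    sst = float(np.sum((fit_series.y - fit_series.y.mean()) ** 2))
    if sst >= cfg.flat_sst:  # fits are reported even for gated-flat cells
        base.update(quadratic=fit_quadratic(fit_series), linear=fit_linear(fit_series))

    if anova_p is not None and anova_p > cfg.alpha:
        return RelationClass(
            FLAT, None, reason=f"no significant storage-time effect (p = {anova_p:.3g})",
            **base,
        )
    if sst < cfg.flat_sst:
        return RelationClass(FLAT, None, reason="zero-variance response", **base)

    quad = base["quadratic"]
    lin = base["linear"]

    if max(quad.r_squared, lin.r_squared) < cfg.min_r2:
        return RelationClass(
            FLAT, None, reason="no model reaches the minimum R^2", **base
        )
    if (
        quad.r_squared - lin.r_squared >= cfg.quad_margin
        and quad.a < 0
        and quad.b > 0
    ):
        return RelationClass(POSITIVE_QUADRATIC, quad, reason="rise-then-fall parabola", **base)
    if lin.slope < 0 and lin.r_squared >= cfg.min_r2:
        return RelationClass(NEGATIVE_LINEAR, lin, reason="monotone linear decline", **base)
    return RelationClass(OTHER, lin, reason="no supported relation shape", **base)
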