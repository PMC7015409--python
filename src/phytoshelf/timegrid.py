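"""log3 encoding of the geometric storage-time grid.

Storage times are sampled on a geometric series (0, 3, 9, 27, 81, 243 weeks);
fitting happens on the log3 axis where that grid becomes 0..5. Week 0 (the
post-fermentation baseline) occupies the 3^0 slot by convention, so
``encode_time(0) == 0`` — the only point where encode/decode do not round-trip.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError

logger = logging.getLogger(__name__)

DEFAULT_GRID_WEEKS: tuple[float, ...] = (0.0, 3.0, 9.0, 27.0, 81.0, 243.0)

REPLICATE_LEVEL = "replicate_level"
PER_TIME_MEANS = "per_time_means"


def encode_time(weeks: float) -> float:
    """Map storage time in weeks to the log3 axis; week 0 maps to x = 0."""
    if not math.isfinite(weeks) or weeks < 0:
        raise ValueError(f"storage time must be a finite value >= 0 weeks, got {weeks!r}")
    if weeks == 0:
        return 0.0
    return math.log(weeks) / math.log(3.0)


def decode_time(x: float) -> float:
    """Antilog: log3 coordinate back to real weeks (3**x)."""
    if not math.isfinite(x):
        raise ValueError(f"log3 coordinate must be finite, got {x!r}")
    return 3.0 ** x


def encode_times(weeks) -> np.ndarray:
    return np.array([encode_time(w) for w in np.asarray(weeks, dtype=float)])


@dataclass(frozen=True)
class TransformedSeries:
    """(x, y) points on the log3-time axis for one treatment cell."""

    x: np.ndarray
    y: np.ndarray
    label: tuple = ()
    aggregation: str = PER_TIME_MEANS
    time_weeks: np.ndarray = field(default=None)  # original weeks, same order as x

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.time_weeks is not None:
            object.__setattr__(self, "time_weeks", np.asarray(self.time_weeks, dtype=float))
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have matching shapes")

    @property
    def n_points(self) -> int:
        return self.x.size


def to_series(
    samples: pd.DataFrame,
    cell: tuple[str, int, str],
    aggregation: str = PER_TIME_MEANS,
) -> TransformedSeries:
    """Extract one treatment cell and put it on the log3 axis.

    ``cell`` is (compound, drying_temp_C, condition). ``per_time_means``
    averages replicates within each sampling time; ``replicate_level`` keeps
    every row. At least 3 distinct times are required (a quadratic fit needs
    3 degrees of freedom).
    """
    compound, temp, condition = cell
    sub = samples[
        (samples["compound"] == compound)
        & (samples["drying_temp_C"] == temp)
        & (samples["condition"] == condition)
    ]
    times = np.sort(sub["time_weeks"].unique())
    if times.size < 3:
        raise InsufficientDataError(
            f"cell {cell} has {times.size} distinct time points; need >= 3"
        )
    if aggregation == PER_TIME_MEANS:
        means = sub.groupby("time_weeks")["concentration_ug_per_ml"].mean()
        weeks = means.index.to_numpy(dtype=float)
        y = means.to_numpy(dtype=float)
    elif aggregation == REPLICATE_LEVEL:
        ordered = sub.sort_values(["time_weeks", "replicate"], kind="mergesort")
        weeks = ordered["time_weeks"].to_numpy(dtype=float)
        y = ordered["concentration_ug_per_ml"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return TransformedSeries(
        x=encode_times(weeks), y=y, label=cell, aggregation=aggregation, time_weeks=weeks
    )
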