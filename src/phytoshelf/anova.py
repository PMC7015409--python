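"""One-way ANOVA of concentration on storage time, with %TTV.

TTV (total treatment variation) is reported as the share of the total sum of
squares attributed to the treatment factor, 100 * SS_treatment / SS_total —
the eta-squared reading of "percent of TTV".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError


@dataclass(frozen=True)
class AnovaTable:
    ss_treatment: float
    ss_error: float
    ss_total: float
    df_treatment: int
    df_error: int
    f_stat: float
    p_value: float
    ttv_percent: float


def one_way_anova(groups) -> AnovaTable:
    """Standard fixed-effects one-way decomposition over ``groups``.

    ``groups`` is a sequence of 1-D arrays, one per factor level (here the
    storage time-frames of one treatment cell). Requires >= 2 levels and
    >= 2 observations in every level so the error stratum has df.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InsufficientDataError("one-way ANOVA needs >= 2 factor levels")
    if min(g.size for g in groups) < 2:
        raise InsufficientDataError("one-way ANOVA needs >= 2 replicates per level")

    all_y = np.concatenate(groups)
    grand = all_y.mean()
    ss_total = float(np.sum((all_y - grand) ** 2))
    ss_treatment = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_error = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))

    # round-off guard: sums of squares at machine level relative to the
    # uncentered scale are identically zero (e.g. a constant response)
    tiny = np.finfo(float).eps ** 2 * max(1.0, float(all_y @ all_y)) * all_y.size
    ss_treatment = 0.0 if ss_treatment < tiny else ss_treatment
    ss_error = 0.0 if ss_error < tiny else ss_error
    ss_total = 0.0 if ss_total < tiny else ss_total

    df_treatment = len(groups) - 1
    df_error = all_y.size - len(groups)
    ms_treatment = ss_treatment / df_treatment
    ms_error = ss_error / df_error

    if ms_error > 0:
        f_stat = ms_treatment / ms_error
        p_value = float(stats.f.sf(f_stat, df_treatment, df_error))
    elif ms_treatment > 0:  # deterministic group differences
        f_stat, p_value = float("inf"), 0.0
    else:  # all observations identical
        f_stat, p_value = float("nan"), 1.0

    ttv_percent = 100.0 * ss_treatment / ss_total if ss_total > 0 else 0.0
    return AnovaTable(
        ss_treatment=ss_treatment, ss_error=ss_error, ss_total=ss_total,
        df_treatment=df_treatment, df_error=df_error,
        f_stat=f_stat, p_value=p_value, ttv_percent=ttv_percent,
    )


def anova_by_time(cell_samples: pd.DataFrame, response: str = "concentration_ug_per_ml") -> AnovaTable:
    """One-way ANOVA of ``response`` on time_weeks within one treatment cell."""
    groups = [
        g[response].to_numpy()
        for _, g in cell_samples.groupby("time_weeks", sort=True)
    ]
    return one_way_anova(groups)


def significance_label(p_value: float, alpha: float = 0.05) -> str:
    """"significant"/"not significant" at alpha; the boundary is inclusive."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value must be in [0, 1], got {p_value}")
    return "significant" if p_value <= alpha else "not significant"
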