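"""Arrhenius-style reaction-order fits and a conformity verdict.

Classical shelf-life practice fits concentration decay under fixed storage
conditions to integrated rate laws on the physical (real weeks) time axis:

    order 0:        C(t) = C0 - k t
    order 1:        C(t) = C0 exp(-k t)
    order 2:        1/C(t) = 1/C0 + k t
    general n != 1: C(t)^(1-n) = C0^(1-n) + (n-1) k t

with rate constants k whose temperature dependence follows Arrhenius. A
series "conforms" to that framework when its best decay fit has k > 0 and a
decent fit, and the trajectory shows no interior concentration maximum. A
rise-then-fall trajectory (interior maximum on the observed range) is the
non-conforming signature that motivates the quadratic shelf-life construction
instead.

Rate-law fits are linearised OLS on the order-appropriate transform, with
goodness-of-fit always scored on the original concentration scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError, TransformDomainError
from .fitting import fit_quadratic
from .timegrid import TransformedSeries, encode_times

R_GAS = 8.314  # J / (mol K)

DEFAULT_ORDER_GRID = tuple(np.arange(0.0, 3.01, 0.25))
_K_TOL = 1e-12


@dataclass(frozen=True)
class ReactionOrderModel:
    order_n: float
    k: float
    c0: float
    r_squared: float
    sse: float
    valid: bool


@dataclass(frozen=True)
class ConformityVerdict:
    conforms: bool
    best_order: ReactionOrderModel | None
    reason: str


def _ols_line(t: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, z, 1)
    return float(slope), float(intercept)


def _score(conc: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    resid = conc - pred
    sse = float(resid @ resid)
    sst = float(np.sum((conc - conc.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return sse, max(min(r2, 1.0), 0.0)


def fit_order(t_weeks, conc, n: float) -> ReactionOrderModel:
    """Fit the integrated rate law of order ``n`` by linearised OLS.

    Times are real weeks (rate laws live in physical time, not log3
    coordinates). Orders >= 1 require strictly positive concentrations for
    the log/power transform. R^2 is computed on the original scale.
    """
    t = np.asarray(t_weeks, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if t.size < 3:
        raise InsufficientDataError("rate-law fit needs >= 3 time points")
    if n != 0 and np.any(conc <= 0):
        raise TransformDomainError(
            f"order {n} transform undefined for non-positive concentrations"
        )

    if n == 0:
        slope, intercept = _ols_line(t, conc)
        k, c0 = -slope, intercept
        pred = c0 - k * t
    elif n == 1:
        slope, intercept = _ols_line(t, np.log(conc))
        k, c0 = -slope, math.exp(intercept)
        pred = c0 * np.exp(-k * t)
    else:
        p = 1.0 - n
        slope, intercept = _ols_line(t, conc ** p)
        k = slope / (n - 1.0)
        if intercept <= 0:
            # transformed intercept outside the physical domain; no usable C0
            return ReactionOrderModel(n, k, math.nan, 0.0, math.inf, False)
        c0 = intercept ** (1.0 / p)
        base = intercept + slope * t
        with np.errstate(invalid="ignore"):
            pred = np.where(base > 0, np.abs(base) ** (1.0 / p), 0.0 if p > 0 else np.inf)
        if not np.all(np.isfinite(pred)):
            return ReactionOrderModel(n, k, c0, 0.0, math.inf, False)

    sse, r2 = _score(conc, pred)
    valid = bool(np.isfinite(k) and k >= 0 and np.isfinite(sse))
    return ReactionOrderModel(order_n=float(n), k=float(k), c0=float(c0),
                              r_squared=r2, sse=sse, valid=valid)


def best_order(t_weeks, conc, n_grid=DEFAULT_ORDER_GRID) -> ReactionOrderModel:
    """Grid search over reaction orders, minimum SSE on the concentration scale.

    Ties break toward the smaller order. Orders whose transform is undefined
    for the data are skipped; if every order is unusable the least-bad fit is
    returned with ``valid = False``.
    """
    conc_arr = np.asarray(conc, dtype=float)
    # improvements below round-off on the data scale are ties, not wins
    tie_tol = 1e-12 * (float(conc_arr @ conc_arr) + 1.0)
    best: ReactionOrderModel | None = None
    for n in n_grid:
        try:
            m = fit_order(t_weeks, conc, n)
        except TransformDomainError:
            continue
        if best is None or m.sse < best.sse - tie_tol:
            best = m
    if best is None:
        raise TransformDomainError("no reaction order is fittable for this series")
    return best


def conformity_test(
    t_weeks,
    conc,
    r2_threshold: float = 0.8,
    n_grid=DEFAULT_ORDER_GRID,
) -> ConformityVerdict:
    """Does the series behave like Arrhenius-style monotone decay?

    Conforms iff (1) the trajectory has no interior maximum — checked by a
    quadratic fit on the log3 axis: a < 0 and b > 0 with the vertex strictly
    inside the observed range is the rise-then-fall signature; (2) the best
    rate-law fit decays (k > 0); and (3) that fit reaches ``r2_threshold``.
    The reason names the first criterion that fails.
    """
    t = np.asarray(t_weeks, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if t.size < 4:
        raise InsufficientDataError("conformity test needs >= 4 time points")

    x = encode_times(t)
    quad = fit_quadratic(TransformedSeries(x=x, y=conc, aggregation="per_time_means"))
    vertex = -quad.b / (2.0 * quad.a) if quad.a != 0 else math.nan
    # the parabola signature alone can misfire on slow monotone decay (the
    # LS fit grows a small rising limb on a geometric grid), so the observed
    # series must corroborate it: its maximum strictly interior and above
    # the initial concentration
    order = np.argsort(x)
    imax = int(np.argmax(conc[order]))
    observed_rise = 0 < imax < x.size - 1 and conc[order][imax] > conc[order][0]
    if quad.a < 0 and quad.b > 0 and x.min() < vertex < x.max() and observed_rise:
        return ConformityVerdict(
            False, None,
            f"interior concentration maximum at x = {vertex:.3f} (rise-then-fall)",
        )

    try:
        best = best_order(t, conc, n_grid=n_grid)
    except TransformDomainError as err:
        return ConformityVerdict(False, None, str(err))
    if not best.valid or best.k <= _K_TOL:
        return ConformityVerdict(False, best, "no decay signal")
    if best.r_squared < r2_threshold:
        return ConformityVerdict(
            False, best,
            f"best decay fit R^2 = {best.r_squared:.3f} < {r2_threshold}",
        )
    return ConformityVerdict(
        True, best, f"order {best.order_n:g} decay, k = {best.k:.4g} per week"
    )


def activation_energy(k1: float, T1: float, k2: float, T2: float) -> float:
    """Two-point Arrhenius activation energy in J/mol.

    Ea = R ln(k1/k2) / (1/T2 - 1/T1); symmetric under swapping the pairs and
    invariant under a common rescaling of the rate unit.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rate constants must be positive")
    if T1 <= 0 or T2 <= 0:
        raise ValueError("temperatures must be positive kelvins")
    if T1 == T2:
        raise ValueError("temperatures must differ")
    return R_GAS * math.log(k1 / k2) / (1.0 / T2 - 1.0 / T1)
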