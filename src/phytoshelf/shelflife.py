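"""Shelf-life from a positive quadratic via the parabola-symmetry construction.

For a downward-opening parabola y = a x^2 + b x + c fitted on the log3-time
axis (a < 0, b > 0, c > 0), shelf-life is defined as the storage time at which
the fitted concentration has returned to its initial post-fermentation level c
(the intercept). By parabola symmetry that happens at

    x3 = 2 * (-b / 2a) = -b/a = x_root_pos - |x_root_neg|,

twice the vertex coordinate, equivalently the positive root minus the absolute
value of the negative root (the two roots sit symmetrically about the vertex
and sum to -b/a). Real weeks follow by the base-3 antilog, 3**x3.

Monotone-decline and flat cells have no such return point: the estimate is
returned with ``predictable = False`` and a reason, never as an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import NoRealRootsError
from .fitting import POSITIVE_QUADRATIC, QuadraticModel, RelationClass
from .timegrid import decode_time

#: Agreement required between the two x3 routes (root subtraction vs -b/a).
X3_CROSSCHECK_TOL = 1e-9


@dataclass(frozen=True)
class ShelfLifeEstimate:
    predictable: bool
    reason: str
    extremum_x: float | None = None
    root_neg: float | None = None
    root_pos: float | None = None
    x3: float | None = None
    shelf_life_weeks: float | None = None
    shelf_life_weeks_rounded: int | None = None
    y_at_x3: float | None = None
    extrapolated: bool = False


def extremum(model: QuadraticModel) -> float:
    """Vertex coordinate -b/(2a); the concentration maximum when a < 0."""
    if model.a == 0:
        raise ValueError("a = 0: not a parabola")
    return -model.b / (2.0 * model.a)


def roots(model: QuadraticModel) -> tuple[float, float]:
    """Real roots of a x^2 + b x + c = 0, ascending; stable two-branch form."""
    a, b, c = model.a, model.b, model.c
    if a == 0:
        raise ValueError("a = 0: not a parabola")
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise NoRealRootsError(f"negative discriminant {disc}")
    sq = math.sqrt(disc)
    # q avoids cancellation between -b and the radical
    q = -0.5 * (b + math.copysign(sq, b)) if b != 0 else 0.5 * sq * (1 if a > 0 else -1)
    if q == 0:  # b == 0 and c == 0: double root at 0
        return (0.0, 0.0)
    r1, r2 = q / a, c / q
    return (min(r1, r2), max(r1, r2))


def shelf_life_x(model: QuadraticModel) -> float | None:
    """x3 by root subtraction, cross-checked against -b/a; None if inapplicable.

    Applicable only to the rise-then-fall pattern a < 0, b > 0, c > 0 (both
    roots real with opposite signs). The two algebraically identical routes
    are both evaluated; disagreement beyond tolerance raises, guarding
    against sign errors.
    """
    a, b, c = model.a, model.b, model.c
    if not (a < 0 and b > 0 and c > 0):
        return None
    root_neg, root_pos = roots(model)
    x3_sub = root_pos - abs(root_neg)
    x3_alg = -b / a
    if abs(x3_sub - x3_alg) > X3_CROSSCHECK_TOL * max(1.0, abs(x3_alg)):
        raise AssertionError(
            f"x3 routes disagree: {x3_sub} (root subtraction) vs {x3_alg} (-b/a)"
        )
    return x3_sub


def estimate(relation: RelationClass) -> ShelfLifeEstimate:
    """Full shelf-life estimate for a classified treatment cell.

    ``positive_quadratic`` cells get the construction plus the base-3 antilog
    to real weeks (raw and rounded to the nearest whole week) and an
    ``extrapolated`` flag when x3 lies beyond the observed design range. All
    other labels return ``predictable = False`` with a reason.
    """
    if relation.label != POSITIVE_QUADRATIC:
        reasons = {
            "negative_linear": "monotone decline; quadratic construction inapplicable",
            "flat": "no storage-time signal",
        }
        return ShelfLifeEstimate(
            predictable=False,
            reason=reasons.get(relation.label, f"relation '{relation.label}' has no shelf-life construction"),
        )
    model = relation.chosen_model
    if not (model.a < 0 and model.b > 0 and model.c > 0):
        return ShelfLifeEstimate(
            predictable=False,
            reason="fitted coefficients violate a < 0, b > 0, c > 0",
        )
    try:
        root_neg, root_pos = roots(model)
    except NoRealRootsError:
        return ShelfLifeEstimate(predictable=False, reason="parabola has no real roots")

    x3 = shelf_life_x(model)
    ext = extremum(model)
    y_at_x3 = float(model.predict(x3))
    weeks = decode_time(x3)
    return ShelfLifeEstimate(
        predictable=True,
        reason="positive quadratic; concentration returns to the intercept at x3",
        extremum_x=ext,
        root_neg=root_neg,
        root_pos=root_pos,
        x3=x3,
        shelf_life_weeks=weeks,
        shelf_life_weeks_rounded=int(round(weeks)),
        y_at_x3=y_at_x3,
        extrapolated=bool(x3 > relation.x_max > 0),
    )
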