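"""Summary statistics: chi-square activation-bias test and percentage formatting."""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .types import ValidationError


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    observed: Tuple[float, ...]
    expected: Tuple[float, ...]


def chisq_goodness_of_fit(observed: Sequence[float], expected: Sequence[float]) -> ChiSquareResult:
    """Pearson goodness-of-fit: statistic = sum (obs - exp)^2 / exp,
    df = cells - 1, upper-tail P from the chi-square distribution.

    Expected counts may be pre-rounded, so equal observed/expected totals are
    not enforced.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.size < 2 or obs.size != exp.size:
        raise ValidationError("need >= 2 cells and matching observed/expected lengths")
    if np.any(exp <= 0):
        raise ValidationError("all expected counts must be > 0")
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    p = float(sps.chi2.sf(statistic, df))
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=max(p, np.nextafter(0, 1)),
        observed=tuple(float(x) for x in obs),
        expected=tuple(float(x) for x in exp),
    )


def activation_bias_test(
    category_activated: int,
    category_total: int,
    global_activated: int,
    global_total: int,
    expected_rounding: str = "none",
) -> ChiSquareResult:
    """Test whether a category's activated fraction departs from the global rate.

    The expected activated count is category_total * global_activated /
    global_total, optionally floored or rounded to an integer (useful when
    comparing against printed integer expectations); the expected repressed
    count is category_total minus the expected activated count.
    """
    if category_total <= 0 or global_total <= 0:
        raise ValidationError("category and global totals must be positive")
    if not (0 <= category_activated <= category_total <= global_total):
        raise ValidationError("counts must satisfy 0 <= activated <= category <= global")
    exp_act = category_total * global_activated / global_total
    if expected_rounding == "floor":
        exp_act = math.floor(exp_act)
    elif expected_rounding == "nearest":
        exp_act = round(exp_act)
    elif expected_rounding != "none":
        raise ValidationError(f"unknown expected_rounding {expected_rounding!r}")
    exp_rep = category_total - exp_act
    obs = (category_activated, category_total - category_activated)
    return chisq_goodness_of_fit(obs, (exp_act, exp_rep))


def format_percentage(count: int, total: int) -> str:
    """Exact one-decimal percentage, rounded half-to-even, e.g. '11.2%'."""
    if total <= 0:
        raise ValidationError("total must be positive")
    pct = (Decimal(count) * 100 / Decimal(total)).quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN)
    return f"{pct}%"
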