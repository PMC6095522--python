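"""Coupling between two biomarkers' signed scores across a compendium.

Each bioset contributes a point (x, y) of signed scores (direction x
-log10 p) for biomarkers A and B.  Coupling is quantified by ordinary
least squares (R^2 and the overall-regression F-test on (1, n-2) df), a
3x3 quadrant table of the two call columns, and a coincidence rate: of the
biosets with a given call for A, the percentage that also carry a given
call for B (e.g. activated-A with suppressed-B).
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import f as f_dist

from .core_io import ScreenRecord

CALLS = ("activated", "no-call", "suppressed")

RegressionResult = namedtuple("RegressionResult", "r_squared f_p_value slope intercept n")
Coincidence = namedtuple("Coincidence", "n_a_with_call n_both percent")


def regress_signed_scores(
    x: Sequence[float], y: Sequence[float]
) -> RegressionResult:
    """OLS of y on x with the overall F-test.

    R^2 = 1 - SSE/SST, F = (n-2) R^2 / (1 - R^2), p = upper tail of
    F(1, n-2).  Requires n >= 3 points and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate regression: x is constant")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:  # y constant: a flat line fits exactly but explains nothing
        return RegressionResult(0.0, 1.0, float(slope), float(intercept), n)
    r2 = 1.0 - float((resid ** 2).sum()) / sst
    r2 = min(max(r2, 0.0), 1.0)
    if r2 >= 1.0:
        return RegressionResult(1.0, 0.0, float(slope), float(intercept), n)
    F = (n - 2) * r2 / (1.0 - r2)
    return RegressionResult(r2, float(f_dist.sf(F, 1, n - 2)), float(slope), float(intercept), n)


@dataclass(frozen=True)
class CouplingReport:
    n: int
    r_squared: float | None
    f_p_value: float | None
    quadrant_counts: Mapping[tuple[str, str], int]  # (call_a, call_b) -> count
    coincidence: Coincidence


def coincidence(
    records: Sequence[ScreenRecord],
    biomarker_a: str,
    biomarker_b: str,
    direction_a: str = "activated",
    direction_b: str = "suppressed",
) -> CouplingReport:
    """Quadrant and coincidence summary of two call columns, plus the signed
    score regression when it is defined (n >= 3 and varying scores);
    otherwise the regression fields are None.

    The coincidence percent is 100 * n_both / n_a_with_call, reported as
    None when no bioset carries the A call.
    """
    if not records:
        raise ValueError("no records")
    for r in records:
        if biomarker_a not in r.calls or biomarker_b not in r.calls:
            raise ValueError(
                f"record {r.bioset_id!r} lacks biomarker column "
                f"{biomarker_a!r} or {biomarker_b!r}"
            )
    quad = {(a, b): 0 for a in CALLS for b in CALLS}
    for r in records:
        quad[(r.calls[biomarker_a].call, r.calls[biomarker_b].call)] += 1

    n_a = sum(1 for r in records if r.calls[biomarker_a].call == direction_a)
    n_both = sum(
        1
        for r in records
        if r.calls[biomarker_a].call == direction_a and r.calls[biomarker_b].call == direction_b
    )
    pct = 100.0 * n_both / n_a if n_a > 0 else None

    x = [r.calls[biomarker_a].signed_score for r in records]
    y = [r.calls[biomarker_b].signed_score for r in records]
    try:
        reg = regress_signed_scores(x, y)
        r2, fp = reg.r_squared, reg.f_p_value
    except ValueError:
        r2 = fp = None

    return CouplingReport(
        n=len(records),
        r_squared=r2,
        f_p_value=fp,
        quadrant_counts=quad,
        coincidence=Coincidence(n_a, n_both, pct),
    )


def group_call_summary(
    records: Sequence[ScreenRecord],
    grouping_key: str,
    biomarker: str,
    call: str = "activated",
) -> dict[str, tuple[int, int]]:
    """Per-group (n_total, n_with_call) over an annotation field such as
    factor_type or sex."""
    out: dict[str, list[int]] = {}
    for r in records:
        try:
            group = str(getattr(r.annotation, grouping_key))
        except AttributeError:
            raise ValueError(f"unknown annotation field {grouping_key!r}") from None
        tally = out.setdefault(group, [0, 0])
        tally[0] += 1
        tally[1] += r.calls[biomarker].call == call
    return {g: (t[0], t[1]) for g, t in out.items()}
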