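"""Point estimators of discrimination ability from a 2x2 taste-test table.

For a single-sample discrimination test with a tap-water arm (size n1) and
a filtered-water arm (size n2):

* sensitivity  Se = a / n1  (probability of answering "tap" in the tap arm),
* specificity  Sp = d / n2  (probability of answering "filtered" in the
  filtered arm),
* odds ratio   OR = Se/(1-Se) * Sp/(1-Sp), algebraically the cross-product
  ratio (a*d)/(b*c),
* AUC = (Se + Sp) / 2, the area under the single-point ROC curve.

OR = 1 and AUC = 0.5 both mean the response is independent of the served
variety; OR > 1 iff AUC > 0.5.  The log-OR standard error
sqrt(1/a + 1/b + 1/c + 1/d) is the Woolf form and underpins all the Wald
inference downstream (five-region test and confidence interval, power).

A zero cell makes the log-OR infinite.  The Haldane–Anscombe correction
(add 0.5 to every cell) is applied only in that case and only when
requested, and is flagged in the result; Se and Sp are always computed on
the raw counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy import stats

from .tables_io import ContingencyTable2x2

Correction = Literal["none", "haldane"]


class ZeroCellError(ValueError):
    """A zero cell makes the odds ratio infinite or undefined without correction."""


@dataclass(frozen=True)
class DiscriminationEstimate:
    """Point estimates from one 2x2 table (full precision, never rounded)."""

    se: float
    sp: float
    odds_ratio: float
    auc: float
    log_or: float
    log_or_se: float
    correction_applied: bool


def _corrected_cells(
    t: ContingencyTable2x2, correction: Correction
) -> tuple[tuple[float, float, float, float], bool]:
    cells = t.cells()
    if min(cells) > 0:
        return tuple(float(x) for x in cells), False
    if correction == "none":
        raise ZeroCellError(
            f"table {cells} has a zero cell; the odds ratio is infinite or "
            "undefined (pass correction='haldane' to add 0.5 to every cell)"
        )
    return tuple(x + 0.5 for x in cells), True


def estimate(
    t: ContingencyTable2x2, correction: Correction = "haldane"
) -> DiscriminationEstimate:
    """Estimate Se, Sp, OR, AUC and the log-OR standard error from a table.

    ``correction="haldane"`` adds 0.5 to all four cells, but only when some
    cell is zero; tables with all-positive cells are untouched either way.
    """
    if t.n1 < 1 or t.n2 < 1:
        raise ValueError(f"both arms must be non-empty, got n1={t.n1}, n2={t.n2}")
    se = t.a / t.n1
    sp = t.d / t.n2
    (a, b, c, d), applied = _corrected_cells(t, correction)
    odds_ratio = (a * d) / (b * c)
    return DiscriminationEstimate(
        se=se,
        sp=sp,
        odds_ratio=odds_ratio,
        auc=(se + sp) / 2.0,
        log_or=math.log(odds_ratio),
        log_or_se=math.sqrt(1 / a + 1 / b + 1 / c + 1 / d),
        correction_applied=applied,
    )


def wald_ci(
    t: ContingencyTable2x2,
    level: float = 0.95,
    correction: Correction = "haldane",
) -> tuple[float, float]:
    """Wald confidence interval for the OR: exp(log_or -/+ z * SE).

    ``z`` is the standard-normal (1+level)/2 quantile, so the interval is
    symmetric about the point estimate on the log scale.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    est = estimate(t, correction=correction)
    z = stats.norm.ppf((1.0 + level) / 2.0)
    return (
        math.exp(est.log_or - z * est.log_or_se),
        math.exp(est.log_or + z * est.log_or_se),
    )
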