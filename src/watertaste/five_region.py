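"""Five-region equivalence inference on the odds ratio.

A conventional null-hypothesis test can only ever prove non-equivalence:
failing to reject OR = 1 does not show the two water varieties taste the
same.  The five-region test instead partitions the OR axis into

* OR > 2        — a recognizable ability to distinguish (lenient variant: OR > 1.5),
* 1 < OR <= 2   — a negligible ability,
* OR = 1        — no ability,
* 0.5 <= OR < 1 — a weak tendency to guess incorrectly,
* OR < 0.5      — a strong tendency to guess incorrectly,

and asks which regions the data allow us to *exclude*.  Each composite
outer region is tested one-sided at its boundary with a Wald z-statistic
on the log-OR; because the Wald statistic is monotone in the boundary, the
supremum of the p-value over the region is attained there, so the boundary
test is the region test.  Concluding OR <= 2 (the upper region rejected)
establishes "no recognizable ability"; rejecting both outer regions
establishes statistical equivalence within [0.5, 2].

The five-region confidence interval is the Wald interval truncated at any
region boundary whose outer region was rejected at the one-sided alpha.
Truncation can only shrink the interval, and guarantees the interval never
overlaps a region the tests have excluded.  Inner regions receive verdicts
by intersection with that interval, not by separate tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from scipy import stats

from .estimators import Correction, estimate, wald_ci
from .tables_io import ContingencyTable2x2

Direction = Literal["greater", "less"]
Verdict = Literal["rejected", "retained"]

#: Region keys, ordered from the largest odds ratios downward.
REGION_RECOGNIZABLE = "recognizable_ability"
REGION_RECOGNIZABLE_LENIENT = "recognizable_ability_lenient"
REGION_NEGLIGIBLE = "negligible_ability"
REGION_NO_ABILITY = "no_ability"
REGION_WEAK_INCORRECT = "weak_incorrect_tendency"
REGION_STRONG_INCORRECT = "strong_incorrect_tendency"


@dataclass(frozen=True)
class RegionPartition:
    """Boundaries of the five OR regions (defaults 0.5, 1, 2; lenient upper 1.5)."""

    lower: float = 0.5
    upper: float = 2.0
    lenient_upper: float = 1.5
    null: float = 1.0

    def __post_init__(self) -> None:
        bounds = (self.lower, self.null, self.lenient_upper, self.upper)
        if any(x <= 0 for x in bounds):
            raise ValueError(f"region boundaries must be positive, got {bounds}")
        if not (self.lower < self.null < self.lenient_upper <= self.upper):
            raise ValueError(
                "boundaries must satisfy lower < 1 < lenient_upper <= upper, "
                f"got {bounds}"
            )


DEFAULT_PARTITION = RegionPartition()


@dataclass(frozen=True)
class FiveRegionResult:
    """Boundary p-values, per-region verdicts, truncated CI and conclusion."""

    p_upper: float
    p_lower: float
    alpha: float
    region_verdicts: dict[str, Verdict]
    ci: tuple[float, float]
    conclusion: str
    p_upper_lenient: float | None = None
    partition: RegionPartition = field(default=DEFAULT_PARTITION)


def boundary_pvalue(
    t: ContingencyTable2x2,
    boundary: float,
    direction: Direction,
    correction: Correction = "haldane",
) -> float:
    """One-sided Wald p-value for the composite hypothesis at its boundary.

    ``direction="greater"`` tests H: OR >= boundary with
    p = Phi((log OR_hat - log boundary) / SE); ``direction="less"`` tests
    H: OR <= boundary with the complementary upper tail.
    """
    if boundary <= 0:
        raise ValueError(f"boundary must be positive, got {boundary}")
    est = estimate(t, correction=correction)
    z = (est.log_or - math.log(boundary)) / est.log_or_se
    if direction == "greater":
        return float(stats.norm.cdf(z))
    if direction == "less":
        return float(stats.norm.sf(z))
    raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")


def five_region_ci(
    t: ContingencyTable2x2,
    level: float = 0.95,
    alpha: float = 0.05,
    partition: RegionPartition = DEFAULT_PARTITION,
    correction: Correction = "haldane",
) -> tuple[float, float]:
    """Wald interval truncated at the boundaries of rejected outer regions."""
    lo, hi = wald_ci(t, level=level, correction=correction)
    if boundary_pvalue(t, partition.lower, "less", correction) < alpha:
        lo = max(lo, partition.lower)
    if boundary_pvalue(t, partition.upper, "greater", correction) < alpha:
        hi = min(hi, partition.upper)
    return (lo, hi)


def _closed_interval_intersects(
    ci: tuple[float, float], lo: float, hi: float, lo_open: bool, hi_open: bool
) -> bool:
    """Whether [ci] intersects the region (lo, hi) with the given openness."""
    ci_lo, ci_hi = ci
    if hi_open:
        if ci_lo >= hi:
            return False
    elif ci_lo > hi:
        return False
    if lo_open:
        if ci_hi <= lo:
            return False
    elif ci_hi < lo:
        return False
    return True


def five_region_test(
    t: ContingencyTable2x2,
    alpha: float = 0.05,
    partition: RegionPartition = DEFAULT_PARTITION,
    lenient_upper: bool = False,
    level: float = 0.95,
    correction: Correction = "haldane",
) -> FiveRegionResult:
    """Run the full five-region analysis on one table.

    Outer regions (OR > upper, OR < lower) are rejected when their boundary
    p-value falls below ``alpha``; inner regions are rejected when they do
    not intersect the five-region confidence interval.  The conclusion
    label reports "no recognizable ability" when the upper region is
    excluded, strengthening to statistical equivalence within
    [lower, upper] when both outer regions are excluded.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    p_upper = boundary_pvalue(t, partition.upper, "greater", correction)
    p_lower = boundary_pvalue(t, partition.lower, "less", correction)
    p_lenient = (
        boundary_pvalue(t, partition.lenient_upper, "greater", correction)
        if lenient_upper
        else None
    )
    ci = five_region_ci(t, level=level, alpha=alpha, partition=partition, correction=correction)

    verdicts: dict[str, Verdict] = {
        REGION_RECOGNIZABLE: "rejected" if p_upper < alpha else "retained",
        REGION_NEGLIGIBLE: (
            "retained"
            if _closed_interval_intersects(ci, partition.null, partition.upper, True, False)
            else "rejected"
        ),
        REGION_NO_ABILITY: (
            "retained" if ci[0] <= partition.null <= ci[1] else "rejected"
        ),
        REGION_WEAK_INCORRECT: (
            "retained"
            if _closed_interval_intersects(ci, partition.lower, partition.null, False, True)
            else "rejected"
        ),
        REGION_STRONG_INCORRECT: "rejected" if p_lower < alpha else "retained",
    }
    if p_lenient is not None:
        verdicts[REGION_RECOGNIZABLE_LENIENT] = (
            "rejected" if p_lenient < alpha else "retained"
        )

    upper_out = p_upper < alpha
    lower_out = p_lower < alpha
    if upper_out and lower_out:
        conclusion = (
            f"statistically equivalent within [{partition.lower:g}, {partition.upper:g}]"
        )
    elif upper_out:
        conclusion = f"no recognizable ability to distinguish (OR <= {partition.upper:g})"
    elif lower_out:
        conclusion = (
            f"no strong tendency to guess incorrectly (OR >= {partition.lower:g})"
        )
    else:
        conclusion = "inconclusive"

    return FiveRegionResult(
        p_upper=p_upper,
        p_lower=p_lower,
        alpha=alpha,
        region_verdicts=verdicts,
        ci=ci,
        conclusion=conclusion,
        p_upper_lenient=p_lenient,
        partition=partition,
    )
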