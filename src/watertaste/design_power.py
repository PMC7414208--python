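"""Power and sample size for the "no recognizable ability" conclusion.

The design question: how many participants are needed so that, when the
true odds ratio is 1 (tasters genuinely cannot tell tap from filtered
water), the one-sided boundary test of H: OR >= 2 rejects with the target
power?  Under the normal approximation the log-OR estimate is Gaussian
with variance Var(log OR) = sum of reciprocal expected cells
1/(n1 Se (1-Se)) + 1/(n2 Sp (1-Sp)), which is 16/n for Se = Sp = 1/2 and
equal arms.  The analytic power for rejecting OR >= B at one-sided alpha
when the true OR is R is

    power = Phi( (ln B - ln R) / sd - z_{1-alpha} ),

which is exactly alpha when R sits on the boundary.  Solving for n at
B = 2, R = 1, alpha = 0.05 and 80% power gives
16 (z_0.95 + z_0.80)^2 / (ln 2)^2 = 205.9, i.e. 206 participants at 1:1
allocation.  A Monte-Carlo method (simulating whole studies, including
per-participant Bernoulli(1/2) allocation if requested, and applying the
actual Wald boundary test) is provided as a check on the approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .synthetic_data import Allocation, simulate_tables

logger = logging.getLogger(__name__)

Method = Literal["analytic", "monte_carlo"]


@dataclass(frozen=True)
class PowerSpec:
    """Design assumptions for the OR-boundary power calculation."""

    true_se: float = 0.5
    true_sp: float = 0.5
    boundary: float = 2.0
    alpha: float = 0.05
    allocation: Allocation = "fixed_equal"
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError(f"target_power must be in (0, 1), got {self.target_power}")
        if self.boundary <= 0:
            raise ValueError(f"boundary must be positive, got {self.boundary}")
        for name, p in (("true_se", self.true_se), ("true_sp", self.true_sp)):
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {p}")

    @property
    def true_log_or(self) -> float:
        return math.log(
            self.true_se / (1.0 - self.true_se) * self.true_sp / (1.0 - self.true_sp)
        )


@dataclass(frozen=True)
class PowerResult:
    n_total: int
    power: float
    method: Method
    mc_reps: int | None = None
    seed: int | None = None


def _analytic_power(spec: PowerSpec, n_total: int) -> float:
    if spec.allocation == "fixed_equal":
        n1 = n_total // 2
        n2 = n_total - n1
    else:
        # Bernoulli(1/2) allocation: use the expected arm sizes.
        n1 = n2 = n_total / 2.0
    cells = (
        n1 * spec.true_se,
        n1 * (1.0 - spec.true_se),
        n2 * spec.true_sp,
        n2 * (1.0 - spec.true_sp),
    )
    if min(cells) < 1.0:
        logger.warning(
            "expected cell below 1 (min %.3f) at n_total=%d; the normal "
            "approximation may be poor",
            min(cells),
            n_total,
        )
    sd = math.sqrt(sum(1.0 / x for x in cells))
    z_crit = stats.norm.ppf(1.0 - spec.alpha)
    return float(
        stats.norm.cdf((math.log(spec.boundary) - spec.true_log_or) / sd - z_crit)
    )


def _monte_carlo_power(
    spec: PowerSpec, n_total: int, mc_reps: int, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    a, b, c, d = simulate_tables(
        n_total, spec.true_se, spec.true_sp, spec.allocation, mc_reps, rng
    )
    cells = np.stack([a, b, c, d]).astype(float)
    zero = (cells == 0).any(axis=0)
    cells[:, zero] += 0.5  # Haldane-Anscombe on zero-cell replicates
    a_, b_, c_, d_ = cells
    log_or = np.log(a_ * d_ / (b_ * c_))
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    p = stats.norm.cdf((log_or - math.log(spec.boundary)) / se)
    return float(np.mean(p < spec.alpha))


def power_at_n(
    spec: PowerSpec,
    n_total: int,
    method: Method = "analytic",
    mc_reps: int = 20_000,
    seed: int = 0,
) -> PowerResult:
    """Power of the one-sided OR-boundary test at a given total sample size."""
    if n_total < 4:
        raise ValueError(f"n_total must be at least 4, got {n_total}")
    if method == "analytic":
        return PowerResult(n_total=n_total, power=_analytic_power(spec, n_total), method=method)
    if method == "monte_carlo":
        power = _monte_carlo_power(spec, n_total, mc_reps, seed)
        return PowerResult(
            n_total=n_total, power=power, method=method, mc_reps=mc_reps, seed=seed
        )
    raise ValueError(f"unknown method {method!r}")


def min_sample_size(
    spec: PowerSpec,
    method: Method = "analytic",
    mc_reps: int = 20_000,
    seed: int = 0,
) -> PowerResult:
    """Smallest total n whose power reaches ``spec.target_power``.

    Starts at the closed-form normal-approximation solution and adjusts by
    monotone search; with 1:1 allocation n moves in steps of 2 so both
    arms stay equal.
    """
    delta = abs(math.log(spec.boundary) - spec.true_log_or)
    if delta < 1e-9:  # on (or numerically on) the boundary
        raise ValueError("true OR sits on the boundary; no finite n attains the target power")
    var_coeff = 2.0 / (spec.true_se * (1.0 - spec.true_se)) + 2.0 / (
        spec.true_sp * (1.0 - spec.true_sp)
    )
    z_a = stats.norm.ppf(1.0 - spec.alpha)
    z_p = stats.norm.ppf(spec.target_power)
    n0 = var_coeff * (z_a + z_p) ** 2 / delta**2

    step = 2 if spec.allocation == "fixed_equal" else 1
    n = max(4, math.ceil(n0))
    if step == 2 and n % 2:
        n += 1

    def _power(nn: int) -> float:
        return power_at_n(spec, nn, method=method, mc_reps=mc_reps, seed=seed).power

    while n > 4 and _power(n - step) >= spec.target_power:
        n -= step
    while _power(n) < spec.target_power:
        n += step

    result = power_at_n(spec, n, method=method, mc_reps=mc_reps, seed=seed)
    return result
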