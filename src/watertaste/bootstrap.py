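"""Percentile bootstrap confidence interval for the AUC.

Two resampling schemes are offered.  ``within_arm`` (the default) keeps
the randomized arm sizes fixed and resamples each arm's binary outcomes as
a binomial draw — it respects the two-arm design, in which arm sizes were
set by the randomization, not sampled.  ``pooled`` resamples whole
(arm, response) pairs from the n participants, letting arm sizes vary; it
is provided for sensitivity analysis.  Endpoints are plain empirical
percentiles of the replicate AUCs (no bias correction or acceleration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .tables_io import ContingencyTable2x2

logger = logging.getLogger(__name__)

Scheme = Literal["within_arm", "pooled"]


@dataclass(frozen=True)
class BootstrapResult:
    point_estimate: float
    lower: float
    upper: float
    n_boot: int
    seed: int
    scheme: Scheme
    n_redraws: int = 0


def bootstrap_auc_ci(
    t: ContingencyTable2x2,
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
    scheme: Scheme = "within_arm",
) -> BootstrapResult:
    """Percentile bootstrap interval for AUC = (Se + Sp)/2.

    Reproducible: the same table, seed, scheme and ``n_boot`` always yield
    the identical interval.  Under the pooled scheme a replicate that
    leaves an arm empty is redrawn (the count is logged and reported).
    """
    if t.n1 < 1 or t.n2 < 1:
        raise ValueError(f"both arms must be non-empty, got n1={t.n1}, n2={t.n2}")
    if n_boot < 100:
        raise ValueError(f"n_boot must be at least 100, got {n_boot}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")

    rng = np.random.default_rng(seed)
    se_hat = t.a / t.n1
    sp_hat = t.d / t.n2
    n_redraws = 0

    if scheme == "within_arm":
        se_star = rng.binomial(t.n1, se_hat, size=n_boot) / t.n1
        sp_star = rng.binomial(t.n2, sp_hat, size=n_boot) / t.n2
    elif scheme == "pooled":
        probs = np.array(t.cells(), dtype=float) / t.n
        draws = rng.multinomial(t.n, probs, size=n_boot)
        while True:
            n1_star = draws[:, 0] + draws[:, 1]
            n2_star = draws[:, 2] + draws[:, 3]
            bad = (n1_star == 0) | (n2_star == 0)
            if not bad.any():
                break
            n_redraws += int(bad.sum())
            draws[bad] = rng.multinomial(t.n, probs, size=int(bad.sum()))
        se_star = draws[:, 0] / n1_star
        sp_star = draws[:, 3] / n2_star
        if n_redraws:
            logger.debug("pooled bootstrap redrew %d degenerate replicates", n_redraws)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    auc_star = (se_star + sp_star) / 2.0
    lo, hi = np.quantile(auc_star, [(1.0 - level) / 2.0, (1.0 + level) / 2.0])
    return BootstrapResult(
        point_estimate=(se_hat + sp_hat) / 2.0,
        lower=float(lo),
        upper=float(hi),
        n_boot=n_boot,
        seed=seed,
        scheme=scheme,
        n_redraws=n_redraws,
    )
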