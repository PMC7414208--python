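"""Simulation of taste-test studies and embedded study fixtures.

The generator reproduces the structure of the real experiment: each cup is
assigned to the tap-water arm when a uniform random decimal is >= 0.5
(per-participant Bernoulli(1/2) randomization), the participant answers
"tap" with probability Se in the tap arm and 1 - Sp in the filtered arm,
and the four baseline covariates are drawn independently with the margins
observed in the study.  Defaults reflect the observed study: 278
participants, Se = 0.76, Sp = 0.21 (which already imply the observed
~78:22 marginal bias toward answering "tap" — no separate bias parameter
is needed), and covariate margins male 118/278, student 247/278,
dispenser-user 189/278, fountain-experience 26/278.

Covariates are simulated independently of the response: the study reports
no covariate-response model, so subgroup effects are represented through
the printed-fixture tables and the integer back-solver below, never
through the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Literal, Mapping

import numpy as np

from ._round import round_half_away
from .tables_io import COVARIATES, ContingencyTable2x2, ParticipantRecord, StudyDataset

Allocation = Literal["fixed_equal", "bernoulli_half"]

#: Probability of the *first* label of each covariate (study margins).
DEFAULT_COVARIATE_MARGINS: Mapping[str, float] = MappingProxyType(
    {
        "gender": 118 / 278,  # male
        "position": 247 / 278,  # student
        "dispenser_last_month": 189 / 278,  # yes
        "fountain_before": 26 / 278,  # yes
    }
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level parameters for one simulated taste test."""

    n_total: int = 278
    true_se: float = 0.76
    true_sp: float = 0.21
    allocation: Allocation = "bernoulli_half"
    covariate_margins: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_COVARIATE_MARGINS
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError(f"n_total must be at least 2, got {self.n_total}")
        for name, p in (("true_se", self.true_se), ("true_sp", self.true_sp)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.allocation not in ("fixed_equal", "bernoulli_half"):
            raise ValueError(f"unknown allocation {self.allocation!r}")
        for cov, p in self.covariate_margins.items():
            if cov not in COVARIATES:
                raise ValueError(f"unknown covariate {cov!r} in margins")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"margin for {cov!r} must be in [0, 1], got {p}")


def simulate_study(cfg: SimulationConfig) -> StudyDataset:
    """Draw one participant-level study; identical config => identical dataset."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_total

    if cfg.allocation == "bernoulli_half":
        # The study's rule: a uniform decimal >= 0.5 sends the cup to tap.
        tap = rng.random(n) >= 0.5
    else:
        tap = np.zeros(n, dtype=bool)
        tap[: n // 2] = True
        tap = tap[rng.permutation(n)]

    p_tap_reply = np.where(tap, cfg.true_se, 1.0 - cfg.true_sp)
    says_tap = rng.random(n) < p_tap_reply

    covariate_values: dict[str, np.ndarray] = {}
    for cov, labels in COVARIATES.items():
        first = rng.random(n) < cfg.covariate_margins.get(cov, 0.5)
        covariate_values[cov] = np.where(first, labels[0], labels[1])

    width = len(str(n))
    records = [
        ParticipantRecord(
            participant_id=f"P{i + 1:0{width}d}",
            gender=str(covariate_values["gender"][i]),
            position=str(covariate_values["position"][i]),
            dispenser_last_month=str(covariate_values["dispenser_last_month"][i]),
            fountain_before=str(covariate_values["fountain_before"][i]),
            arm="tap" if tap[i] else "filtered",
            response="tap" if says_tap[i] else "filtered",
        )
        for i in range(n)
    ]
    return StudyDataset(records=records, provenance=f"simulated, seed={cfg.seed}")


def simulate_tables(
    n_total: int,
    true_se: float,
    true_sp: float,
    allocation: Allocation,
    reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized arm-by-response counts for ``reps`` independent studies.

    Equivalent in distribution to aggregating :func:`simulate_study` per
    replicate, but draws the sufficient counts directly so Monte-Carlo
    power runs take milliseconds.  Returns cell arrays ``(a, b, c, d)``.
    """
    if allocation == "bernoulli_half":
        n1 = rng.binomial(n_total, 0.5, size=reps)
    else:
        n1 = np.full(reps, n_total // 2)
    n2 = n_total - n1
    a = rng.binomial(n1, true_se)
    d = rng.binomial(n2, true_sp)
    return a, n1 - a, n2 - d, d


# ---------------------------------------------------------------------------
# Embedded fixtures: the printed results of the 278-participant study.
# ---------------------------------------------------------------------------

#: (tap-arm size, filtered-arm size) per subgroup.
_ARM_SIZES = {
    "all": (139, 139),
    "gender": {"male": (52, 66), "female": (87, 73)},
    "position": {"student": (124, 123), "faculty": (15, 16)},
    "dispenser_last_month": {"yes": (93, 96), "no": (46, 43)},
    "fountain_before": {"yes": (16, 10), "no": (123, 129)},
}

#: Printed per-subgroup estimates (2 dp) and 95% intervals.
_REPORTED = {
    "all": {"or": 0.85, "or_ci": (0.5, 1.49), "auc": 0.49, "auc_ci": (0.42, 0.56)},
    "gender": {
        "male": {"or": 0.83, "or_ci": (0.45, 1.73), "auc": 0.49, "auc_ci": (0.38, 0.60)},
        "female": {"or": 0.91, "or_ci": (0.43, 2.00), "auc": 0.48, "auc_ci": (0.39, 0.57)},
    },
    "position": {
        "student": {"or": 0.74, "or_ci": (0.43, 1.40), "auc": 0.46, "auc_ci": (0.38, 0.54)},
        "faculty": {"or": 1.50, "or_ci": (0.45, 4.96), "auc": 0.55, "auc_ci": (0.37, 0.72)},
    },
    "dispenser_last_month": {
        "yes": {"or": 1.02, "or_ci": (0.52, 1.99), "auc": 0.50, "auc_ci": (0.42, 0.59)},
        "no": {"or": 0.52, "or_ci": (0.21, 1.55), "auc": 0.42, "auc_ci": (0.30, 0.55)},
    },
    "fountain_before": {
        "yes": {"or": 0.71, "or_ci": (0.17, 2.95), "auc": 0.46, "auc_ci": (0.26, 0.66)},
        "no": {"or": 0.90, "or_ci": (0.50, 1.65), "auc": 0.49, "auc_ci": (0.41, 0.56)},
    },
}

#: Printed arm-balance p-values per covariate.
_BASELINE_PVALUES = {
    "gender": 0.12,
    "position": 1.00,
    "dispenser_last_month": 0.80,
    "fountain_before": 0.34,
}


def paper_fixture() -> dict:
    """The published study's printed numbers as an in-memory fixture.

    Returns the overall arm-by-response table (a=106, b=33, c=110, d=29),
    per-subgroup arm sizes, the printed per-subgroup OR/AUC estimates and
    intervals (2 dp, as reported), and the printed baseline p-values.
    """
    return {
        "table": ContingencyTable2x2(106, 33, 110, 29),
        "arm_sizes": {
            "all": _ARM_SIZES["all"],
            **{cov: dict(_ARM_SIZES[cov]) for cov in COVARIATES},
        },
        "reported": {
            "all": dict(_REPORTED["all"]),
            **{
                cov: {label: dict(vals) for label, vals in _REPORTED[cov].items()}
                for cov in COVARIATES
            },
        },
        "baseline_pvalues": dict(_BASELINE_PVALUES),
    }


def paper_dataset() -> StudyDataset:
    """A deterministic 278-record expansion of the study fixture.

    The expansion reproduces the overall arm-by-response table and every
    covariate's per-arm margins exactly.  The joint covariate-response
    pairing within an arm is an arbitrary fixed order (the study does not
    publish it), so stratified arm-by-response tables are NOT those of the
    published subgroup analysis; use :func:`reconstruct_subgroup_table`
    for candidate subgroup tables.
    """
    fixture = paper_fixture()
    table: ContingencyTable2x2 = fixture["table"]
    arm_specs = [("tap", table.a, table.b), ("filtered", table.c, table.d)]

    records: list[ParticipantRecord] = []
    idx = 0
    for arm_i, (arm, n_tap_reply, n_filt_reply) in enumerate(arm_specs):
        n_arm = n_tap_reply + n_filt_reply
        responses = ["tap"] * n_tap_reply + ["filtered"] * n_filt_reply
        cov_columns: dict[str, list[str]] = {}
        for cov, labels in COVARIATES.items():
            k_first = fixture["arm_sizes"][cov][labels[0]][arm_i]
            cov_columns[cov] = [labels[0]] * k_first + [labels[1]] * (n_arm - k_first)
        for j in range(n_arm):
            idx += 1
            records.append(
                ParticipantRecord(
                    participant_id=f"P{idx:03d}",
                    gender=cov_columns["gender"][j],
                    position=cov_columns["position"][j],
                    dispenser_last_month=cov_columns["dispenser_last_month"][j],
                    fountain_before=cov_columns["fountain_before"][j],
                    arm=arm,
                    response=responses[j],
                )
            )
    return StudyDataset(records=records, provenance="paper fixture")


def reconstruct_subgroup_table(
    n1: int, n2: int, or_2dp: float, auc_2dp: float
) -> list[ContingencyTable2x2]:
    """All tables with the given arm sizes whose OR and AUC print as targeted.

    Exhaustively enumerates a in [0, n1] and d in [0, n2] and keeps tables
    whose cross-product OR and (Se+Sp)/2 both round (half away from zero,
    2 dp) to the targets.  Cells making the OR infinite or undefined are
    skipped.  Returns candidates with a ascending, then d; an empty list
    signals inconsistent targets.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError(f"arm sizes must be at least 1, got n1={n1}, n2={n2}")
    out: list[ContingencyTable2x2] = []
    for a in range(n1 + 1):
        b = n1 - a
        for d in range(n2 + 1):
            c = n2 - d
            if b * c == 0:
                continue
            if round_half_away((a * d) / (b * c), 2) != or_2dp:
                continue
            if round_half_away((a / n1 + d / n2) / 2.0, 2) != auc_2dp:
                continue
            out.append(ContingencyTable2x2(a, b, c, d))
    return out
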