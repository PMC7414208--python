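"""End-to-end analysis orchestration, baseline balance tests, and reports.

``run_full_analysis`` drives the whole pipeline on either participant-level
data or an aggregated table: counts and response percentages, Se/Sp/OR/AUC
estimates, the five-region test and confidence interval, the bootstrap AUC
interval, covariate stratification, and arm-balance p-values.  Every value
is serialized at full precision alongside its printed-style rounding
(half away from zero, 2 dp for estimates and 1 dp for percentages), and
the settings block records everything needed to regenerate the report
bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from ._round import round_half_away
from .bootstrap import BootstrapResult, Scheme, bootstrap_auc_ci
from .estimators import Correction, estimate, wald_ci
from .five_region import DEFAULT_PARTITION, FiveRegionResult, RegionPartition, five_region_test
from .tables_io import COVARIATES, ContingencyTable2x2, StudyDataset, aggregate

BaselineMethod = Literal["chisq_yates", "fisher"]


@dataclass(frozen=True)
class AnalysisSettings:
    """Everything needed to reproduce a report bit-identically."""

    alpha: float = 0.05
    level: float = 0.95
    n_boot: int = 10_000
    seed: int = 0
    correction: Correction = "haldane"
    scheme: Scheme = "within_arm"
    baseline_method: BaselineMethod = "chisq_yates"
    lenient_upper: bool = True

    def __post_init__(self) -> None:
        required = ("alpha", "level", "n_boot", "seed", "correction", "scheme")
        for name in required:
            if getattr(self, name) is None:
                raise ValueError(f"missing setting: {name}")


@dataclass
class AnalysisReport:
    provenance: str
    settings: AnalysisSettings
    overall: dict
    strata: dict
    baseline: dict


def covariate_balance_test(
    counts: Sequence[Sequence[int]], method: BaselineMethod = "chisq_yates"
) -> float:
    """Arm-balance p-value for a 2x2 arm-by-category count matrix.

    ``chisq_yates`` is the continuity-corrected Pearson chi-square;
    ``fisher`` the two-sided exact test (summing outcome probabilities no
    larger than the observed table's).
    """
    table = np.asarray(counts, dtype=int)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 count matrix, got shape {table.shape}")
    if method == "chisq_yates":
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("zero marginal total: expected cell is 0, use fisher")
        return float(stats.chi2_contingency(table, correction=True).pvalue)
    if method == "fisher":
        return float(stats.fisher_exact(table).pvalue)
    raise ValueError(f"unknown baseline method {method!r}")


def baseline_comparison(
    ds: StudyDataset, covariate: str, method: BaselineMethod = "chisq_yates"
) -> float:
    """Test whether a covariate is balanced between the randomized arms."""
    if covariate not in COVARIATES:
        raise ValueError(
            f"unknown covariate {covariate!r}; expected one of {sorted(COVARIATES)}"
        )
    labels = COVARIATES[covariate]
    counts = [
        [
            sum(1 for r in ds.records if r.arm == arm and getattr(r, covariate) == lab)
            for lab in labels
        ]
        for arm in ("tap", "filtered")
    ]
    return covariate_balance_test(counts, method=method)


def _rounded_pair(value: float, ndigits: int = 2) -> dict:
    return {"value": value, "rounded": round_half_away(value, ndigits)}


def _five_region_dict(res: FiveRegionResult) -> dict:
    out = {
        "p_upper": _rounded_pair(res.p_upper),
        "p_lower": _rounded_pair(res.p_lower),
        "alpha": res.alpha,
        "ci_lower": _rounded_pair(res.ci[0]),
        "ci_upper": _rounded_pair(res.ci[1]),
        "region_verdicts": dict(res.region_verdicts),
        "conclusion": res.conclusion,
    }
    if res.p_upper_lenient is not None:
        out["p_upper_lenient"] = _rounded_pair(res.p_upper_lenient)
    return out


def _bootstrap_dict(res: BootstrapResult) -> dict:
    return {
        "point_estimate": _rounded_pair(res.point_estimate),
        "lower": _rounded_pair(res.lower),
        "upper": _rounded_pair(res.upper),
        "n_boot": res.n_boot,
        "seed": res.seed,
        "scheme": res.scheme,
        "n_redraws": res.n_redraws,
    }


def _stratum_seed(base_seed: int, index: int) -> int:
    """Deterministic per-stratum bootstrap seed, kept below 2**31."""
    return int(np.random.SeedSequence(base_seed, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def _analyse_table(
    t: ContingencyTable2x2,
    settings: AnalysisSettings,
    partition: RegionPartition,
    seed: int,
) -> dict:
    est = estimate(t, correction=settings.correction)
    wald = wald_ci(t, level=settings.level, correction=settings.correction)
    fr = five_region_test(
        t,
        alpha=settings.alpha,
        partition=partition,
        lenient_upper=settings.lenient_upper,
        level=settings.level,
        correction=settings.correction,
    )
    boot = bootstrap_auc_ci(
        t,
        level=settings.level,
        n_boot=settings.n_boot,
        seed=seed,
        scheme=settings.scheme,
    )
    n_tap_replies = t.a + t.c
    return {
        "counts": {"a": t.a, "b": t.b, "c": t.c, "d": t.d, "n1": t.n1, "n2": t.n2, "n": t.n},
        "percent_replying_tap": {
            "tap_arm": _rounded_pair(100.0 * t.a / t.n1, 1),
            "filtered_arm": _rounded_pair(100.0 * t.c / t.n2, 1),
            "total": _rounded_pair(100.0 * n_tap_replies / t.n, 1),
            "total_count": n_tap_replies,
        },
        "estimate": {
            "se": _rounded_pair(est.se),
            "sp": _rounded_pair(est.sp),
            "odds_ratio": _rounded_pair(est.odds_ratio),
            "auc": _rounded_pair(est.auc),
            "log_or_se": _rounded_pair(est.log_or_se, 4),
            "correction_applied": est.correction_applied,
        },
        "wald_ci": {"lower": _rounded_pair(wald[0]), "upper": _rounded_pair(wald[1])},
        "five_region": _five_region_dict(fr),
        "bootstrap_auc": _bootstrap_dict(boot),
    }


def run_full_analysis(
    data: StudyDataset | ContingencyTable2x2,
    settings: AnalysisSettings | None = None,
    partition: RegionPartition = DEFAULT_PARTITION,
) -> AnalysisReport:
    """Run the complete pipeline and assemble an :class:`AnalysisReport`.

    Participant-level input is additionally stratified over all four
    covariates and tested for arm balance; an aggregated table yields the
    overall analysis only.
    """
    settings = settings if settings is not None else AnalysisSettings()

    if isinstance(data, ContingencyTable2x2):
        overall_table = data
        provenance = "aggregated table"
        strata_tables: dict[str, dict[str, ContingencyTable2x2]] = {}
        baseline: dict[str, float] = {}
    elif isinstance(data, StudyDataset):
        overall_table = aggregate(data)["all"]
        provenance = data.provenance or "participant records"
        strata_tables = {cov: aggregate(data, stratify_by=cov) for cov in COVARIATES}
        baseline = {
            cov: baseline_comparison(data, cov, method=settings.baseline_method)
            for cov in COVARIATES
        }
    else:
        raise TypeError(f"expected StudyDataset or ContingencyTable2x2, got {type(data)!r}")

    overall = _analyse_table(
        overall_table, settings, partition, _stratum_seed(settings.seed, 0)
    )
    strata: dict[str, dict] = {}
    idx = 1
    for cov, tables in strata_tables.items():
        strata[cov] = {}
        for label, t in tables.items():
            strata[cov][label] = _analyse_table(
                t, settings, partition, _stratum_seed(settings.seed, idx)
            )
            idx += 1

    return AnalysisReport(
        provenance=provenance,
        settings=settings,
        overall=overall,
        strata=strata,
        baseline={cov: _rounded_pair(p) for cov, p in baseline.items()},
    )


def report_to_json(report: AnalysisReport) -> str:
    payload = {
        "provenance": report.provenance,
        "settings": asdict(report.settings),
        "overall": report.overall,
        "strata": report.strata,
        "baseline": report.baseline,
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def report_to_tsv(report: AnalysisReport) -> str:
    """Human-readable tab-separated summary mirroring the study's tables."""
    lines = [
        "stratum\tlabel\tn\tOR\tfive-region CI\tAUC\tbootstrap CI\tconclusion"
    ]

    def _row(stratum: str, label: str, block: dict) -> str:
        fr = block["five_region"]
        bt = block["bootstrap_auc"]
        return (
            f"{stratum}\t{label}\t{block['counts']['n']}\t"
            f"{block['estimate']['odds_ratio']['rounded']:.2f}\t"
            f"[{fr['ci_lower']['rounded']:.2f}, {fr['ci_upper']['rounded']:.2f}]\t"
            f"{block['estimate']['auc']['rounded']:.2f}\t"
            f"[{bt['lower']['rounded']:.2f}, {bt['upper']['rounded']:.2f}]\t"
            f"{fr['conclusion']}"
        )

    lines.append(_row("all", "all", report.overall))
    for cov, labels in report.strata.items():
        for label, block in labels.items():
            lines.append(_row(cov, label, block))
    if report.baseline:
        lines.append("")
        lines.append("covariate\tbaseline p-value")
        for cov, p in report.baseline.items():
            lines.append(f"{cov}\t{p['rounded']:.2f}")
    return "\n".join(lines) + "\n"
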