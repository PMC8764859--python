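"""Cohort-level contingency statistics and summary tables.

Group comparisons use Pearson's chi-square test without continuity
correction; when any expected cell count falls below 5 the comparison falls
back to Fisher's exact test (two-sided).  Rates are reported as percentages
to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .concordance import CATEGORIES, ConcordanceResult, is_transferable
from .karyotype import PlatformDiagnosis

__all__ = ["ContingencyTable2x2", "CohortRecord", "TestResult",
           "pearson_chi2", "fisher_exact", "compare_groups", "cohort_summary"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("yes", "no")

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def expected(self) -> np.ndarray:
        t = self.counts
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


@dataclass(frozen=True)
class TestResult:
    method: str  # "chi2" | "fisher"
    p_value: float
    statistic: Optional[float] = None


def pearson_chi2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Classical Pearson chi-square (1 df, no continuity correction)."""
    if (table.expected == 0).any():
        raise ValueError("zero marginal total; chi-square undefined")
    stat, p, _, _ = sps.chi2_contingency(table.counts, correction=False)
    return float(stat), float(p)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (hypergeometric, fixed marginals)."""
    _, p = sps.fisher_exact(table.counts, alternative="two-sided")
    return float(p)


def compare_groups(table: ContingencyTable2x2) -> TestResult:
    """Chi-square with Fisher fallback when any expected count is below 5."""
    if (table.expected < 5).any():
        return TestResult(method="fisher", p_value=fisher_exact(table))
    stat, p = pearson_chi2(table)
    return TestResult(method="chi2", p_value=p, statistic=stat)


@dataclass
class CohortRecord:
    """One enrolled embryo: both diagnoses, covariates, concordance call."""

    embryo_id: str
    snp: PlatformDiagnosis
    ngs: PlatformDiagnosis
    maternal_age: Optional[float] = None
    good_quality: Optional[bool] = None
    concordance: Optional[ConcordanceResult] = None

    @property
    def mosaic_type_snp(self) -> str:
        """Whole-chromosome vs segmental (arm or sub-arm) mosaicism on SNP."""
        scopes = {"whole" if e.scope == "whole" else "segmental"
                  for e in self.snp.mosaic_events}
        if scopes == {"whole"}:
            return "whole"
        if scopes == {"segmental"}:
            return "segmental"
        return "both"

    @property
    def ngs_mosaic_level(self) -> Optional[int]:
        """Highest mosaic level among NGS mosaic events, if any."""
        levels = [e.level_percent for e in self.ngs.mosaic_events
                  if e.level_percent is not None]
        return max(levels) if levels else None


def _rate(k: int, n: int) -> float:
    return round(100.0 * k / n, 2)


def _stratum_table(records, key, label1, label2, group_fn) -> dict:
    """Complete-vs-not 2x2 for a two-group stratification + test."""
    g1 = [r for r in records if group_fn(r) is True]
    g2 = [r for r in records if group_fn(r) is False]
    c1 = sum(r.concordance.category == "complete" for r in g1)
    c2 = sum(r.concordance.category == "complete" for r in g2)
    t = ContingencyTable2x2(c1, len(g1) - c1, c2, len(g2) - c2,
                            row_labels=(label1, label2),
                            col_labels=("complete", "not_complete"))
    res = compare_groups(t)
    return {
        "stratum": key,
        "groups": {
            label1: {"complete": c1, "n": len(g1),
                     "rate": _rate(c1, len(g1)) if g1 else None},
            label2: {"complete": c2, "n": len(g2),
                     "rate": _rate(c2, len(g2)) if g2 else None},
        },
        "method": res.method,
        "p_value": round(res.p_value, 3),
        "excluded": len(records) - len(g1) - len(g2),
    }


def cohort_summary(records: Sequence[CohortRecord]) -> dict:
    """Aggregate a classified cohort into concordance / outcome / strata tables.

    Requires every record to carry a concordance result.  Returns a
    JSON-serializable dict with (i) five-way concordance counts and rates,
    (ii) NGS outcome counts with the 50%-level split, (iii) transferability,
    and (iv) stratified complete-concordance comparisons (maternal age at 35,
    whole vs segmental SNP mosaicism excluding mixed, embryo quality).
    """
    if not records:
        raise ValueError("empty cohort")
    missing = [r.embryo_id for r in records if r.concordance is None]
    if missing:
        raise ValueError(f"unclassified records: {missing}")
    n = len(records)
    counts = {cat: sum(r.concordance.category == cat for r in records)
              for cat in CATEGORIES}
    rates = {cat: _rate(k, n) for cat, k in counts.items()}

    ngs_mosaic = [r for r in records if r.ngs.mosaic_events]
    low = sum(r.ngs_mosaic_level <= 50 for r in ngs_mosaic)
    high = len(ngs_mosaic) - low
    ngs_outcomes = {
        "euploid": sum(r.ngs.overall_class == "euploid" for r in records),
        "aneuploid": sum(r.ngs.overall_class == "aneuploid" for r in records),
        "mosaic": len(ngs_mosaic),
        "mosaic_low_level": low,    # <= 50%
        "mosaic_high_level": high,  # > 50%
        "mosaic_low_rate_of_mosaic": _rate(low, len(ngs_mosaic)) if ngs_mosaic else None,
        "mosaic_high_rate_of_mosaic": _rate(high, len(ngs_mosaic)) if ngs_mosaic else None,
    }
    transferable = sum(is_transferable(r.ngs) for r in records)
    strata = [
        _stratum_table(
            records, "maternal_age", "under_35", "35_and_over",
            lambda r: None if r.maternal_age is None else r.maternal_age < 35),
        _stratum_table(
            records, "mosaic_type", "whole_chromosome", "segmental",
            lambda r: {"whole": True, "segmental": False}.get(r.mosaic_type_snp)),
        _stratum_table(
            records, "embryo_quality", "good", "low",
            lambda r: r.good_quality),
    ]
    return {
        "n": n,
        "concordance_counts": counts,
        "concordance_rates": rates,
        "mosaic_by_ngs": {"count": len(ngs_mosaic), "rate": _rate(len(ngs_mosaic), n)},
        "ngs_outcomes": ngs_outcomes,
        "transferable": {"count": transferable, "rate": _rate(transferable, n)},
        "untransferable": {"count": n - transferable, "rate": _rate(n - transferable, n)},
        "strata": strata,
    }
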