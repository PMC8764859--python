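"""Synthetic reference cohort of dual-platform embryo diagnoses.

No public per-embryo dataset exists for the dual-platform design this
package implements, so this module builds one synthetically: a per-embryo
diagnosis table (supplementary-table dialect) whose *aggregate* composition
is specified up front — the five-way concordance counts, the low/high
mosaic-level split, and the margins of the three stratified comparisons
(maternal age, whole-vs-segmental SNP mosaicism, embryo quality).  The
default composition is the package's 105-embryo reference cohort used in the
worked example.

Each row carries SNP and NGS notations that, when parsed and classified by
:func:`pgtmosaic.concordance.classify_concordance`, reproduce the requested
category by construction — so the cohort summary recomputes every rate and
p-value from the per-embryo rows rather than copying the specified totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["CohortComposition", "synthetic_cohort_table"]


@dataclass(frozen=True)
class CohortComposition:
    """Aggregate targets for the synthetic cohort (defaults: 105 embryos)."""

    # five-way concordance counts
    complete: int = 50
    partial: int = 19
    discordant_mosaic: int = 11
    aneuploid_by_ngs: int = 14
    euploid_by_ngs: int = 11
    # SNP mosaic type margins: complete vs rest (the single whole+segmental
    # embryo sits in the partial category and is excluded from the stratum)
    whole_complete: int = 21
    seg_complete: int = 29
    whole_total: int = 49
    seg_total: int = 55
    n_both: int = 1
    # age margin: embryos under 35 years, among complete / overall
    under35_complete: int = 37
    under35_total: int = 82
    # quality margin: good-quality embryos, among complete / overall
    good_complete: int = 38
    good_total: int = 80
    # NGS mosaic level split (low = level <= 50%)
    low_level: int = 57

    @property
    def n(self) -> int:
        return (self.complete + self.partial + self.discordant_mosaic
                + self.aneuploid_by_ngs + self.euploid_by_ngs)

    @property
    def n_mosaic_ngs(self) -> int:
        return self.complete + self.partial + self.discordant_mosaic


def _split(total: int, k: int, weights: list[int]) -> list[int]:
    """Deterministically apportion ``k`` items over groups of size weights."""
    out, acc, given = [], 0.0, 0
    for w in weights[:-1]:
        acc += k * w / total
        take = int(round(acc)) - given
        out.append(take)
        given += take
    out.append(k - given)
    return out


def synthetic_cohort_table(composition: CohortComposition = CohortComposition()
                           ) -> pd.DataFrame:
    """Build the per-embryo table (columns: embryo_id, snp_result, ngs_result,
    ngs_level, maternal_age, good_quality).

    Deterministic: the same composition always yields the same table.
    """
    comp = composition
    cats = (["complete"] * comp.complete + ["partial"] * comp.partial
            + ["discordant_mosaic"] * comp.discordant_mosaic
            + ["aneuploid_by_ngs"] * comp.aneuploid_by_ngs
            + ["euploid_by_ngs"] * comp.euploid_by_ngs)
    sizes = [comp.complete, comp.partial, comp.discordant_mosaic,
             comp.aneuploid_by_ngs, comp.euploid_by_ngs]
    noncomp_sizes = sizes[1:]

    # mosaic type per embryo: category-wise counts of whole-chromosome rows
    whole_rest = comp.whole_total - comp.whole_complete
    whole_by_cat = [comp.whole_complete] + _split(
        comp.n - comp.complete - comp.n_both, whole_rest,
        [comp.partial - comp.n_both] + noncomp_sizes[1:])
    # the mixed (whole+segmental) embryos lead the partial category
    under35_by_cat = [comp.under35_complete] + _split(
        comp.n - comp.complete, comp.under35_total - comp.under35_complete,
        noncomp_sizes)
    good_by_cat = [comp.good_complete] + _split(
        comp.n - comp.complete, comp.good_total - comp.good_complete,
        noncomp_sizes)
    low_by_cat = _split(comp.n_mosaic_ngs, comp.low_level, sizes[:3])

    rows = []
    cat_index = {c: 0 for c in set(cats)}
    cat_order = ["complete", "partial", "discordant_mosaic",
                 "aneuploid_by_ngs", "euploid_by_ngs"]
    autosomes = [str(i) for i in range(1, 23)]
    for i, cat in enumerate(cats):
        ci = cat_order.index(cat)
        j = cat_index[cat]  # index within category
        cat_index[cat] += 1
        sign = "+" if (i % 2 == 0) else "-"
        chrom = autosomes[i % 22]
        other = autosomes[(i + 7) % 22]
        n_both_cat = comp.n_both if cat == "partial" else 0
        if j < n_both_cat:
            snp = f"{sign}mos({chrom}),{sign}mos({other}q)"
        elif j < n_both_cat + whole_by_cat[ci]:
            snp = f"{sign}mos({chrom})"
        else:
            snp = f"{sign}mos({chrom}{'p' if i % 4 < 2 else 'q'})"
        if cat == "complete":
            ngs = snp
        elif cat == "partial":
            extra = autosomes[(i + 11) % 22]
            ngs = f"{snp},{'-' if sign == '+' else '+'}mos({extra}p)"
        elif cat == "discordant_mosaic":
            ngs = f"{'-' if sign == '+' else '+'}mos({other})"
        elif cat == "aneuploid_by_ngs":
            ngs = f"{sign}{chrom}"
        else:
            ngs = "euploid"
        if cat in ("complete", "partial", "discordant_mosaic"):
            if j < low_by_cat[ci]:
                level = 20 + (j * 5) % 35   # 20..50: low-level mosaic
            else:
                level = 55 + (j * 5) % 30   # 55..80: high-level mosaic
        else:
            level = ""
        under35 = j < under35_by_cat[ci]
        age = (26 + (i * 3) % 9) if under35 else (35 + (i * 3) % 8)
        good = j < good_by_cat[ci]
        rows.append({
            "embryo_id": f"E{i + 1:03d}",
            "snp_result": snp,
            "ngs_result": ngs,
            "ngs_level": level,
            "maternal_age": age,
            "good_quality": "yes" if good else "no",
        })
    return pd.DataFrame(rows)
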