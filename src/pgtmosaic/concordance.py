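"""Between-platform concordance classification at chromosome-arm resolution.

Two diagnoses of the same embryo — one SNP-array, one NGS — are compared on
the *types* of mosaicism they report: the key of a mosaic event is
(chromosome, whole|p|q, gain|loss).  Deletion vs duplication on the same arm,
and whole-chromosome vs single-arm mosaicism of the same chromosome, are
different types and never match; segmental coordinate differences within the
same arm are ignored.

Categories (mutually exclusive and exhaustive for an SNP-mosaic embryo):

* ``complete`` — identical key sets;
* ``partial`` — overlapping but not identical key sets (including the case
  where NGS reports a strict superset of the SNP arms);
* ``discordant_mosaic`` — both platforms report mosaicism but of completely
  different types;
* ``aneuploid_by_ngs`` / ``euploid_by_ngs`` — NGS reports no mosaicism at
  all, only pure aneuploidy / nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .karyotype import GenomeModel, PlatformDiagnosis, event_keys

__all__ = ["ConcordanceResult", "classify_concordance", "is_transferable",
           "CATEGORIES"]

CATEGORIES = ("complete", "partial", "discordant_mosaic",
              "aneuploid_by_ngs", "euploid_by_ngs")


@dataclass(frozen=True)
class ConcordanceResult:
    category: str
    snp_keys: frozenset
    ngs_keys: frozenset
    shared: frozenset
    snp_only: frozenset
    ngs_only: frozenset
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _mosaic_keys(d: PlatformDiagnosis, genome: GenomeModel) -> frozenset:
    keys: set = set()
    for e in d.mosaic_events:
        keys |= event_keys(e, genome)
    return frozenset(keys)


def classify_concordance(snp: PlatformDiagnosis, ngs: PlatformDiagnosis,
                         genome: GenomeModel) -> ConcordanceResult:
    """Classify one embryo's pair of diagnoses.

    The SNP diagnosis must contain at least one mosaic event (only embryos
    judged mosaic by the array are re-tested).  When NGS reports both mosaic
    and pure-aneuploid events, the mosaic keys drive the category; the
    aneuploid/euploid-by-NGS branches require NGS to report *no* mosaicism.
    """
    s = _mosaic_keys(snp, genome)
    if not s:
        raise ValueError("SNP diagnosis carries no mosaic event; "
                         "concordance is defined for SNP-mosaic embryos only")
    n = _mosaic_keys(ngs, genome)
    shared = s & n
    flags = []
    # audit flag: whole-chromosome vs arm mosaicism of the same chromosome
    # and direction physically overlaps but counts as a different type
    for chrom, scope, direction in s:
        probe = {("whole", "p"), ("whole", "q"), ("p", "whole"), ("q", "whole")}
        for s2, n2 in probe:
            if scope == s2 and (chrom, n2, direction) in n:
                flags.append(f"whole_vs_arm:{chrom}:{direction}")
                break
    if not n:
        if ngs.aneuploid_events:
            category = "aneuploid_by_ngs"
        elif not ngs.events:
            category = "euploid_by_ngs"
        else:  # unreachable: events are mosaic or not
            category = "euploid_by_ngs"
    elif s == n:
        category = "complete"
    elif shared:
        category = "partial"
    else:
        category = "discordant_mosaic"
    return ConcordanceResult(
        category=category, snp_keys=s, ngs_keys=n, shared=frozenset(shared),
        snp_only=frozenset(s - n), ngs_only=frozenset(n - s),
        flags=tuple(sorted(set(flags))))


def is_transferable(ngs: PlatformDiagnosis) -> bool:
    """Transfer eligibility from the NGS diagnosis.

    Transferable embryos are euploid or carry only mosaic events, each with a
    level of at most 50%; any pure aneuploidy, or any mosaic level above 50%,
    makes the embryo untransferable.
    """
    if ngs.aneuploid_events:
        return False
    for e in ngs.mosaic_events:
        if e.level_percent is None:
            raise ValueError("mosaic event without a level; transferability "
                             "requires quantified mosaicism")
        if e.level_percent > 50:
            return False
    return True
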