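"""Low-pass NGS QC, GC normalization, CNV-value estimation and classification.

The caller estimates a CNV value on the scale where disomy = 2 from
GC-normalized bin counts, and classifies it by fixed intervals:

* < 1.20 or > 2.80 — pure aneuploidy (loss / gain);
* [1.20, 1.80] or [2.20, 2.80] — mosaic, with level |CNV - 2| x 100 %;
* (1.80, 2.20) — euploid.

The 1.80/2.20 endpoints belong to the mosaic class: a mean copy number of
exactly 2.2 is a 20% mosaic, not euploid.  Sub-arm segments are reported only
at >= 4 Mb, the platform's segmental resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._segmentation import binary_segmentation, robust_sigma
from .karyotype import CnEvent, GenomeModel, PlatformDiagnosis
from .simulate import NgsSignal

__all__ = ["NgsQcReport", "CnvSegment", "PloidyClass", "NgsCallerParams",
           "ngs_qc", "gc_normalize", "segment_cnv", "classify_cnv", "call_ngs"]


@dataclass(frozen=True)
class NgsQcReport:
    total_reads: int
    map_ratio: float       # %
    duplicate_rate: float  # % (recorded; no published gate)
    gc_content: float      # %
    sd: float              # stdev of per-bin CNV estimates (2 x normalized ratio)
    passed: bool
    failures: tuple[str, ...] = ()


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start_bp: int
    end_bp: int
    scope: str  # "whole" | "p" | "q" | "segment"
    cnv_value: float
    n_bins: int
    se: float = 0.0  # standard error of cnv_value (median over bins)

    def __post_init__(self):
        if self.cnv_value < 0:
            raise ValueError("cnv_value must be >= 0")


@dataclass(frozen=True)
class PloidyClass:
    kind: str  # "euploid" | "mosaic" | "aneuploid"
    direction: Optional[str] = None       # "gain" | "loss" for non-euploid
    level_percent: Optional[int] = None   # mosaic only


@dataclass(frozen=True)
class NgsCallerParams:
    """Published QC gates and classification intervals, plus algorithm knobs."""

    qc_min_reads: int = 700_000
    qc_min_map_ratio: float = 80.0
    qc_gc_range: tuple[float, float] = (39.0, 45.0)
    qc_max_sd: float = 3.5  # gate on the package's operational sd statistic
    mosaic_low: float = 1.20
    mosaic_high: float = 2.80
    euploid_low: float = 1.80
    euploid_high: float = 2.20
    min_segment_bp: int = 4_000_000  # segmental resolution floor
    min_seg_bins: int = 4
    arm_cover_frac: float = 0.9
    whole_merge_tol: float = 0.4   # max CNV gap when merging both arms to whole
    penalty_factor: float = 5.0
    call_z_min: float = 3.5  # min |CNV - 2| / se to call a segment aberrant
    min_autosomal_bins: int = 20


def gc_normalize(signal: NgsSignal,
                 params: NgsCallerParams = NgsCallerParams()) -> pd.DataFrame:
    """Per-bin copy ratio after GC-decile median normalization.

    Bin count densities are divided by the median density of their GC decile
    (deciles defined on autosomal bins; a decile with no bins falls back to
    the global median), then rescaled so the autosomal median ratio is 1.
    Deterministic.  Returns the bin table with a ``ratio`` column.
    """
    df = signal.df.copy()
    auto = ~df["chrom"].isin(["X", "Y"])
    if int(auto.sum()) < params.min_autosomal_bins:
        raise ValueError("too few autosomal bins for GC normalization")
    density = df["read_count"] / (df["end"] - df["start"] + 1)
    edges = np.unique(np.quantile(df.loc[auto, "gc_fraction"], np.linspace(0, 1, 11)))
    decile = np.clip(np.searchsorted(edges, df["gc_fraction"], side="right") - 1,
                     0, len(edges) - 2)
    global_median = float(density[auto].median())
    ratio = np.empty(len(df))
    for d in range(len(edges) - 1):
        in_d = decile == d
        ref = density[in_d & auto]
        med = float(ref.median()) if len(ref) else global_median
        ratio[in_d] = density[in_d] / (med if med > 0 else global_median)
    ratio = ratio / float(np.median(ratio[auto]))
    return df.assign(ratio=ratio)


def ngs_qc(signal: NgsSignal,
           params: NgsCallerParams = NgsCallerParams()) -> NgsQcReport:
    """Sequencing-run quality control.

    Read-count noise (``sd``) is the standard deviation of per-bin CNV
    estimates (2 x GC-normalized ratio) over autosomal bins — an operational
    definition of the vendor's opaque SD statistic; its 3.5 gate is
    configurable.
    """
    if signal.df.empty:
        raise ValueError("empty NGS signal")
    norm = gc_normalize(signal, params)
    auto = ~norm["chrom"].isin(["X", "Y"])
    sd = float((2.0 * norm.loc[auto, "ratio"]).std())
    meta = signal.meta
    total_reads = int(meta.get("total_reads", 0))
    map_ratio = float(meta.get("map_ratio", 100.0))
    duplicate = float(meta.get("duplicate_rate", 0.0))
    gc_content = float(meta.get("gc_content", 100.0 * signal.df["gc_fraction"].mean()))
    failures = []
    if total_reads < params.qc_min_reads:
        failures.append("total_reads")
    if map_ratio < params.qc_min_map_ratio:
        failures.append("map_ratio")
    lo, hi = params.qc_gc_range
    if not lo <= gc_content <= hi:
        failures.append("gc_content")
    if sd >= params.qc_max_sd:
        failures.append("sd")
    return NgsQcReport(total_reads, map_ratio, duplicate, gc_content, sd,
                       passed=not failures, failures=tuple(failures))


def classify_cnv(cnv_value: float,
                 params: NgsCallerParams = NgsCallerParams()) -> PloidyClass:
    """Map a CNV value (disomy = 2) to its ploidy class.

    The classification partitions [0, inf) monotonically:
    aneuploid-loss < mosaic-loss < euploid < mosaic-gain < aneuploid-gain.
    For mosaic calls the level is |CNV - 2| x 100, rounded to the nearest
    integer percent.
    """
    if cnv_value < 0:
        raise ValueError("cnv_value must be >= 0")
    eps = 1e-9  # interval endpoints belong to the mosaic class
    if cnv_value < params.mosaic_low - eps:
        return PloidyClass("aneuploid", "loss")
    if cnv_value <= params.euploid_low + eps:
        return PloidyClass("mosaic", "loss",
                           int(round(abs(cnv_value - 2.0) * 100)))
    if cnv_value < params.euploid_high - eps:
        return PloidyClass("euploid")
    if cnv_value <= params.mosaic_high + eps:
        return PloidyClass("mosaic", "gain",
                           int(round(abs(cnv_value - 2.0) * 100)))
    return PloidyClass("aneuploid", "gain")


def segment_cnv(normalized: pd.DataFrame, genome: GenomeModel,
                params: NgsCallerParams = NgsCallerParams()) -> list[CnvSegment]:
    """Per-arm binary segmentation of the CNV profile (2 x normalized ratio).

    Segments shorter than the 4 Mb floor are merged into their longer
    neighbor; a segment covering essentially the whole arm is promoted to arm
    scope.  CNV value is 2 x the median ratio of the segment's bins.
    """
    out = []
    for chrom in genome.chromosomes:
        sub = normalized[normalized["chrom"] == chrom]
        for arm in ("p", "q"):
            lo, hi = genome.arm_bounds(chrom, arm)
            mid = (sub["start"] + sub["end"]) // 2
            m = sub[(mid >= lo) & (mid <= hi)]
            if m.empty:
                continue
            cnv = 2.0 * m["ratio"].to_numpy()
            starts = m["start"].to_numpy()
            ends = m["end"].to_numpy()
            segs = binary_segmentation(cnv, min_size=params.min_seg_bins,
                                       penalty_factor=params.penalty_factor)
            # absorb sub-floor segments into their longer neighbor
            segs = list(segs)
            changed = True
            while changed and len(segs) > 1:
                changed = False
                for idx, (i, j) in enumerate(segs):
                    span = ends[j - 1] - starts[i] + 1
                    if span <= params.min_segment_bp:
                        if idx == 0:
                            segs[1] = (i, segs[1][1])
                        elif idx == len(segs) - 1:
                            segs[idx - 1] = (segs[idx - 1][0], j)
                        else:
                            left = segs[idx - 1][1] - segs[idx - 1][0]
                            right = segs[idx + 1][1] - segs[idx + 1][0]
                            if left >= right:
                                segs[idx - 1] = (segs[idx - 1][0], j)
                            else:
                                segs[idx + 1] = (i, segs[idx + 1][1])
                        del segs[idx]
                        changed = True
                        break
            sigma_bin = robust_sigma(cnv)
            for i, j in segs:
                scope = arm if (j - i) >= params.arm_cover_frac * len(m) else "segment"
                out.append(CnvSegment(
                    chrom=chrom, start_bp=int(starts[i]), end_bp=int(ends[j - 1]),
                    scope=scope, cnv_value=float(np.median(cnv[i:j])),
                    n_bins=j - i,
                    se=float(1.2533 * sigma_bin / np.sqrt(j - i))))
    return out


def call_ngs(signal: NgsSignal, genome: GenomeModel,
             params: NgsCallerParams = NgsCallerParams()) -> PlatformDiagnosis:
    """Full NGS diagnosis: QC, GC normalization, segmentation, classification.

    Non-euploid segments become events; mosaic events carry the CNV value and
    the implied level percentage.  Both arms consistent (same class and
    direction, similar CNV) merge into one whole-chromosome event.  QC
    failure flags the diagnosis unreliable but calling still proceeds.
    """
    qc = ngs_qc(signal, params)
    norm = gc_normalize(signal, params)
    segments = segment_cnv(norm, genome, params)
    events: list[CnEvent] = []
    by_chrom: dict[str, list[CnvSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    def significant(s: CnvSegment) -> bool:
        # evidence gate: the deviation from disomy must clear the noise floor
        return abs(s.cnv_value - 2.0) >= params.call_z_min * s.se

    for chrom, segs in by_chrom.items():
        arm_scope = {s.scope: s for s in segs if s.scope in ("p", "q")}
        merged_whole = False
        if len(arm_scope) == 2:
            p, q = arm_scope["p"], arm_scope["q"]
            cp, cq = classify_cnv(p.cnv_value, params), classify_cnv(q.cnv_value, params)
            # direction agreement suffices: the mosaic/aneuploid kind is
            # re-decided on the pooled dosage, else arms of a full aneuploidy
            # can straddle the 2.80/1.20 boundary and fail to merge
            if (cp.kind != "euploid" and cq.kind != "euploid"
                    and cp.direction == cq.direction
                    and significant(p) and significant(q)
                    and abs(p.cnv_value - q.cnv_value) <= params.whole_merge_tol):
                cnv = (p.cnv_value * p.n_bins + q.cnv_value * q.n_bins) \
                    / (p.n_bins + q.n_bins)
                cls = classify_cnv(cnv, params)
                events.append(CnEvent(
                    chrom=chrom, scope="whole", direction=cls.direction,
                    mosaic=cls.kind == "mosaic",
                    level_percent=cls.level_percent, cnv_value=round(cnv, 2)))
                merged_whole = True
        whole_direction = events[-1].direction if merged_whole else None
        for s in segs:
            if merged_whole and s.scope in ("p", "q"):
                continue
            cls = classify_cnv(s.cnv_value, params)
            if cls.kind == "euploid" or not significant(s):
                continue
            # a residual same-direction piece of a merged whole-chromosome
            # aberration is part of that event, not a second one
            if merged_whole and cls.direction == whole_direction:
                continue
            if s.scope == "segment" and s.end_bp - s.start_bp + 1 <= params.min_segment_bp:
                continue
            events.append(CnEvent(
                chrom=chrom, scope=s.scope, direction=cls.direction,
                mosaic=cls.kind == "mosaic",
                start_bp=s.start_bp if s.scope == "segment" else None,
                end_bp=s.end_bp if s.scope == "segment" else None,
                level_percent=cls.level_percent, cnv_value=round(s.cnv_value, 2)))
    return PlatformDiagnosis("NGS", events=events, qc=qc, unreliable=not qc.passed)
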