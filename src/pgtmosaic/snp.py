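"""SNP-array QC and per-arm ploidy calling from LogR/BAF signal.

Data quality follows the chip criteria: median LogR deviation < 0.2 and
median call rate > 0.98.  Mosaicism on an arm is called when the BAF scatter
of heterozygous-pattern loci is not concentrated at 0.5 *and* the arm's
median LogR exceeds +/-0.2; dosage beyond the full-aneuploidy thresholds is
called as pure (non-mosaic) aneuploidy.  The SNP platform cannot quantify the
mosaic level, so its events never carry ``level_percent``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._segmentation import binary_segmentation
from .karyotype import CnEvent, GenomeModel, PlatformDiagnosis
from .simulate import SnpSignal

__all__ = ["SnpQcReport", "ArmSummary", "SnpCallerParams",
           "snp_qc", "summarize_arms", "call_snp"]


@dataclass(frozen=True)
class SnpQcReport:
    median_logr_deviation: float
    median_call_rate: float
    passed: bool


@dataclass(frozen=True)
class ArmSummary:
    chrom: str
    arm: str
    median_logr: float
    baf_scatter: float
    n_markers: int


@dataclass(frozen=True)
class SnpCallerParams:
    """Thresholds of the SNP-array calling rules.

    ``logr_mosaic`` (0.2) is the published mosaicism dosage threshold; the
    full-aneuploidy boundaries place dosage within 10% of copy number 1 or 3.
    ``tau_baf``/``theta_scatter`` operationalize "BAF scatter not concentrated
    at 0.5".  ``min_seg_bp`` is the platform's segmental resolution floor.
    """

    qc_max_logr_deviation: float = 0.2
    qc_min_call_rate: float = 0.98
    tau_baf: float = 0.1          # het-locus deviation counted as scattered
    theta_scatter: float = 0.5    # scattered fraction required for a call
    het_band: tuple[float, float] = (0.15, 0.85)  # BAF window of het-pattern loci
    het_floor: float = 0.1        # below this het fraction: loss of heterozygosity
    logr_mosaic: float = 0.2
    logr_full_gain: float = math.log2(1.45)   # ~0.536: dosage within 10% of CN 3
    logr_full_loss: float = math.log2(0.55)   # ~-0.862: dosage within 10% of CN 1
    min_seg_bp: int = 10_000_000  # SNP segmental resolution (coarser than NGS)
    min_markers: int = 20
    seg_window_bp: int = 2_000_000  # aggregation window for the changepoint scan
    min_window_markers: int = 5
    whole_merge_tol: float = 0.15  # max arm |median LogR| gap for whole-chrom merge
    arm_cover_frac: float = 0.8
    penalty_factor: float = 4.0


def snp_qc(signal: SnpSignal,
           params: SnpCallerParams = SnpCallerParams()) -> SnpQcReport:
    """Chip-level quality control on the autosomal markers."""
    df = signal.df
    if df.empty:
        raise ValueError("empty SNP signal")
    auto = df[~df["chrom"].isin(["X", "Y"])]
    called = auto[auto["called"]]
    genome_median = float(called["logr"].median())
    deviation = float((called["logr"] - genome_median).abs().median())
    call_rate = float(auto["called"].mean())
    passed = (deviation < params.qc_max_logr_deviation
              and call_rate > params.qc_min_call_rate)
    return SnpQcReport(deviation, call_rate, passed)


def _baf_scatter(baf: np.ndarray, params: SnpCallerParams) -> float:
    """Fraction of het-pattern loci whose BAF deviates from 0.5.

    Loci with BAF inside ``het_band`` are treated as heterozygous-pattern.
    When almost none remain (loss of heterozygosity, as in full monosomy) the
    BAF distribution is maximally un-concentrated at 0.5, so scatter is 1.
    """
    if len(baf) == 0:
        return 1.0
    lo, hi = params.het_band
    het = baf[(baf >= lo) & (baf <= hi)]
    if len(het) / len(baf) < params.het_floor:
        return 1.0
    return float(np.mean(np.abs(het - 0.5) > params.tau_baf))


def summarize_arms(signal: SnpSignal, genome: GenomeModel,
                   params: SnpCallerParams = SnpCallerParams(),
                   qc: SnpQcReport | None = None) -> list[ArmSummary]:
    """Median LogR and BAF scatter per chromosome arm (called markers only)."""
    if qc is None:
        qc = snp_qc(signal, params)
    if not qc.passed:
        warnings.warn("summarizing arms on a signal that failed QC", stacklevel=2)
    df = signal.df[signal.df["called"]]
    genome_median = float(df[~df["chrom"].isin(["X", "Y"])]["logr"].median())
    out = []
    for chrom in genome.chromosomes:
        sub = df[df["chrom"] == chrom]
        for arm in ("p", "q"):
            lo, hi = genome.arm_bounds(chrom, arm)
            m = sub[(sub["pos"] >= lo) & (sub["pos"] <= hi)]
            if len(m) < params.min_markers:
                continue
            out.append(ArmSummary(
                chrom=chrom, arm=arm,
                median_logr=float(m["logr"].median()) - genome_median,
                baf_scatter=_baf_scatter(m["baf"].to_numpy(), params),
                n_markers=len(m)))
    return out


def _classify_segment(median_logr: float, scatter: float,
                      params: SnpCallerParams) -> tuple[str, bool] | None:
    """(direction, mosaic) of a region, or None when normal."""
    if median_logr >= params.logr_full_gain and scatter > params.theta_scatter:
        return "gain", False
    if median_logr <= params.logr_full_loss:
        return "loss", False
    if scatter > params.theta_scatter:
        if median_logr > params.logr_mosaic:
            return "gain", True
        if median_logr < -params.logr_mosaic:
            return "loss", True
    return None


def _window_medians(logr: np.ndarray, pos: np.ndarray, lo: int, hi: int,
                    params: SnpCallerParams):
    """Median LogR per fixed genomic window; returns (medians, marker index bounds).

    Windows coarser than the amplification-bias tile decorrelate the MDA
    component, so the changepoint scan sees independent window noise rather
    than marker-level noise with a wavy baseline.
    """
    w = params.seg_window_bp
    edges = np.arange(lo, hi + w, w)
    idx = np.searchsorted(pos, edges)
    meds, bounds = [], []
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a >= params.min_window_markers:
            meds.append(float(np.median(logr[a:b])))
            bounds.append((int(a), int(b)))
    return np.array(meds), bounds


def call_snp(signal: SnpSignal, genome: GenomeModel,
             params: SnpCallerParams = SnpCallerParams()) -> PlatformDiagnosis:
    """Arm-level ploidy diagnosis from the SNP-array signal.

    Each arm is scanned by binary segmentation on windowed median LogR;
    segments at least ``min_seg_bp`` long are classified by marker-level
    median LogR and BAF scatter.  A segment covering essentially the whole
    arm is reported at arm scope, and both arms agreeing in direction,
    mosaic state and dosage merge into one whole-chromosome event.  A QC
    failure flags the diagnosis unreliable but calling still proceeds.
    """
    qc = snp_qc(signal, params)
    df = signal.df[signal.df["called"]]
    genome_median = float(df[~df["chrom"].isin(["X", "Y"])]["logr"].median())
    events: list[CnEvent] = []
    for chrom in genome.chromosomes:
        sub = df[df["chrom"] == chrom]
        arm_calls: dict[str, tuple] = {}
        arm_events: list[CnEvent] = []
        for arm in ("p", "q"):
            lo, hi = genome.arm_bounds(chrom, arm)
            m = sub[(sub["pos"] >= lo) & (sub["pos"] <= hi)]
            if len(m) < params.min_markers:
                continue
            logr = m["logr"].to_numpy() - genome_median
            baf = m["baf"].to_numpy()
            pos = m["pos"].to_numpy()
            meds, bounds = _window_medians(logr, pos, lo, hi, params)
            if len(meds) == 0:
                continue
            min_win = max(2, params.min_seg_bp // params.seg_window_bp // 2)
            wsegs = binary_segmentation(meds, min_size=min_win,
                                        penalty_factor=params.penalty_factor)
            calls = []
            for wi, wj in wsegs:
                i, j = bounds[wi][0], bounds[wj - 1][1]
                cls = _classify_segment(float(np.median(logr[i:j])),
                                        _baf_scatter(baf[i:j], params), params)
                calls.append((i, j, cls))
            # merge adjacent same-class segments
            merged = [calls[0]]
            for i, j, cls in calls[1:]:
                pi, pj, pcls = merged[-1]
                if cls == pcls:
                    merged[-1] = (pi, j, cls)
                else:
                    merged.append((i, j, cls))
            # a consistent direction over (nearly) the whole arm is one arm
            # event even when pieces straddle the mosaic/full dosage boundary
            aberrant = [(i, j, cls) for i, j, cls in merged if cls is not None]
            n_aberrant = sum(j - i for i, j, _ in aberrant)
            directions = {cls[0] for _, _, cls in aberrant}
            if (aberrant and len(directions) == 1
                    and n_aberrant >= params.arm_cover_frac * len(m)):
                cls = _classify_segment(float(np.median(logr)),
                                        _baf_scatter(baf, params), params)
                if cls is not None:
                    direction, mosaic = cls
                    arm_calls[arm] = (direction, mosaic, float(np.median(logr)))
                    arm_events.append(CnEvent(chrom=chrom, scope=arm,
                                              direction=direction, mosaic=mosaic))
                    continue
            for i, j, cls in aberrant:
                start, end = int(pos[i]), int(pos[j - 1])
                if end - start + 1 < params.min_seg_bp:
                    continue
                events.append(CnEvent(chrom=chrom, scope="segment",
                                      direction=cls[0], mosaic=cls[1],
                                      start_bp=start, end_bp=end))
        if len(arm_calls) == 2:
            (d1, _, v1), (d2, _, v2) = arm_calls["p"], arm_calls["q"]
            if d1 == d2 and abs(v1 - v2) <= params.whole_merge_tol:
                # mosaic-vs-full is re-decided on the chromosome-wide markers:
                # a small arm's median straddles the full-dosage threshold
                chrom_logr = sub["logr"].to_numpy() - genome_median
                cls = _classify_segment(float(np.median(chrom_logr)),
                                        _baf_scatter(sub["baf"].to_numpy(), params),
                                        params)
                if cls is not None and cls[0] == d1:
                    events.append(CnEvent(chrom=chrom, scope="whole",
                                          direction=cls[0], mosaic=cls[1]))
                    arm_events = []
        events.extend(arm_events)
    return PlatformDiagnosis("SNP", events=events, qc=qc, unreliable=not qc.passed)
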