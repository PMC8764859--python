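"""Trophectoderm-biopsy simulator: cell mixtures, WGA bias, dual-platform signals.

The generative model mirrors how a mosaic embryo is actually assayed: a biopsy
of 5-10 trophectoderm cells drawn from a mixture of cell lines is amplified
once by multiple displacement amplification (MDA), and *both* platforms read
separate aliquots of the same amplified product.  Accordingly one
:class:`LocusWeights` instance (the per-tile amplification bias) feeds both the
SNP-array renderer and the read-count renderer, so platform disagreements in
simulation arise from platform noise and calling rules, not from independent
amplifications.

Signals:

* SNP array — per-marker LogR (log2 dosage ratio, 0 at disomy) and B-allele
  frequency (BAF), ~300k markers genome-wide.
* NGS — low-pass read counts in fixed genomic bins with a GC-dependent
  efficiency curve, >= 0.7 million single-end 36 bp reads.

All stochastic operations take an explicit seed; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .karyotype import CnEvent, GenomeModel

__all__ = [
    "CellKaryotype",
    "BiopsyTruth",
    "LocusWeights",
    "SnpParams",
    "NgsParams",
    "SnpSignal",
    "NgsSignal",
    "make_biopsy",
    "expected_copy_number",
    "simulate_mda",
    "render_snp",
    "render_ngs",
    "simulate_embryo",
]


@dataclass(frozen=True)
class CellKaryotype:
    """A single cell line: integer copy states on a disomic baseline.

    ``copy_numbers[i]`` is the total copy number over ``events[i]``'s region
    (1 for a loss, 3 for a gain by default); copy number is 2 elsewhere.
    Events must be non-mosaic and non-overlapping within a chromosome.
    """

    events: tuple[CnEvent, ...] = ()
    copy_numbers: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.events) != len(self.copy_numbers):
            raise ValueError("one copy number per event required")
        for e, cn in zip(self.events, self.copy_numbers):
            if e.mosaic:
                raise ValueError("cell-line events are non-mosaic by definition")
            if cn < 0:
                raise ValueError("copy numbers must be >= 0")
        by_chrom: dict[str, list[CnEvent]] = {}
        for e in self.events:
            by_chrom.setdefault(e.chrom, []).append(e)
        for chrom, evs in by_chrom.items():
            if len(evs) > 1 and any(e.scope == "whole" for e in evs):
                raise ValueError(f"overlapping events on chr{chrom}")

    @classmethod
    def disomic(cls) -> "CellKaryotype":
        return cls()

    @classmethod
    def with_event(cls, event: CnEvent, copy_number: Optional[int] = None) -> "CellKaryotype":
        if copy_number is None:
            copy_number = 3 if event.direction == "gain" else 1
        return cls((event,), (copy_number,))

    def _region_mask(self, event: CnEvent, genome: GenomeModel,
                     chrom: str, pos: np.ndarray) -> np.ndarray:
        if event.chrom != chrom:
            return np.zeros(pos.shape, dtype=bool)
        if event.scope == "whole":
            return np.ones(pos.shape, dtype=bool)
        if event.scope in ("p", "q"):
            lo, hi = genome.arm_bounds(chrom, event.scope)
        else:
            lo, hi = event.start_bp, event.end_bp
        return (pos >= lo) & (pos <= hi)

    def copy_profile(self, genome: GenomeModel, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integer copy number of this cell line at each position."""
        cn = np.full(pos.shape, 2, dtype=np.int64)
        for e, c in zip(self.events, self.copy_numbers):
            cn[self._region_mask(e, genome, chrom, pos)] = c
        return cn


@dataclass(frozen=True)
class BiopsyTruth:
    """Ground-truth composition of one biopsy: cell lines with mixing fractions."""

    components: tuple[tuple[CellKaryotype, float], ...]
    n_cells: int = 5
    seed: Optional[int] = None

    def __post_init__(self):
        fracs = [f for _, f in self.components]
        if not fracs or any(f < 0 or f > 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")

    @classmethod
    def from_fraction(cls, event: CnEvent, fraction: float,
                      n_cells: int = 5, copy_number: Optional[int] = None,
                      seed: Optional[int] = None) -> "BiopsyTruth":
        """Exact two-component mixture (no cell-count sampling)."""
        abn = CellKaryotype.with_event(event, copy_number)
        comps = []
        if fraction < 1:
            comps.append((CellKaryotype.disomic(), 1.0 - fraction))
        if fraction > 0:
            comps.append((abn, fraction))
        return cls(tuple(comps), n_cells=n_cells, seed=seed)

    def mixture_profile(self, genome: GenomeModel, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Mixture-weighted (fractional) copy number at each position."""
        cn = np.zeros(pos.shape, dtype=float)
        for k, f in self.components:
            cn += f * k.copy_profile(genome, chrom, pos)
        return cn


def make_biopsy(event: CnEvent, fraction: float, n_cells: int = 5,
                seed: Optional[int] = None, copy_number: Optional[int] = None) -> BiopsyTruth:
    """Sample a 5-10 cell biopsy from an embryo with one abnormal cell line.

    The realized abnormal cell count is Binomial(n_cells, fraction), so a
    small biopsy quantizes the mosaic fraction to multiples of 1/n_cells.
    Deterministic under a fixed seed.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if not 5 <= n_cells <= 10:
        raise ValueError("a trophectoderm biopsy has 5-10 cells")
    rng = np.random.default_rng(seed)
    k = int(rng.binomial(n_cells, fraction))
    return BiopsyTruth.from_fraction(event, k / n_cells, n_cells=n_cells,
                                     copy_number=copy_number, seed=seed)


def expected_copy_number(truth: BiopsyTruth, genome: GenomeModel,
                         chrom: str, scope: str = "whole",
                         start_bp: Optional[int] = None,
                         end_bp: Optional[int] = None) -> float:
    """Analytic mixture-mean copy number over a region.

    Computed from the nominal fractions (not realized cells):
    sum_i fraction_i x mean copy number of component i over the region,
    bp-weighted.  This is the quantity an intermediate-copy-number assay
    estimates, and is why complementary mixtures (40% monosomy + 60% trisomy
    vs 80% disomy + 20% trisomy, both 2.2) are indistinguishable downstream.
    """
    if scope == "whole":
        lo, hi = 1, genome.length(chrom)
    elif scope in ("p", "q"):
        lo, hi = genome.arm_bounds(chrom, scope)
    elif scope == "segment":
        lo, hi = start_bp, end_bp
    else:
        raise ValueError(f"invalid scope {scope!r}")
    total = 0.0
    for k, f in truth.components:
        # bp-weighted mean copy number of this cell line over [lo, hi]
        mean_cn = 2.0
        for e, c in zip(k.events, k.copy_numbers):
            if e.chrom != chrom:
                continue
            if e.scope == "whole":
                elo, ehi = 1, genome.length(chrom)
            elif e.scope in ("p", "q"):
                elo, ehi = genome.arm_bounds(chrom, e.scope)
            else:
                elo, ehi = e.start_bp, e.end_bp
            overlap = max(0, min(hi, ehi) - max(lo, elo) + 1)
            mean_cn += (c - 2) * overlap / (hi - lo + 1)
        total += f * mean_cn
    return total


@dataclass
class LocusWeights:
    """Multiplicative amplification weight per genomic tile, shared by both assays.

    Weights are 2^(sigma_log * Z) per tile, normalized to mean 1, so
    ``sigma_log`` is the standard deviation of log2 weights.
    """

    tile_bp: int
    weights: dict[str, np.ndarray]
    sigma_log: float
    seed: Optional[int] = None

    def at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        idx = np.minimum((np.asarray(pos) - 1) // self.tile_bp,
                         len(self.weights[chrom]) - 1).astype(np.int64)
        return self.weights[chrom][idx]


def simulate_mda(genome: GenomeModel, tile_kb: int = 1000,
                 sigma_log: float = 0.2, seed: Optional[int] = None) -> LocusWeights:
    """Draw the per-tile MDA amplification-bias field.

    ``sigma_log = 0`` gives weights identically 1 (no bias).
    """
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    rng = np.random.default_rng(seed)
    tile_bp = int(tile_kb * 1000)
    weights = {}
    for chrom in genome.chromosomes:
        n = int(np.ceil(genome.length(chrom) / tile_bp))
        weights[chrom] = np.exp2(sigma_log * rng.standard_normal(n))
    mean = np.mean(np.concatenate(list(weights.values())))
    for chrom in weights:
        weights[chrom] = weights[chrom] / mean
    return LocusWeights(tile_bp, weights, sigma_log, seed)


@dataclass(frozen=True)
class SnpParams:
    """SNP-array renderer parameters (~300k markers, GenomeStudio-like scales)."""

    n_markers: int = 300_000
    sigma_lrr: float = 0.15     # per-marker LogR noise sd (log2 units)
    sigma_baf: float = 0.03     # per-marker BAF noise sd
    het_prob: float = 0.5       # baseline heterozygosity of markers
    nocall_prob: float = 0.01   # per-marker no-call probability


@dataclass(frozen=True)
class NgsParams:
    """Low-pass sequencing renderer parameters (VeriSeq-like scales)."""

    bin_kb: int = 1000
    total_reads: int = 700_000  # mapped-read target; raw reads = mapped / map_ratio
    read_length: int = 36
    gc_coeffs: tuple[float, float, float] = (1.0, 0.0, -8.0)  # efficiency ~ c0+c1*d+c2*d^2, d = gc-0.42
    overdispersion: float = 0.1  # extra-Poisson variance factor: var = lam*(1+od)
    deterministic: bool = False  # counts = expectations (noiseless limit)
    map_ratio_mean: float = 96.0
    map_ratio_sd: float = 1.0
    duplicate_mean: float = 12.0
    duplicate_sd: float = 2.0
    gc_mean: float = 0.42
    gc_sd: float = 0.04


@dataclass
class SnpSignal:
    """Per-marker LogR/BAF table with rendering metadata."""

    df: pd.DataFrame  # chrom, pos, logr, baf, called
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        baf = self.df["baf"].to_numpy()
        if len(baf) and (np.nanmin(baf) < 0 or np.nanmax(baf) > 1):
            raise ValueError("BAF outside [0, 1]")


@dataclass
class NgsSignal:
    """Per-bin GC/read-count table with sequencing QC metadata."""

    df: pd.DataFrame  # chrom, start, end, gc_fraction, read_count
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.df) and self.df["read_count"].min() < 0:
            raise ValueError("read counts must be >= 0")


def _marker_positions(genome: GenomeModel, n_markers: int,
                      rng: np.random.Generator) -> dict[str, np.ndarray]:
    lengths = np.array([genome.length(c) for c in genome.chromosomes], dtype=float)
    alloc = np.maximum(1, np.round(n_markers * lengths / lengths.sum()).astype(int))
    out = {}
    for chrom, n in zip(genome.chromosomes, alloc):
        pos = np.sort(rng.integers(1, genome.length(chrom) + 1, size=n))
        out[chrom] = pos
    return out


def render_snp(truth: BiopsyTruth, weights: LocusWeights, genome: GenomeModel,
               params: SnpParams = SnpParams(), seed: Optional[int] = None) -> SnpSignal:
    """Render the SNP-array signal from the amplified biopsy.

    Per marker the total copy number ``c`` and B-allele copies ``b`` are the
    mixture-weighted values over cell lines (each line's allele content drawn
    consistently from the baseline genotype), giving ``BAF = b/c`` and
    ``LogR = log2((c/2) * w)`` plus Gaussian noise; BAF is truncated to [0, 1]
    and drawn uniformly where c = 0.
    """
    rng = np.random.default_rng(seed)
    positions = _marker_positions(genome, params.n_markers, rng)
    frames = []
    for chrom in genome.chromosomes:
        pos = positions[chrom]
        n = len(pos)
        geno = rng.choice(np.array([0, 1, 2]), size=n, p=[
            (1 - params.het_prob) / 2, params.het_prob, (1 - params.het_prob) / 2])
        c_mix = np.zeros(n)
        b_mix = np.zeros(n)
        for kary, frac in truth.components:
            cn = kary.copy_profile(genome, chrom, pos)
            b = geno.astype(float).copy()
            gain = cn > 2
            if gain.any():
                # each extra copy duplicates a uniformly chosen original allele
                extra = cn[gain] - 2
                b[gain] += rng.binomial(extra, geno[gain] / 2.0)
            loss = cn < 2
            if loss.any():
                # keep cn alleles sampled without replacement from the two
                b[loss] = rng.hypergeometric(geno[loss], 2 - geno[loss],
                                             np.maximum(cn[loss], 0))
            b[cn == 0] = 0.0
            c_mix += frac * cn
            b_mix += frac * b
        with np.errstate(divide="ignore", invalid="ignore"):
            baf = np.where(c_mix > 0, b_mix / np.maximum(c_mix, 1e-12), rng.random(n))
        baf = np.clip(baf + params.sigma_baf * rng.standard_normal(n), 0.0, 1.0)
        w = weights.at(chrom, pos)
        logr = np.log2(np.maximum(c_mix, 0.05) / 2.0 * w) \
            + params.sigma_lrr * rng.standard_normal(n)
        called = rng.random(n) >= params.nocall_prob
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "logr": logr, "baf": baf, "called": called}))
    df = pd.concat(frames, ignore_index=True)
    meta = {"n_markers": int(len(df)), "seed": seed,
            "sigma_lrr": params.sigma_lrr, "sigma_baf": params.sigma_baf,
            "nocall_prob": params.nocall_prob, "platform": "SNP"}
    return SnpSignal(df, meta)


def _bin_table(genome: GenomeModel, bin_bp: int) -> pd.DataFrame:
    rows = []
    for chrom in genome.chromosomes:
        length = genome.length(chrom)
        starts = np.arange(1, length + 1, bin_bp)
        ends = np.minimum(starts + bin_bp - 1, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _smooth_gc(n: int, rng: np.random.Generator, mean: float, sd: float) -> np.ndarray:
    raw = rng.standard_normal(n + 4)
    kernel = np.ones(5) / 5.0
    sm = np.convolve(raw, kernel, mode="valid")
    sm = sm / np.sqrt((kernel ** 2).sum())  # restore unit variance after smoothing
    return np.clip(mean + sd * sm, 0.30, 0.60)


def render_ngs(truth: BiopsyTruth, weights: LocusWeights, genome: GenomeModel,
               params: NgsParams = NgsParams(), seed: Optional[int] = None) -> NgsSignal:
    """Render binned low-pass read counts from the amplified biopsy.

    Bin expectation is proportional to width x (copy number / 2) x MDA weight
    x GC efficiency, normalized so expected mapped reads sum to
    ``params.total_reads``; counts are negative-binomial with variance
    lambda*(1+overdispersion) (Poisson at 0; exact expectations when
    ``deterministic``).
    """
    if params.total_reads <= 0:
        raise ValueError("total_reads must be positive")
    rng = np.random.default_rng(seed)
    bins = _bin_table(genome, params.bin_kb * 1000)
    gc = np.concatenate([
        _smooth_gc((bins["chrom"] == c).sum(), rng, params.gc_mean, params.gc_sd)
        for c in genome.chromosomes])
    mid = ((bins["start"] + bins["end"]) // 2).to_numpy()
    width = (bins["end"] - bins["start"] + 1).to_numpy().astype(float)
    cn = np.concatenate([
        truth.mixture_profile(genome, c, mid[(bins["chrom"] == c).to_numpy()])
        for c in genome.chromosomes])
    w = np.concatenate([
        weights.at(c, mid[(bins["chrom"] == c).to_numpy()])
        for c in genome.chromosomes])
    d = gc - 0.42
    c0, c1, c2 = params.gc_coeffs
    eff = np.maximum(c0 + c1 * d + c2 * d ** 2, 0.05)
    lam = width * (cn / 2.0) * w * eff
    lam = lam / lam.sum() * params.total_reads
    if params.deterministic:
        counts = lam
    elif params.overdispersion > 0:
        shape = lam / params.overdispersion
        lam_mix = rng.gamma(np.maximum(shape, 1e-12), params.overdispersion)
        counts = rng.poisson(lam_mix).astype(float)
    else:
        counts = rng.poisson(lam).astype(float)
    map_ratio = float(np.clip(rng.normal(params.map_ratio_mean, params.map_ratio_sd), 50, 100))
    duplicate = float(np.clip(rng.normal(params.duplicate_mean, params.duplicate_sd), 0, 100))
    mapped = float(counts.sum())
    df = bins.assign(gc_fraction=gc, read_count=counts)
    meta = {
        "total_reads": int(round(mapped / (map_ratio / 100.0))),
        "mapped_reads": int(round(mapped)),
        "read_length": params.read_length,
        "map_ratio": map_ratio,
        "duplicate_rate": duplicate,
        "gc_content": float(100.0 * np.average(gc, weights=width * np.maximum(counts, 0) + 1e-9)),
        "seed": seed,
        "platform": "NGS",
    }
    return NgsSignal(df, meta)


def simulate_embryo(truth: BiopsyTruth, genome: GenomeModel,
                    snp_params: SnpParams = SnpParams(),
                    ngs_params: NgsParams = NgsParams(),
                    mda_sigma_log: float = 0.2, mda_tile_kb: int = 1000,
                    seed: Optional[int] = None) -> tuple[SnpSignal, NgsSignal]:
    """Render both platform signals from one shared MDA product.

    The single-amplification, dual-aliquot design: one amplification-bias
    field is drawn and reused by both renderers.
    """
    ss = np.random.SeedSequence(seed)
    s_mda, s_snp, s_ngs = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    weights = simulate_mda(genome, tile_kb=mda_tile_kb, sigma_log=mda_sigma_log, seed=s_mda)
    snp = render_snp(truth, weights, genome, snp_params, seed=s_snp)
    ngs = render_ngs(truth, weights, genome, ngs_params, seed=s_ngs)
    return snp, ngs
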