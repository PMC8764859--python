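"""File formats, per-embryo table ingestion and run configuration.

Interchange formats are TSV with ``# key: value`` header comments (seed,
config hash) and JSON for summaries.  Segment coordinates in all tables are
1-based inclusive (cytogenetic convention; note this differs from BED's
0-based half-open — flagged in the format header).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .concordance import classify_concordance
from .karyotype import (CnEvent, GenomeModel, NotationParseError,
                        GenomeLookupError, PlatformDiagnosis,
                        format_diagnosis, parse_mosaic_notation)
from .simulate import NgsParams, NgsSignal, SnpParams, SnpSignal
from .snp import SnpCallerParams
from .ngs import NgsCallerParams
from .stats import CohortRecord

__all__ = ["RunConfig", "DEFAULT_DIALECT", "read_diagnosis_table",
           "write_signal_tsv", "read_snp_signal", "read_ngs_signal",
           "write_diagnosis_tsv", "read_diagnosis_tsv",
           "write_concordance_tsv"]

# maps standard field -> column name in a supplementary-style table
DEFAULT_DIALECT = {
    "embryo_id": "embryo_id",
    "snp": "snp_result",
    "ngs": "ngs_result",
    "level": "ngs_level",
    "age": "maternal_age",
    "quality": "good_quality",
}


class SimulatorConfig(BaseModel):
    n_markers: int = 300_000
    sigma_lrr: float = 0.15
    sigma_baf: float = 0.03
    het_prob: float = 0.5
    nocall_prob: float = 0.01
    bin_kb: int = 1000
    total_reads: int = 700_000
    read_length: int = 36
    overdispersion: float = 0.1
    mda_sigma_log: float = 0.2
    mda_tile_kb: int = 1000


class SnpThresholds(BaseModel):
    qc_max_logr_deviation: float = 0.2
    qc_min_call_rate: float = 0.98
    logr_mosaic: float = 0.2
    min_seg_bp: int = 10_000_000
    tau_baf: float = 0.1
    theta_scatter: float = 0.5


class NgsThresholds(BaseModel):
    qc_min_reads: int = 700_000
    qc_min_map_ratio: float = 80.0
    qc_gc_low: float = 39.0
    qc_gc_high: float = 45.0
    qc_max_sd: float = 3.5
    mosaic_low: float = 1.20
    euploid_low: float = 1.80
    euploid_high: float = 2.20
    mosaic_high: float = 2.80
    min_segment_bp: int = 4_000_000


class StatsConfig(BaseModel):
    fisher_min_expected: float = 5.0
    transfer_max_level: float = 50.0
    age_cut: float = 35.0


class RunConfig(BaseModel):
    """Complete pipeline configuration; every published threshold appears once."""

    genome_build: str = "hg19-schematic"
    chromosomes: Optional[list[str]] = None
    seed: int = 0
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)
    snp: SnpThresholds = Field(default_factory=SnpThresholds)
    ngs: NgsThresholds = Field(default_factory=NgsThresholds)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def genome(self) -> GenomeModel:
        g = GenomeModel.default()
        return g.subset(self.chromosomes) if self.chromosomes else g

    def snp_params(self) -> SnpParams:
        s = self.simulator
        return SnpParams(n_markers=s.n_markers, sigma_lrr=s.sigma_lrr,
                         sigma_baf=s.sigma_baf, het_prob=s.het_prob,
                         nocall_prob=s.nocall_prob)

    def ngs_params(self) -> NgsParams:
        s = self.simulator
        return NgsParams(bin_kb=s.bin_kb, total_reads=s.total_reads,
                         read_length=s.read_length,
                         overdispersion=s.overdispersion)

    def snp_caller_params(self) -> SnpCallerParams:
        t = self.snp
        return SnpCallerParams(
            qc_max_logr_deviation=t.qc_max_logr_deviation,
            qc_min_call_rate=t.qc_min_call_rate, tau_baf=t.tau_baf,
            theta_scatter=t.theta_scatter, logr_mosaic=t.logr_mosaic,
            min_seg_bp=t.min_seg_bp)

    def ngs_caller_params(self) -> NgsCallerParams:
        t = self.ngs
        return NgsCallerParams(
            qc_min_reads=t.qc_min_reads, qc_min_map_ratio=t.qc_min_map_ratio,
            qc_gc_range=(t.qc_gc_low, t.qc_gc_high), qc_max_sd=t.qc_max_sd,
            mosaic_low=t.mosaic_low, euploid_low=t.euploid_low,
            euploid_high=t.euploid_high, mosaic_high=t.mosaic_high,
            min_segment_bp=t.min_segment_bp)


def _write_tsv(df: pd.DataFrame, path: Union[str, Path], header: dict) -> None:
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: Union[str, Path]) -> tuple[pd.DataFrame, dict]:
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].partition(":")
            header[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return df, header


def write_signal_tsv(signal: Union[SnpSignal, NgsSignal],
                     path: Union[str, Path]) -> None:
    header = {"format": "pgtmosaic-signal/1", "coordinates": "1-based inclusive"}
    header.update({k: v for k, v in signal.meta.items() if v is not None})
    _write_tsv(signal.df, path, header)


def read_snp_signal(path: Union[str, Path]) -> SnpSignal:
    df, header = _read_tsv(path)
    return SnpSignal(df, meta=header)


def read_ngs_signal(path: Union[str, Path]) -> NgsSignal:
    df, header = _read_tsv(path)
    for k in ("total_reads", "mapped_reads"):
        if k in header:
            header[k] = int(header[k])
    for k in ("map_ratio", "duplicate_rate", "gc_content"):
        if k in header:
            header[k] = float(header[k])
    return NgsSignal(df, meta=header)


def _diagnosis_rows(d: PlatformDiagnosis, genome: GenomeModel) -> list[dict]:
    base = {"embryo_id": d.embryo_id, "platform": d.platform,
            "overall_class": d.overall_class,
            "qc_pass": not d.unreliable,
            "notation": format_diagnosis(d, genome)}
    if not d.events:
        return [dict(base, chrom="", scope="", direction="", mosaic="",
                     start_bp="", end_bp="", level_percent="", cnv_value="")]
    rows = []
    for e in d.events:
        rows.append(dict(
            base, chrom=e.chrom, scope=e.scope, direction=e.direction,
            mosaic=e.mosaic, start_bp=e.start_bp or "", end_bp=e.end_bp or "",
            level_percent="" if e.level_percent is None else e.level_percent,
            cnv_value="" if e.cnv_value is None else e.cnv_value))
    return rows


def write_diagnosis_tsv(diagnoses: list[PlatformDiagnosis], genome: GenomeModel,
                        path: Union[str, Path], header: Optional[dict] = None) -> None:
    rows = [r for d in diagnoses for r in _diagnosis_rows(d, genome)]
    hdr = {"format": "pgtmosaic-diagnosis/1", "coordinates": "1-based inclusive"}
    hdr.update(header or {})
    _write_tsv(pd.DataFrame(rows), path, hdr)


def read_diagnosis_tsv(path: Union[str, Path]) -> list[PlatformDiagnosis]:
    df, _ = _read_tsv(path)
    out = []
    for (embryo_id, platform), grp in df.groupby(["embryo_id", "platform"], sort=False):
        events = []
        for _, row in grp.iterrows():
            if not isinstance(row["chrom"], str) and pd.isna(row["chrom"]):
                continue
            if row["chrom"] == "" or pd.isna(row["scope"]):
                continue
            events.append(CnEvent(
                chrom=str(row["chrom"]), scope=row["scope"],
                direction=row["direction"], mosaic=bool(row["mosaic"]),
                start_bp=int(row["start_bp"]) if _has(row["start_bp"]) else None,
                end_bp=int(row["end_bp"]) if _has(row["end_bp"]) else None,
                level_percent=float(row["level_percent"]) if _has(row["level_percent"]) else None,
                cnv_value=float(row["cnv_value"]) if _has(row["cnv_value"]) else None))
        qc_pass = bool(grp.iloc[0]["qc_pass"])
        out.append(PlatformDiagnosis(platform, events=events,
                                     embryo_id=str(embryo_id),
                                     unreliable=not qc_pass))
    return out


def _has(v) -> bool:
    return v is not None and v == v and v != ""


def _parse_quality(v) -> Optional[bool]:
    if isinstance(v, bool):
        return v
    if v is None or v != v:
        return None
    s = str(v).strip().lower()
    if s in ("yes", "true", "good", "1"):
        return True
    if s in ("no", "false", "low", "poor", "0"):
        return False
    return None


def read_diagnosis_table(source: Union[str, Path, pd.DataFrame],
                         genome: GenomeModel,
                         dialect: Optional[dict] = None,
                         classify: bool = True
                         ) -> tuple[list[CohortRecord], list[dict]]:
    """Ingest a per-embryo diagnosis table (supplementary-table style).

    ``dialect`` maps the standard fields (embryo_id, snp, ngs, level, age,
    quality) to the file's column names; unparseable rows are collected into
    the returned reject report, never silently dropped.  The per-embryo NGS
    level is attached to every mosaic NGS event (the table dialect carries
    one level per embryo).  With ``classify`` the between-platform
    concordance is computed per record.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    if isinstance(source, (str, Path)):
        df, _ = _read_tsv(source)
    else:
        df = source
    if df.empty:
        raise ValueError("empty diagnosis table")
    for fieldname in ("embryo_id", "snp", "ngs"):
        if dialect[fieldname] not in df.columns:
            raise ValueError(f"missing mandatory column {dialect[fieldname]!r} "
                             f"(field {fieldname})")
    records, rejects = [], []
    for idx, row in df.iterrows():
        embryo_id = str(row[dialect["embryo_id"]])
        try:
            snp_events = parse_mosaic_notation(str(row[dialect["snp"]]), genome)
            ngs_events = parse_mosaic_notation(str(row[dialect["ngs"]]), genome)
            level = row.get(dialect["level"])
            if _has(level):
                level = float(level)
                ngs_events = [replace(e, level_percent=level) if e.mosaic else e
                              for e in ngs_events]
            snp = PlatformDiagnosis("SNP", events=snp_events, embryo_id=embryo_id)
            ngs = PlatformDiagnosis("NGS", events=ngs_events, embryo_id=embryo_id)
            age_col = dialect["age"]
            age = float(row[age_col]) if age_col in df.columns and _has(row.get(age_col)) else None
            quality = _parse_quality(row.get(dialect["quality"]))
            rec = CohortRecord(embryo_id=embryo_id, snp=snp, ngs=ngs,
                               maternal_age=age, good_quality=quality)
            if classify:
                rec.concordance = classify_concordance(snp, ngs, genome)
            records.append(rec)
        except (NotationParseError, GenomeLookupError, ValueError) as err:
            rejects.append({"row": int(idx), "embryo_id": embryo_id,
                            "error": str(err)})
    return records, rejects


def write_concordance_tsv(records: list[CohortRecord],
                          path: Union[str, Path],
                          header: Optional[dict] = None) -> None:
    def fmt_keys(keys) -> str:
        return ";".join(f"{c}{s if s != 'whole' else ''}:{d}"
                        for c, s, d in sorted(keys))

    rows = []
    for r in records:
        c = r.concordance
        rows.append({
            "embryo_id": r.embryo_id,
            "category": c.category if c else "",
            "shared": fmt_keys(c.shared) if c else "",
            "snp_only": fmt_keys(c.snp_only) if c else "",
            "ngs_only": fmt_keys(c.ngs_only) if c else "",
            "flags": ";".join(c.flags) if c else "",
        })
    hdr = {"format": "pgtmosaic-concordance/1"}
    hdr.update(header or {})
    _write_tsv(pd.DataFrame(rows), path, hdr)
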