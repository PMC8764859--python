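"""Genome model, copy-number events and mosaic-call notation.

The notation dialect used throughout the package writes one diagnosis as a
comma-separated list of events.  A mosaic event is ``[+|-]mos(<locus>)`` and a
non-mosaic (pure) aneuploidy drops the ``mos``: ``+21`` is a pure trisomy 21,
``-mos(2q)`` a mosaic loss of the long arm of chromosome 2, ``+mos(16p12.2-q21)``
a mosaic segmental gain spanning the centromere of chromosome 16.  An empty
diagnosis is written ``euploid``.

Coordinates are 1-based inclusive, following cytogenetic convention.  Band
coordinates come from a bundled *schematic* cytoband table (see
``data/cytobands_schematic.tsv``): chromosome lengths are hg19, centromere
midpoints are approximate, and band names subdivide each arm uniformly in
ISCN style.  It is a synthetic stand-in for a curated ideogram, adequate for
arm-level reasoning and reproducible segment round-trips, not for looking up
real band boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "GenomeModel",
    "CnEvent",
    "PlatformDiagnosis",
    "NotationParseError",
    "GenomeLookupError",
    "parse_mosaic_notation",
    "format_event",
    "format_diagnosis",
    "event_keys",
    "build_schematic_cytobands",
]

# hg19 chromosome lengths (bp) and approximate centromere midpoints (bp).
_CHROM_LENGTHS = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}
_CENTROMERES = {
    "1": 125_000_000, "2": 93_300_000, "3": 91_000_000, "4": 50_400_000,
    "5": 48_400_000, "6": 61_000_000, "7": 59_900_000, "8": 45_600_000,
    "9": 49_000_000, "10": 40_200_000, "11": 53_700_000, "12": 35_800_000,
    "13": 17_900_000, "14": 17_600_000, "15": 19_000_000, "16": 36_600_000,
    "17": 24_000_000, "18": 17_200_000, "19": 26_500_000, "20": 27_500_000,
    "21": 13_200_000, "22": 14_700_000, "X": 60_600_000, "Y": 12_500_000,
}

_CHROM_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y"]


class NotationParseError(ValueError):
    """Malformed mosaic-call notation; the message names the offending token."""


class GenomeLookupError(KeyError):
    """Unknown chromosome, arm or cytoband."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return self.args[0] if self.args else ""


def build_schematic_cytobands(
    lengths: dict[str, int],
    centromeres: dict[str, int],
    band_mb: float = 6.0,
) -> pd.DataFrame:
    """Generate a schematic ISCN-style band table by uniform arm subdivision.

    Each arm is cut into major bands of roughly ``band_mb`` megabases named
    from the centromere outward (11, 12, 13, 21, 22, ...), each split into
    three sub-bands (.1, .2, .3), again numbered away from the centromere.
    Returns a DataFrame with columns (chrom, band, start, end), 1-based
    inclusive, one row per sub-band.
    """
    rows = []
    for chrom in lengths:
        cen = centromeres[chrom]
        for arm in ("p", "q"):
            lo, hi = (1, cen) if arm == "p" else (cen + 1, lengths[chrom])
            arm_len = hi - lo + 1
            n_major = max(3, round(arm_len / (band_mb * 1e6)))
            # sub-band edges, indexed from the centromere outward
            n_sub = 3 * n_major
            edges = [lo + round(i * arm_len / n_sub) for i in range(n_sub)] + [hi + 1]
            for i in range(n_sub):
                major, sub = i // 3, i % 3
                name = f"{arm}{major // 3 + 1}{major % 3 + 1}.{sub + 1}"
                if arm == "p":  # p-arm numbering runs toward pter (descending coords)
                    start, end = edges[n_sub - 1 - i], edges[n_sub - i] - 1
                else:
                    start, end = edges[i], edges[i + 1] - 1
                rows.append((chrom, name, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "band", "start", "end"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _load_bundled_cytobands() -> pd.DataFrame:
    ref = resources.files("pgtmosaic.data").joinpath("cytobands_schematic.tsv")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype={"chrom": str})


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with lengths, centromeres and a cytoband table.

    The p arm is ``[1, centromere]`` and the q arm ``(centromere, length]``,
    1-based inclusive.
    """

    chromosomes: tuple[str, ...]
    lengths: dict[str, int]
    centromeres: dict[str, int]
    cytobands: pd.DataFrame = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        for c in self.chromosomes:
            if c not in self.lengths or c not in self.centromeres:
                raise GenomeLookupError(f"chromosome {c!r} missing length/centromere")
            if not 0 < self.centromeres[c] < self.lengths[c]:
                raise ValueError(f"centromere of chr{c} outside (0, length)")
        if self.cytobands is None:
            object.__setattr__(self, "cytobands", _load_bundled_cytobands())

    @classmethod
    def default(cls, chromosomes: Optional[Iterable[str]] = None) -> "GenomeModel":
        """The bundled 24-chromosome model, optionally restricted to a subset."""
        chroms = tuple(chromosomes) if chromosomes is not None else tuple(_CHROM_ORDER)
        return cls(chroms, dict(_CHROM_LENGTHS), dict(_CENTROMERES))

    def subset(self, chromosomes: Iterable[str]) -> "GenomeModel":
        chroms = tuple(chromosomes)
        unknown = [c for c in chroms if c not in self.chromosomes]
        if unknown:
            raise GenomeLookupError(f"unknown chromosome(s) {unknown}")
        return replace(self, chromosomes=chroms)

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(c for c in self.chromosomes if c not in ("X", "Y"))

    def length(self, chrom: str) -> int:
        self._check_chrom(chrom)
        return self.lengths[chrom]

    def centromere(self, chrom: str) -> int:
        self._check_chrom(chrom)
        return self.centromeres[chrom]

    def arm_bounds(self, chrom: str, arm: str) -> tuple[int, int]:
        """1-based inclusive (start, end) of an arm."""
        self._check_chrom(chrom)
        cen = self.centromeres[chrom]
        if arm == "p":
            return 1, cen
        if arm == "q":
            return cen + 1, self.lengths[chrom]
        raise GenomeLookupError(f"unknown arm {arm!r}")

    def arm_of(self, chrom: str, pos: int) -> str:
        return "p" if pos <= self.centromere(chrom) else "q"

    def band_span(self, chrom: str, band: str) -> tuple[int, int]:
        """Coordinate span of a band ('p12.2') or major band ('q21')."""
        self._check_chrom(chrom)
        cb = self.cytobands
        rows = cb[(cb["chrom"] == chrom)
                  & ((cb["band"] == band) | cb["band"].str.startswith(band + "."))]
        if rows.empty:
            raise GenomeLookupError(f"unknown band {chrom}{band}")
        return int(rows["start"].min()), int(rows["end"].max())

    def band_at(self, chrom: str, pos: int) -> str:
        """Name of the sub-band containing a position."""
        self._check_chrom(chrom)
        cb = self.cytobands
        rows = cb[(cb["chrom"] == chrom) & (cb["start"] <= pos) & (cb["end"] >= pos)]
        if rows.empty:
            raise GenomeLookupError(f"position {pos} outside chr{chrom} bands")
        return str(rows.iloc[0]["band"])

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self.chromosomes:
            raise GenomeLookupError(f"unknown chromosome {chrom!r}")


_VALID_SCOPES = ("whole", "p", "q", "segment")


@dataclass(frozen=True)
class CnEvent:
    """One copy-number abnormality on one chromosome.

    ``scope`` is ``whole``, an arm (``p``/``q``) or ``segment`` with 1-based
    inclusive ``start_bp``/``end_bp``.  ``level_percent`` (fraction of abnormal
    cells implied by the copy-number signal, 0-100) is reported by the NGS
    caller only; the SNP-array caller cannot quantify it and leaves it None.
    """

    chrom: str
    scope: str
    direction: str  # "gain" | "loss"
    mosaic: bool = False
    start_bp: Optional[int] = None
    end_bp: Optional[int] = None
    level_percent: Optional[float] = None
    cnv_value: Optional[float] = None

    def __post_init__(self):
        if self.scope not in _VALID_SCOPES:
            raise ValueError(f"invalid scope {self.scope!r}")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.scope == "segment":
            if self.start_bp is None or self.end_bp is None:
                raise ValueError("segment scope requires start_bp and end_bp")
            if not 0 < self.start_bp <= self.end_bp:
                raise ValueError("segment coordinates must satisfy 0 < start <= end")
        elif self.start_bp is not None or self.end_bp is not None:
            raise ValueError("coordinates only allowed for segment scope")
        if self.level_percent is not None and not 0 <= self.level_percent <= 100:
            raise ValueError("level_percent must lie in [0, 100]")


@dataclass
class PlatformDiagnosis:
    """One platform's call set for one embryo."""

    platform: str  # "SNP" | "NGS"
    events: list[CnEvent] = field(default_factory=list)
    qc: object = None
    embryo_id: Optional[str] = None
    unreliable: bool = False  # set when QC failed

    def __post_init__(self):
        if self.platform not in ("SNP", "NGS"):
            raise ValueError(f"invalid platform {self.platform!r}")
        if self.platform == "SNP":
            for e in self.events:
                if e.level_percent is not None:
                    raise ValueError("SNP-array events cannot carry a mosaic level")
        for e in self.events:
            if e.scope == "whole":
                clash = [o for o in self.events
                         if o is not e and o.chrom == e.chrom
                         and o.scope != "whole" and o.direction == e.direction]
                if clash:
                    raise ValueError(
                        f"whole-chromosome event on chr{e.chrom} coexists with an "
                        f"arm/segment event of the same direction")

    @property
    def overall_class(self) -> str:
        if not self.events:
            return "euploid"
        flags = {e.mosaic for e in self.events}
        if flags == {True}:
            return "mosaic"
        if flags == {False}:
            return "aneuploid"
        return "mosaic_and_aneuploid"

    @property
    def mosaic_events(self) -> list[CnEvent]:
        return [e for e in self.events if e.mosaic]

    @property
    def aneuploid_events(self) -> list[CnEvent]:
        return [e for e in self.events if not e.mosaic]


_TOKEN_RE = re.compile(
    r"^(?P<sign>[+-])(?:(?P<mos>mos)\()?(?P<chrom>\d{1,2}|X|Y)(?P<locus>[^)]*)(?P<close>\))?$"
)
_BAND_RE = re.compile(r"^(?P<arm>[pq])(?P<num>\d+(?:\.\d+)?)$")


def _resolve_locus(chrom: str, locus: str, genome: GenomeModel):
    """Map the locus part of a token to (scope, start, end)."""
    if locus == "":
        return "whole", None, None
    if locus in ("p", "q"):
        return locus, None, None
    parts = locus.split("-")
    if len(parts) > 2 or not all(_BAND_RE.match(p or "") for p in parts):
        raise NotationParseError(f"malformed locus {chrom}{locus!r}")
    spans = [genome.band_span(chrom, p) for p in parts]
    start = min(s for s, _ in spans)
    end = max(e for _, e in spans)
    return "segment", start, end


def parse_mosaic_notation(text: str, genome: GenomeModel) -> list[CnEvent]:
    """Parse a diagnosis notation string into a list of events.

    ``euploid`` (or an empty string) parses to the empty list.  Raises
    :class:`NotationParseError` on malformed tokens and
    :class:`GenomeLookupError` on unknown chromosomes/bands.
    """
    text = text.strip()
    if text == "" or text.lower() == "euploid":
        return []
    events = []
    for raw in text.split(","):
        token = raw.strip()
        m = _TOKEN_RE.match(token)
        if not m or (m.group("mos") and not m.group("close")) \
                or (not m.group("mos") and m.group("close")):
            raise NotationParseError(f"malformed token {token!r}")
        chrom = m.group("chrom")
        genome._check_chrom(chrom)
        scope, start, end = _resolve_locus(chrom, m.group("locus"), genome)
        events.append(CnEvent(
            chrom=chrom,
            scope=scope,
            direction="gain" if m.group("sign") == "+" else "loss",
            mosaic=bool(m.group("mos")),
            start_bp=start,
            end_bp=end,
        ))
    return events


def format_event(e: CnEvent, genome: GenomeModel) -> str:
    sign = "+" if e.direction == "gain" else "-"
    if e.scope == "whole":
        locus = e.chrom
    elif e.scope in ("p", "q"):
        locus = f"{e.chrom}{e.scope}"
    else:
        b1 = genome.band_at(e.chrom, e.start_bp)
        b2 = genome.band_at(e.chrom, e.end_bp)
        locus = f"{e.chrom}{b1}" if b1 == b2 else f"{e.chrom}{b1}-{b2}"
    return f"{sign}mos({locus})" if e.mosaic else f"{sign}{locus}"


def format_diagnosis(d: PlatformDiagnosis, genome: GenomeModel) -> str:
    """Inverse of :func:`parse_mosaic_notation`; empty diagnoses → ``euploid``."""
    if not d.events:
        return "euploid"
    return ",".join(format_event(e, genome) for e in d.events)


def event_keys(e: CnEvent, genome: GenomeModel) -> frozenset:
    """Arm-scope concordance keys ``(chrom, whole|p|q, direction)`` for an event.

    Whole-chromosome mosaicism is a different *type* from arm mosaicism, so a
    whole-chromosome event yields the single key ``(chrom, 'whole', dir)``,
    never the pair of arm keys.  A segment contributes one key per arm it
    overlaps; segment coordinates themselves never appear in keys.
    """
    if e.scope == "whole":
        return frozenset({(e.chrom, "whole", e.direction)})
    if e.scope in ("p", "q"):
        return frozenset({(e.chrom, e.scope, e.direction)})
    if e.end_bp > genome.length(e.chrom):
        raise ValueError(f"segment end {e.end_bp} beyond chr{e.chrom}")
    cen = genome.centromere(e.chrom)
    arms = set()
    if e.start_bp <= cen:
        arms.add("p")
    if e.end_bp > cen:
        arms.add("q")
    return frozenset({(e.chrom, a, e.direction) for a in arms})
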