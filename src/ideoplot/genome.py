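"""Genome coordinate system: chromosomes, centromeres, cytogenetic bands.

Bands use the UCSC convention internally: 0-based, half-open intervals and
the gieStain vocabulary (gneg, gpos25..gpos100, acen, gvar, stalk).
Chromosome names are stored without the ``chr`` prefix; only the 24
canonical human chromosomes (1-22, X, Y) are modelled.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ConfigurationError, InputFormatError

__all__ = [
    "Stain",
    "CytoBand",
    "ChromosomeDef",
    "GenomeAssembly",
    "CANONICAL_CHROMS",
    "normalize_chrom",
    "parse_cytoband",
    "serialize_cytoband",
    "load_cytoband",
    "build_genome",
    "builtin_genome",
    "synthetic_genome",
]

#: Canonical human chromosome names in karyotype order.
CANONICAL_CHROMS: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_CHROM_ORDER = {name: i for i, name in enumerate(CANONICAL_CHROMS)}


class Stain(str, Enum):
    """UCSC gieStain classes for cytogenetic bands."""

    GNEG = "gneg"
    GPOS25 = "gpos25"
    GPOS50 = "gpos50"
    GPOS75 = "gpos75"
    GPOS100 = "gpos100"
    ACEN = "acen"
    GVAR = "gvar"
    STALK = "stalk"


@dataclass(frozen=True, slots=True)
class CytoBand:
    """One Giemsa-stained band: a half-open [start_bp, end_bp) interval."""

    chrom: str
    start_bp: int
    end_bp: int
    band_name: str
    stain: Stain

    def __post_init__(self) -> None:
        if self.start_bp < 0:
            raise ValueError(f"band start must be >= 0, got {self.start_bp}")
        if self.end_bp <= self.start_bp:
            raise ValueError(
                f"band end ({self.end_bp}) must exceed start ({self.start_bp})"
            )
        if not isinstance(self.stain, Stain):
            object.__setattr__(self, "stain", Stain(self.stain))


@dataclass(frozen=True, slots=True)
class ChromosomeDef:
    """A chromosome: total length and the span of its centromeric (acen) bands."""

    name: str
    length_bp: int
    centromere_start_bp: int
    centromere_end_bp: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere_start_bp < self.centromere_end_bp <= self.length_bp):
            raise ValueError(
                f"chromosome {self.name}: centromere span "
                f"({self.centromere_start_bp}, {self.centromere_end_bp}) "
                f"invalid for length {self.length_bp}"
            )


class GenomeAssembly:
    """Ordered chromosomes plus per-chromosome sorted, disjoint band lists."""

    def __init__(
        self,
        chromosomes: Iterable[ChromosomeDef],
        bands: dict[str, Iterable[CytoBand]] | None = None,
    ):
        self.chromosomes: tuple[ChromosomeDef, ...] = tuple(chromosomes)
        self._by_name = {c.name: c for c in self.chromosomes}
        bands = bands or {}
        self.bands: dict[str, tuple[CytoBand, ...]] = {
            c.name: tuple(bands.get(c.name, ())) for c in self.chromosomes
        }
        self._validate()

    def _validate(self) -> None:
        for chrom, blist in self.bands.items():
            if chrom not in self._by_name:
                raise ValueError(f"bands reference unknown chromosome {chrom!r}")
            length = self._by_name[chrom].length_bp
            prev_end = 0
            for band in blist:
                if band.chrom != chrom:
                    raise ValueError(
                        f"band {band.band_name} filed under {chrom} but labelled {band.chrom}"
                    )
                if band.start_bp < prev_end:
                    raise ValueError(
                        f"chromosome {chrom}: bands unsorted or overlapping at {band.band_name}"
                    )
                if band.end_bp > length:
                    raise ValueError(
                        f"chromosome {chrom}: band {band.band_name} exceeds length {length}"
                    )
                prev_end = band.end_bp

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self.chromosomes)

    def chromosome(self, name: str) -> ChromosomeDef:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no chromosome {name!r} in assembly") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAssembly):
            return NotImplemented
        return self.chromosomes == other.chromosomes and self.bands == other.bands


def normalize_chrom(label: str) -> str | None:
    """Map a user-facing chromosome label onto the canonical bare form.

    Accepts an optional ``chr`` prefix and lower-case x/y. Returns None for
    anything outside chromosomes 1-22, X and Y (mitochondrion, alt contigs,
    random scaffolds ...).
    """
    name = label.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    name = name.upper()
    return name if name in _CHROM_ORDER else None


def parse_cytoband(stream: Iterable[str] | str) -> list[CytoBand]:
    """Parse UCSC cytoBand lines into a sorted band list.

    Each line carries five tab-separated fields: chrom, chromStart,
    chromEnd, name, gieStain. Lines for non-canonical contigs are silently
    skipped. Malformed lines raise :class:`InputFormatError` with the
    offending line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    bands: list[CytoBand] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise InputFormatError(
                f"expected 5 tab-separated fields, got {len(fields)}", line_no
            )
        raw_chrom, raw_start, raw_end, name, raw_stain = fields
        chrom = normalize_chrom(raw_chrom)
        if chrom is None:
            continue
        try:
            start, end = int(raw_start), int(raw_end)
        except ValueError:
            raise InputFormatError(
                f"non-integer coordinates {raw_start!r}/{raw_end!r}", line_no
            ) from None
        try:
            stain = Stain(raw_stain)
        except ValueError:
            raise InputFormatError(f"unknown stain {raw_stain!r}", line_no) from None
        try:
            bands.append(CytoBand(chrom, start, end, name, stain))
        except ValueError as exc:
            raise InputFormatError(str(exc), line_no) from None
    bands.sort(key=lambda b: (_CHROM_ORDER[b.chrom], b.start_bp))
    return bands


def serialize_cytoband(bands: Iterable[CytoBand]) -> str:
    """Write bands back out in the UCSC cytoBand dialect (``chr`` prefix)."""
    return "".join(
        f"chr{b.chrom}\t{b.start_bp}\t{b.end_bp}\t{b.band_name}\t{b.stain.value}\n"
        for b in bands
    )


def load_cytoband(path: str | Path) -> list[CytoBand]:
    """Read a cytoBand file from disk, transparently handling gzip."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        return parse_cytoband(fh)


def build_genome(bands: Iterable[CytoBand]) -> GenomeAssembly:
    """Assemble chromosomes from a band list.

    Chromosome length is the maximum band end; the centromere is the union
    of that chromosome's acen bands. Every chromosome present must carry at
    least one acen band.
    """
    bands = sorted(bands, key=lambda b: (_CHROM_ORDER[b.chrom], b.start_bp))
    if not bands:
        raise ValueError("cannot build a genome from an empty band list")
    per_chrom: dict[str, list[CytoBand]] = {}
    for band in bands:
        per_chrom.setdefault(band.chrom, []).append(band)
    chromosomes = []
    for chrom in CANONICAL_CHROMS:
        if chrom not in per_chrom:
            continue
        blist = per_chrom[chrom]
        length = max(b.end_bp for b in blist)
        acen = [b for b in blist if b.stain is Stain.ACEN]
        if not acen:
            raise ValueError(f"chromosome {chrom} has bands but no acen (centromere) band")
        chromosomes.append(
            ChromosomeDef(
                name=chrom,
                length_bp=length,
                centromere_start_bp=min(b.start_bp for b in acen),
                centromere_end_bp=max(b.end_bp for b in acen),
            )
        )
    return GenomeAssembly(chromosomes, per_chrom)


@lru_cache(maxsize=1)
def _builtin() -> GenomeAssembly:
    try:
        text = (
            resources.files("ideoplot.data")
            .joinpath("hg19_bands_synthetic.txt")
            .read_text()
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise ConfigurationError(
            "bundled band file hg19_bands_synthetic.txt is missing"
        ) from exc
    genome = build_genome(parse_cytoband(text))
    if len(genome) != 24:
        raise ConfigurationError(
            f"bundled band file is corrupt: {len(genome)} chromosomes, expected 24"
        )
    return genome


def builtin_genome() -> GenomeAssembly:
    """The bundled human (hg19-scale) assembly: 24 chromosomes with bands.

    The band table is a synthetic stand-in shipped with the package:
    chromosome lengths, centromere spans, acrocentric stalk bands and the
    large heterochromatin (gvar) blocks follow the published hg19
    coordinates, while the grey-band pattern along the arms is generated
    rather than measured. It is deterministic and identical across calls.
    """
    return _builtin()


def synthetic_genome(n_chrom: int, length_bp: int, seed: int) -> GenomeAssembly:
    """A small reproducible test genome.

    ``n_chrom`` chromosomes (named from the canonical list) of equal
    ``length_bp``, each with a centromere just either side of the midpoint
    and a seeded alternating gneg/gpos band pattern tiling the arms.
    """
    if not (1 <= n_chrom <= 24):
        raise ValueError(f"n_chrom must be in 1..24, got {n_chrom}")
    if length_bp < 20:
        raise ValueError(f"length_bp too small to band: {length_bp}")
    rng = np.random.default_rng(seed)
    gpos = [Stain.GPOS25, Stain.GPOS50, Stain.GPOS75, Stain.GPOS100]
    bands: list[CytoBand] = []
    for ci in range(n_chrom):
        chrom = CANONICAL_CHROMS[ci]
        mid = length_bp // 2
        cen_s = max(1, mid - max(1, length_bp // 20))
        cen_e = min(length_bp, mid + max(1, length_bp // 20))
        for arm, lo, hi in (("p", 0, cen_s), ("q", cen_e, length_bp)):
            n_bands = int(rng.integers(2, 6))
            cuts = np.unique(
                np.concatenate(
                    [[lo, hi], rng.integers(lo + 1, hi, size=n_bands - 1)]
                )
            )
            for i, (a, b) in enumerate(zip(cuts[:-1], cuts[1:])):
                stain = Stain.GNEG if i % 2 == 0 else gpos[int(rng.integers(0, 4))]
                bands.append(CytoBand(chrom, int(a), int(b), f"{arm}{i + 1}", stain))
        bands.append(CytoBand(chrom, cen_s, mid, "p_cen", Stain.ACEN))
        bands.append(CytoBand(chrom, mid, cen_e, "q_cen", Stain.ACEN))
    return build_genome(bands)
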