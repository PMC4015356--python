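"""Parsing of the tab-delimited annotation input file.

One file drives a whole plot. The recognized, case-insensitive headers are

====================  =========  ==================================================
header                required   meaning
====================  =========  ==================================================
CHR                   yes        chromosome (1-22, X, Y; ``chr`` prefix tolerated)
POS                   yes        1-based position, or start of a region
END                   no         1-based inclusive region end
PHENOTYPE             no         phenotype label, drawn as a colored glyph
NOTE / ANNOTATION     no         free text shown beside the chromosome (<= 10 chars)
ETHNICITY / ANCESTRY  no         ancestry group, drawn as a glyph shape (up to 3)
GROUP                 no         group identifier for gradient coloring
POSCOLOR              no         integer 0-7 coloring the transverse mark
====================  =========  ==================================================

Unrecognized columns are ignored with a warning. Invalid rows are fatal,
not skipped: silently dropping data from a plot misleads, so every error
names the offending line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

from .errors import InputFormatError
from .genome import GenomeAssembly, normalize_chrom

__all__ = [
    "NOTE_MAX_CHARS",
    "AnnotationRecord",
    "ParsedInput",
    "parse_input",
    "truncate_note",
    "validate_against_genome",
]

#: Upper bound on NOTE text length; longer notes are truncated.
NOTE_MAX_CHARS = 10

_CANONICAL_HEADERS = {
    "chr": "CHR",
    "pos": "POS",
    "end": "END",
    "phenotype": "PHENOTYPE",
    "note": "NOTE",
    "annotation": "NOTE",
    "ethnicity": "ETHNICITY",
    "ancestry": "ETHNICITY",
    "group": "GROUP",
    "poscolor": "POSCOLOR",
}


@dataclass(frozen=True, slots=True)
class AnnotationRecord:
    """One input row: a genomic point or region plus optional attributes."""

    chrom: str
    pos_bp: int
    end_bp: int | None = None
    phenotype: str | None = None
    note: str | None = None
    ancestry: str | None = None
    group: str | None = None
    poscolor: int | None = None
    line_no: int = 0

    @property
    def is_region(self) -> bool:
        return self.end_bp is not None


@dataclass
class ParsedInput:
    """Records in file order plus which recognized columns were present."""

    records: list[AnnotationRecord]
    present_columns: frozenset[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def phenotypes(self) -> list[str]:
        """Distinct phenotype labels in first-appearance order."""
        return _first_seen(r.phenotype for r in self.records)

    @property
    def ancestries(self) -> list[str]:
        """Distinct ancestry labels in first-appearance order."""
        return _first_seen(r.ancestry for r in self.records)

    @property
    def groups(self) -> dict[str, str]:
        """Phenotype -> group map from rows that carry both."""
        out: dict[str, str] = {}
        for r in self.records:
            if r.phenotype is not None and r.group is not None:
                out.setdefault(r.phenotype, r.group)
        return out


def _first_seen(labels: Iterable[str | None]) -> list[str]:
    seen: dict[str, None] = {}
    for label in labels:
        if label is not None:
            seen.setdefault(label, None)
    return list(seen)


def truncate_note(text: str) -> str:
    """Clip note text to the 10-character display budget (by characters)."""
    return text[:NOTE_MAX_CHARS]


def _parse_int(value: str, what: str, line_no: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise InputFormatError(f"{what} must be an integer, got {value!r}", line_no) from None


def parse_input(stream: Iterable[str] | str) -> ParsedInput:
    """Parse the annotation TSV. The first line must be the header."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = iter(stream)
    try:
        header_line = next(lines)
    except StopIteration:
        raise InputFormatError("empty input: missing header line") from None

    warnings: list[str] = []
    col_of: dict[str, int] = {}
    for idx, raw in enumerate(header_line.rstrip("\r\n").split("\t")):
        name = _CANONICAL_HEADERS.get(raw.strip().lower())
        if name is None:
            warnings.append(f"ignoring unrecognized column {raw.strip()!r}")
            continue
        if name in col_of:
            raise InputFormatError(f"duplicate column {name}", 1)
        col_of[name] = idx
    for required in ("CHR", "POS"):
        if required not in col_of:
            raise InputFormatError(f"missing required column {required}")

    def cell(fields: list[str], name: str) -> str:
        idx = col_of.get(name)
        if idx is None or idx >= len(fields):
            return ""
        return fields[idx].strip()

    records: list[AnnotationRecord] = []
    for line_no, raw in enumerate(lines, start=2):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        fields = line.split("\t")

        chrom = normalize_chrom(cell(fields, "CHR"))
        if chrom is None:
            raise InputFormatError(
                f"unknown chromosome label {cell(fields, 'CHR')!r}", line_no
            )
        pos = _parse_int(cell(fields, "POS"), "POS", line_no)
        if pos < 1:
            raise InputFormatError(f"POS must be >= 1, got {pos}", line_no)

        end: int | None = None
        if cell(fields, "END"):
            end = _parse_int(cell(fields, "END"), "END", line_no)
            if end < pos:
                raise InputFormatError(f"END ({end}) < POS ({pos})", line_no)

        poscolor: int | None = None
        if cell(fields, "POSCOLOR"):
            poscolor = _parse_int(cell(fields, "POSCOLOR"), "POSCOLOR", line_no)
            if not (0 <= poscolor <= 7):
                raise InputFormatError(
                    f"POSCOLOR must be an integer 0-7, got {poscolor}", line_no
                )

        note: str | None = cell(fields, "NOTE") or None
        if note is not None and len(note) > NOTE_MAX_CHARS:
            warnings.append(
                f"line {line_no}: note truncated to {NOTE_MAX_CHARS} characters"
            )
            note = truncate_note(note)

        records.append(
            AnnotationRecord(
                chrom=chrom,
                pos_bp=pos,
                end_bp=end,
                phenotype=cell(fields, "PHENOTYPE") or None,
                note=note,
                ancestry=cell(fields, "ETHNICITY") or None,
                group=cell(fields, "GROUP") or None,
                poscolor=poscolor,
                line_no=line_no,
            )
        )
    return ParsedInput(records, frozenset(col_of), warnings)


def validate_against_genome(
    records: Iterable[AnnotationRecord], genome: GenomeAssembly
) -> list[AnnotationRecord]:
    """Check every record against chromosome bounds; return them unchanged."""
    out = []
    for rec in records:
        if rec.chrom not in genome:
            raise InputFormatError(
                f"chromosome {rec.chrom} not in the genome assembly", rec.line_no
            )
        length = genome.chromosome(rec.chrom).length_bp
        if rec.pos_bp > length:
            raise InputFormatError(
                f"POS {rec.pos_bp} beyond chromosome {rec.chrom} length {length}",
                rec.line_no,
            )
        if rec.end_bp is not None and rec.end_bp > length:
            raise InputFormatError(
                f"END {rec.end_bp} beyond chromosome {rec.chrom} length {length}",
                rec.line_no,
            )
        out.append(rec)
    return out
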