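"""Reproducible synthetic annotation files.

Emulates the kinds of study outputs the plots are built from: GWAS-
catalog-style SNP/phenotype points, array-coverage-style dense line sets,
and CNV-style base-pair regions. Output is tab-delimited text in the
recognized input dialect and always re-parses cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .colors import DEFAULT_SEED
from .genome import GenomeAssembly

__all__ = ["SyntheticStudySpec", "generate_synthetic_input"]


@dataclass
class SyntheticStudySpec:
    """Shape of a synthetic study.

    ``region_fraction`` of records get an END span (CNV-like regions);
    ``note_fraction`` get a short NOTE. Ancestry labels, a phenotype->group
    map and a POSCOLOR fraction switch on the corresponding optional
    columns.
    """

    n_records: int
    phenotype_labels: Sequence[str] = ()
    region_fraction: float = 0.0
    ancestry_labels: Sequence[str] | None = None
    note_fraction: float = 0.0
    group_of: Mapping[str, str] | None = None
    poscolor_fraction: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError(f"n_records must be >= 1, got {self.n_records}")
        for name in ("region_fraction", "note_fraction", "poscolor_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def generate_synthetic_input(spec: SyntheticStudySpec, genome: GenomeAssembly) -> str:
    """Write a seeded, reproducible annotation file for the given genome.

    Positions are uniform within chromosome bounds; phenotypes are drawn
    round-robin so every label appears; regions span 0.2-2% of their
    chromosome.
    """
    rng = np.random.default_rng(spec.seed)
    header = ["CHR", "POS"]
    if spec.phenotype_labels:
        header.append("PHENOTYPE")
    has_end = spec.region_fraction > 0
    if has_end:
        header.append("END")
    if spec.note_fraction > 0:
        header.append("NOTE")
    if spec.ancestry_labels:
        header.append("ETHNICITY")
    if spec.group_of is not None:
        header.append("GROUP")
    if spec.poscolor_fraction > 0:
        header.append("POSCOLOR")

    chrom_names = genome.names
    lines = ["\t".join(header)]
    for i in range(spec.n_records):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        length = genome.chromosome(chrom).length_bp
        row: dict[str, str] = {"CHR": chrom}
        if has_end and rng.random() < spec.region_fraction:
            span = max(1, int(length * rng.uniform(0.002, 0.02)))
            pos = int(rng.integers(1, max(2, length - span)))
            row["POS"] = str(pos)
            row["END"] = str(min(pos + span, length))
        else:
            row["POS"] = str(int(rng.integers(1, length + 1)))
            if has_end:
                row["END"] = ""
        if spec.phenotype_labels:
            phen = spec.phenotype_labels[i % len(spec.phenotype_labels)]
            row["PHENOTYPE"] = phen
            if spec.group_of is not None:
                row["GROUP"] = spec.group_of.get(phen, "other")
        if spec.note_fraction > 0:
            row["NOTE"] = f"loc{i:04d}"[:10] if rng.random() < spec.note_fraction else ""
        if spec.ancestry_labels:
            row["ETHNICITY"] = spec.ancestry_labels[
                int(rng.integers(0, len(spec.ancestry_labels)))
            ]
        if spec.poscolor_fraction > 0:
            row["POSCOLOR"] = (
                str(int(rng.integers(0, 8)))
                if rng.random() < spec.poscolor_fraction
                else ""
            )
        lines.append("\t".join(row.get(h, "") for h in header))
    return "\n".join(lines) + "\n"
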