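"""Genomic interval annotations for HERV loci and host genes.

Coordinates are 0-based half-open internally.  GTF output is converted to
1-based closed, BED output stays 0-based half-open, following the respective
format conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class LocusAnnotation:
    """A single retroviral locus: an interval with a family label."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    family: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"locus {self.locus_id}: start must be < end "
                f"(got [{self.start}, {self.end}))"
            )

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True, order=True)
class GeneAnnotation:
    """A host gene interval."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end "
                f"(got [{self.start}, {self.end}))"
            )

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i}")
        seen.add(i)


def write_bed(features: Iterable[LocusAnnotation | GeneAnnotation], path: str | Path) -> None:
    """Write features as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for f in features:
            name = getattr(f, "locus_id", None) or getattr(f, "gene_id")
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


def write_gtf(
    loci: Iterable[LocusAnnotation] = (),
    genes: Iterable[GeneAnnotation] = (),
    path: str | Path = "annotation.gtf",
) -> None:
    """Write loci and genes as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for l in loci:
            attrs = f'locus_id "{l.locus_id}"; family "{l.family}";'
            fh.write(
                f"{l.chrom}\thervscope\tlocus\t{l.start + 1}\t{l.end}\t.\t{l.strand}\t.\t{attrs}\n"
            )
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\thervscope\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> tuple[list[LocusAnnotation], list[GeneAnnotation]]:
    """Read a GTF file written by :func:`write_gtf` back into annotations."""
    loci: list[LocusAnnotation] = []
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, feat, start, end, _score, strand, _frame, attr_str = (
                line.rstrip("\n").split("\t")
            )
            attrs = dict(_ATTR_RE.findall(attr_str))
            start0, end0 = int(start) - 1, int(end)
            if feat == "locus":
                loci.append(
                    LocusAnnotation(
                        attrs["locus_id"], chrom, start0, end0, strand,
                        attrs.get("family", ""),
                    )
                )
            elif feat == "gene":
                genes.append(
                    GeneAnnotation(
                        attrs["gene_id"], chrom, start0, end0, strand,
                        attrs.get("biotype", "protein_coding"),
                    )
                )
    _check_unique([l.locus_id for l in loci], "locus")
    _check_unique([g.gene_id for g in genes], "gene")
    return loci, genes


def read_bed(path: str | Path, family_from_name: bool = True) -> list[LocusAnnotation]:
    """Read BED6 into loci; family parsed from the name's FAMILY_band convention."""
    from .families import parse_locus_name

    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 else "."
            family = parse_locus_name(name)[0] if family_from_name else ""
            loci.append(LocusAnnotation(name, chrom, start, end, strand, family))
    _check_unique([l.locus_id for l in loci], "locus")
    return loci
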