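"""Genomic annotation layer: intervals, gene models, and super enhancers.

Super enhancers (SEs) are large enhancer clusters taken from a curated BED
catalog.  Because an SE fully embedded in a gene shares its transcriptional
unit with that gene, SE boundaries are optionally extended to the enclosing
gene body: the SE start becomes the minimum start over all embedding genes
and the SE end the maximum end.  After extension, SEs that collapse onto
identical coordinates are merged into a single record.

All coordinates are 0-based half-open throughout the package.  BED input is
read natively; GTF (1-based inclusive) is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

#: Total hg38 genome length in bp, the denominator for genomic length
#: fractions in enrichment statistics.
GENOME_LENGTH_HG38 = 3_088_286_401

INTERGENIC = "intergenic"
PARTIAL_OVERLAP = "partial_overlap"
EMBEDDED = "embedded"
CATEGORIES = (INTERGENIC, PARTIAL_OVERLAP, EMBEDDED)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies fully within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body with identifier and strand ('+', '-', or '.')."""

    gene_id: str
    interval: GenomicInterval
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")


@dataclass
class SuperEnhancer:
    """A super enhancer with its current (possibly extended) interval.

    ``interval`` always contains ``original``; ``category`` records the
    three-way SE-gene overlap classification and ``embedding_gene_ids`` the
    genes that fully contain the original interval (non-empty iff embedded).
    """

    se_id: str
    interval: GenomicInterval
    original: GenomicInterval = None  # type: ignore[assignment]
    category: str | None = None
    embedding_gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.original is None:
            self.original = self.interval
        if not self.interval.contains(self.original):
            raise ValueError(
                f"SE {self.se_id}: interval must contain the original interval"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals (0-based half-open, as in BED).

    The 4th column, when present, is kept as the interval name.  Malformed
    lines raise ValueError naming the offending line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            intervals.append(GenomicInterval(chrom, start, end, name=name))
    return intervals


def read_se_bed(path: str | Path) -> list[SuperEnhancer]:
    """Read a BED file of super enhancers; unnamed records get SE_<i> ids."""
    ses = []
    for i, iv in enumerate(read_bed(path)):
        se_id = iv.name if iv.name is not None else f"SE_{i + 1}"
        base = GenomicInterval(iv.chrom, iv.start, iv.end)
        ses.append(SuperEnhancer(se_id=se_id, interval=base))
    return ses


def _parse_gtf_attributes(attr_block: str, path, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_block.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: unparseable attribute {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GTF file.

    Only rows whose feature type is ``gene`` are kept.  GTF's 1-based
    inclusive coordinates are converted to 0-based half-open on read.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            try:
                start_1based, end_incl = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = _parse_gtf_attributes(fields[8], path, lineno)
            if "gene_id" not in attrs:
                raise ValueError(f"{path}:{lineno}: gene feature lacks gene_id attribute")
            strand = fields[6] if fields[6] in ("+", "-") else "."
            genes.append(
                GeneModel(
                    gene_id=attrs["gene_id"],
                    interval=GenomicInterval(fields[0], start_1based - 1, end_incl),
                    strand=strand,
                )
            )
    return genes


def classify_se(se: SuperEnhancer, genes: Sequence[GeneModel]) -> str:
    """Three-way SE-gene classification on the SE's *original* interval.

    intergenic: no gene overlaps by >= 1 bp; embedded: at least one gene
    fully contains the SE (embedding_gene_ids is populated); partial_overlap
    otherwise.  Strand is ignored.
    """
    overlapping = [g for g in genes if g.interval.overlaps(se.original)]
    embedding = [g.gene_id for g in overlapping if g.interval.contains(se.original)]
    if embedding:
        se.category = EMBEDDED
        se.embedding_gene_ids = embedding
    elif overlapping:
        se.category = PARTIAL_OVERLAP
        se.embedding_gene_ids = []
    else:
        se.category = INTERGENIC
        se.embedding_gene_ids = []
    return se.category


def extend_se_boundaries(
    ses: Iterable[SuperEnhancer], genes: Sequence[GeneModel]
) -> list[SuperEnhancer]:
    """Extend embedded SEs to the span of their embedding genes and collapse.

    For each embedded SE the new start is the minimum start over the genes
    that fully contain it and the new end the maximum end over those genes;
    non-embedded SEs are unchanged.  SEs identical after extension (same
    chromosome, start and end) are collapsed into one record whose id is the
    comma-joined union of the member ids.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    extended: list[SuperEnhancer] = []
    for se in ses:
        if se.category is None:
            classify_se(se, genes)
        if se.category == EMBEDDED:
            embedders = [gene_by_id[gid] for gid in se.embedding_gene_ids]
            new_start = min(min(g.interval.start for g in embedders), se.original.start)
            new_end = max(max(g.interval.end for g in embedders), se.original.end)
            interval = GenomicInterval(se.original.chrom, new_start, new_end)
        else:
            interval = se.original
        extended.append(
            SuperEnhancer(
                se_id=se.se_id,
                interval=interval,
                original=se.original,
                category=se.category,
                embedding_gene_ids=list(se.embedding_gene_ids),
            )
        )

    # Collapse records whose extended coordinates coincide (insertion order kept).
    by_coords: dict[tuple[str, int, int], SuperEnhancer] = {}
    for se in extended:
        key = (se.interval.chrom, se.interval.start, se.interval.end)
        if key in by_coords:
            keep = by_coords[key]
            keep.se_id = f"{keep.se_id},{se.se_id}"
            keep.embedding_gene_ids = sorted(
                set(keep.embedding_gene_ids) | set(se.embedding_gene_ids)
            )
            if se.category == EMBEDDED:
                keep.category = EMBEDDED
            # keep.original stays the first member's original; both are
            # contained in the shared extended interval by construction.
            if not keep.interval.contains(keep.original):  # pragma: no cover
                raise AssertionError("collapse broke the containment invariant")
        else:
            by_coords[key] = se
    return list(by_coords.values())


def write_se_bed(ses: Iterable[SuperEnhancer], path: str | Path) -> None:
    """Write SEs as BED5: chrom, start, end, id, category."""
    with open(path, "w") as fh:
        for se in ses:
            fh.write(
                f"{se.interval.chrom}\t{se.interval.start}\t{se.interval.end}"
                f"\t{se.se_id}\t{se.category or '.'}\n"
            )


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Sum of interval lengths (no overlap merging)."""
    return sum(iv.length for iv in intervals)
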