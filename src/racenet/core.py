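"""Core genomic data model shared by the whole pipeline.

All internal coordinates are 0-based, half-open ``[start, end)``; GFF I/O
converts to and from the 1-based inclusive convention at the boundary
(:mod:`racenet.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "ProjectedExonSet",
    "ExperimentKey",
    "project_exons",
    "meld_intervals",
    "meld_racefrags",
    "covered_bp",
    "interval_gap",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span with optional strand.

    Parameters
    ----------
    chrom : str
        Chromosome / sequence identifier.
    start, end : int
        0-based inclusive start, exclusive end; ``end > start >= 0``.
    strand : str
        One of ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start},{self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Nucleotide gap between nearest edges; 0 if overlapping or book-ended.

    Raises if the intervals sit on different chromosomes.
    """
    if a.chrom != b.chrom:
        raise ValueError("gap undefined across chromosomes")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


@dataclass
class GeneModel:
    """A gene locus with one or more transcripts (exon-interval lists).

    ``coding_spans`` holds the per-transcript CDS intervals (possibly empty
    for non-coding transcripts).
    """

    gene_id: str
    locus: GenomicInterval
    transcripts: list[list[GenomicInterval]]
    coding_spans: list[list[GenomicInterval]] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.coding_spans:
            self.coding_spans = [[] for _ in self.transcripts]
        if len(self.coding_spans) != len(self.transcripts):
            raise ValueError("coding_spans / transcripts length mismatch")
        for exons in self.transcripts:
            prev_end = None
            for ex in sorted(exons, key=lambda e: e.start):
                if not self.locus.contains(ex):
                    raise ValueError(
                        f"{self.gene_id}: exon {ex} outside locus {self.locus}"
                    )
                if prev_end is not None and ex.start < prev_end:
                    raise ValueError(f"{self.gene_id}: overlapping exons in transcript")
                prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.locus.strand

    def exon_union(self) -> list[GenomicInterval]:
        """Merged union of all exons across transcripts (projected exons)."""
        return meld_intervals(ex for tx in self.transcripts for ex in tx)

    def coding_union(self) -> list[GenomicInterval]:
        return meld_intervals(cd for spans in self.coding_spans for cd in spans)


@dataclass
class ProjectedExonSet:
    """Per-gene exon-union segments with positional classes, plus ACEPs.

    ``segments`` are the maximal runs of the exon union; ``classes`` labels
    each segment with a subset of ``{"internal", "most5", "most3"}`` by
    strand-aware order.  ``aceps`` are atomic coding exon projections: the
    coding union split at every annotated exon boundary falling inside it.
    """

    gene_id: str
    segments: list[GenomicInterval]
    classes: list[set[str]]
    aceps: list[GenomicInterval]


@dataclass(frozen=True, order=True)
class ExperimentKey:
    """One hybridization = one primer pool applied to one tissue/sample pool."""

    pool_id: str
    sample_id: str

    def __post_init__(self) -> None:
        if not self.pool_id or not self.sample_id:
            raise ValueError("pool_id and sample_id must be non-empty")


def meld_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals per chromosome.

    Strand is dropped (result is unstranded); output sorted by (chrom, start).
    Idempotent.
    """
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def meld_racefrags(frags: Sequence) -> tuple[list[GenomicInterval], int]:
    """Project RACEfrags from all experiments onto the genome.

    Accepts RACEfrag-like objects (``.interval``) or bare intervals; merges
    any overlapping or book-ended spans and returns ``(projected, covered_bp)``.
    """
    ivs = [getattr(f, "interval", f) for f in frags]
    merged = meld_intervals(ivs)
    return merged, covered_bp(merged)


def covered_bp(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in meld_intervals(intervals))


def project_exons(gene: GeneModel) -> ProjectedExonSet:
    """Project a gene's isoforms onto the genome.

    Segments are the maximal runs of the exon union.  ACEPs split the coding
    union at every annotated exon start/end (from any transcript of this
    gene) falling strictly inside a coding run, so no ACEP straddles an
    annotated exon boundary.  Segment classes are assigned strand-aware: the
    5'-most segment of a ``-`` gene is the rightmost one.
    """
    if not gene.transcripts:
        raise ValueError(f"{gene.gene_id}: gene has no transcripts")
    segments = gene.exon_union()
    n = len(segments)
    classes: list[set[str]] = [set() for _ in range(n)]
    if n:
        i5, i3 = (0, n - 1) if gene.strand != "-" else (n - 1, 0)
        classes[i5].add("most5")
        classes[i3].add("most3")
        for i in range(n):
            if i not in (i5, i3):
                classes[i].add("internal")

    boundaries = sorted(
        {b for tx in gene.transcripts for ex in tx for b in (ex.start, ex.end)}
    )
    aceps: list[GenomicInterval] = []
    for run in gene.coding_union():
        cuts = [run.start] + [b for b in boundaries if run.start < b < run.end]
        cuts.append(run.end)
        for a, b in zip(cuts, cuts[1:]):
            aceps.append(GenomicInterval(run.chrom, a, b))
    return ProjectedExonSet(gene.gene_id, segments, classes, aceps)
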