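"""Gene-anatomy segments derived from gene models.

All coordinates are 0-based half-open (BED convention). A gene model is a
single transcript (when annotation carries several isoforms the longest one
is used, see :mod:`chipdeg.io`). From each model up to 16 named segments are
derived, strand-aware:

``TSS1500``, ``TSS200``       promoter windows upstream of the TSS
``TSSplus200``                first 200 bp downstream of the TSS
``TTS200``                    200 bp downstream of the TTS
``UTR5``, ``UTR3``            untranslated exonic regions (require CDS)
``first_exon`` .. ``last_exon``   exon/intron anatomy in transcription order
``single_exon``, ``single_intron`` populated only for 1-exon / 1-intron genes
``full_transcript``           union of exons
``full_gene``                 exons plus introns as one interval
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from chipdeg.util import clip_interval

Interval = tuple[int, int]

#: canonical column/output order of segment kinds
SEGMENT_KINDS: tuple[str, ...] = (
    "TSS1500",
    "TSS200",
    "TSSplus200",
    "TTS200",
    "UTR5",
    "UTR3",
    "first_exon",
    "first_intron",
    "exon_body",
    "intron_body",
    "last_intron",
    "last_exon",
    "single_exon",
    "single_intron",
    "full_transcript",
    "full_gene",
)


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene/transcript.

    ``exons`` are non-overlapping, coordinate-sorted 0-based half-open
    intervals on a single chromosome. ``cds_start``/``cds_end`` (genomic,
    strand-independent, ``cds_start < cds_end``) delimit the coding region
    when known; without them UTR segments are reported as missing.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    exons: tuple[Interval, ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError(f"gene {self.gene_id}: exon list is empty")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: empty exon [{s}, {e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
        object.__setattr__(self, "exons", exons)
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")
        if self.cds_start is not None and self.cds_end <= self.cds_start:
            raise ValueError("cds_end must be greater than cds_start")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site (genomic coordinate)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Transcription termination site (genomic coordinate)."""
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )


@dataclass
class SegmentSet:
    """Named segments of one gene; absent segments are simply not present."""

    gene_id: str
    chromosome: str
    strand: str
    segments: dict[str, tuple[Interval, ...]] = field(default_factory=dict)

    def intervals(self, kind: str) -> Optional[tuple[Interval, ...]]:
        return self.segments.get(kind)

    def length(self, kind: str) -> Optional[int]:
        ivs = self.segments.get(kind)
        if ivs is None:
            return None
        return sum(e - s for s, e in ivs)

    def __contains__(self, kind: str) -> bool:
        return kind in self.segments


def _exonic_overlap(exons: Iterable[Interval], lo: int, hi: int) -> tuple[Interval, ...]:
    out = []
    for s, e in exons:
        cs, ce = max(s, lo), min(e, hi)
        if ce > cs:
            out.append((cs, ce))
    return tuple(out)


def extract_segments(gene: GeneModel, chromosome_length: int) -> SegmentSet:
    """Derive the named segments of ``gene``, clipped to ``[0, chromosome_length)``.

    Promoter/terminator windows are strand-mirrored; exon/intron anatomy is
    indexed in transcription order (on the minus strand the first exon is the
    rightmost one). Segments that are empty after clipping, or undefined for
    the gene (e.g. introns of a single-exon gene, UTRs without CDS), are
    recorded as missing rather than zero-length.
    """
    if chromosome_length < gene.end:
        raise ValueError(
            f"chromosome_length {chromosome_length} < gene end {gene.end}"
        )
    segs: dict[str, tuple[Interval, ...]] = {}

    def put(kind: str, *intervals: Interval) -> None:
        clipped = [clip_interval(s, e, 0, chromosome_length) for s, e in intervals]
        clipped = [(s, e) for s, e in clipped if e > s]
        if clipped:
            segs[kind] = tuple(clipped)

    tss, tts = gene.tss, gene.tts
    if gene.strand == "+":
        put("TSS1500", (tss - 1500, tss))
        put("TSS200", (tss - 200, tss))
        put("TSSplus200", (tss, tss + 200))
        put("TTS200", (tts, tts + 200))
    else:
        put("TSS1500", (tss, tss + 1500))
        put("TSS200", (tss, tss + 200))
        put("TSSplus200", (tss - 200, tss))
        put("TTS200", (tts - 200, tts))

    exons = gene.exons
    introns = gene.introns
    tx_exons = exons if gene.strand == "+" else exons[::-1]
    tx_introns = introns if gene.strand == "+" else introns[::-1]

    put("first_exon", tx_exons[0])
    put("last_exon", tx_exons[-1])
    if len(exons) == 1:
        put("single_exon", exons[0])
    if len(exons) >= 3:
        body = tx_exons[1:-1]
        put("exon_body", *sorted(body))

    if introns:
        put("first_intron", tx_introns[0])
        put("last_intron", tx_introns[-1])
        if len(introns) == 1:
            put("single_intron", introns[0])
        if len(introns) >= 3:
            put("intron_body", *sorted(tx_introns[1:-1]))

    if gene.cds_start is not None:
        if gene.strand == "+":
            utr5 = _exonic_overlap(exons, gene.start, gene.cds_start)
            utr3 = _exonic_overlap(exons, gene.cds_end, gene.end)
        else:
            utr5 = _exonic_overlap(exons, gene.cds_end, gene.end)
            utr3 = _exonic_overlap(exons, gene.start, gene.cds_start)
        if utr5:
            put("UTR5", *utr5)
        if utr3:
            put("UTR3", *utr3)

    put("full_transcript", *exons)
    put("full_gene", (gene.start, gene.end))
    return SegmentSet(gene.gene_id, gene.chromosome, gene.strand, segs)


def extract_all_segments(
    genes: Iterable[GeneModel], chromosome_lengths: Mapping[str, int]
) -> dict[str, SegmentSet]:
    """Segment sets for a collection of genes, keyed by gene_id."""
    out: dict[str, SegmentSet] = {}
    for gene in genes:
        if gene.gene_id in out:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        out[gene.gene_id] = extract_segments(
            gene, chromosome_lengths[gene.chromosome]
        )
    return out


def gene_intervals(genes: Iterable[GeneModel]) -> dict[str, tuple[str, int, int]]:
    """``gene_id -> (chromosome, start, end)`` over the full gene span."""
    return {g.gene_id: (g.chromosome, g.start, g.end) for g in genes}
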