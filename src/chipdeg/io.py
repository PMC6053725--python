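"""Readers and writers for the standard formats the pipeline consumes.

Gene models: GFF3 / GTF (1-based closed on disk, converted to 0-based
half-open in memory) and BED12. Reads: 6-column BED. Peaks: ENCODE
narrowPeak. Expression / labels: TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from chipdeg.segments import GeneModel, SegmentSet, SEGMENT_KINDS


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_bed12(path: str | os.PathLike) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"malformed BED12 line for {name}")
            exons = tuple(
                (start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            )
            cds = (
                (thick_start, thick_end)
                if thick_end > thick_start
                else (None, None)
            )
            gene_id, _, tx = name.partition("|")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=tx or gene_id + ".1",
                    chromosome=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=cds[0],
                    cds_end=cds[1],
                )
            )
            if exons[-1][1] != end:
                raise ValueError(f"BED12 blocks do not span chromEnd for {name}")
    return genes


def write_bed12(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, e in g.exons)
            thick = (
                (g.cds_start, g.cds_end)
                if g.cds_start is not None
                else (g.start, g.start)
            )
            fh.write(
                "\t".join(
                    (
                        g.chromosome,
                        str(g.start),
                        str(g.end),
                        f"{g.gene_id}|{g.transcript_id}",
                        "0",
                        g.strand,
                        str(thick[0]),
                        str(thick[1]),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    )
                )
                + "\n"
            )


def write_gff3(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:

            def row(ftype: str, s: int, e: int, attrs: str) -> str:
                return "\t".join(
                    (
                        g.chromosome,
                        "chipdeg",
                        ftype,
                        str(s + 1),  # GFF3 is 1-based closed
                        str(e),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    )
                )

            fh.write(row("gene", g.start, g.end, f"ID={g.gene_id}") + "\n")
            fh.write(
                row(
                    "mRNA",
                    g.start,
                    g.end,
                    f"ID={g.transcript_id};Parent={g.gene_id}",
                )
                + "\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    row(
                        "exon",
                        s,
                        e,
                        f"ID={g.transcript_id}.exon{i};Parent={g.transcript_id}",
                    )
                    + "\n"
                )
            if g.cds_start is not None:
                for i, (s, e) in enumerate(g.exons, 1):
                    cs, ce = max(s, g.cds_start), min(e, g.cds_end)
                    if ce > cs:
                        fh.write(
                            row(
                                "CDS",
                                cs,
                                ce,
                                f"ID={g.transcript_id}.cds{i};Parent={g.transcript_id}",
                            )
                            + "\n"
                        )


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3.

    One transcript per gene is kept: the one with the largest total exon
    length (ties broken by transcript_id).
    """
    return _read_gff_like(path, gtf=False)


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    return _read_gff_like(path, gtf=True)


def _read_gff_like(path: str | os.PathLike, gtf: bool) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=not gtf,
        disable_infer_transcripts=not gtf,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        if not transcripts:
            transcripts = [gene]
        scored = []
        for t in transcripts:
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(t, featuretype="exon")
            )
            if not exons:
                exons = [(t.start - 1, t.end)]
            cds = sorted(
                (f.start - 1, f.end) for f in db.children(t, featuretype="CDS")
            )
            scored.append((-sum(e - s for s, e in exons), t.id, exons, cds))
        scored.sort()
        _, tid, exons, cds = scored[0]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                transcript_id=tid,
                chromosome=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                cds_start=cds[0][0] if cds else None,
                cds_end=cds[-1][1] if cds else None,
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return genes


def read_annotation(path: str | os.PathLike) -> list[GeneModel]:
    """Dispatch on extension: .bed/.bed12 -> BED12, .gtf -> GTF, else GFF3."""
    name = str(path).lower()
    if name.endswith((".bed", ".bed12")):
        return read_bed12(path)
    if name.endswith(".gtf"):
        return read_gtf(path)
    return read_gff3(path)


# ---------------------------------------------------------------------------
# reads (BED intervals)
# ---------------------------------------------------------------------------

@dataclass
class ReadTrack:
    """Aligned-read intervals of one track, indexed for overlap counting.

    Stores, per chromosome, the sorted start and end coordinates. A read
    overlaps segment ``[s, e)`` iff ``start < e and end > s`` (>= 1 bp,
    bedtools-multicov semantics), so the overlap count is
    ``#(starts < e) - #(ends <= s)``.
    """

    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    total: int

    @classmethod
    def from_intervals(
        cls, chroms: Sequence[str], starts: Sequence[int], ends: Sequence[int]
    ) -> "ReadTrack":
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        s_by: dict[str, np.ndarray] = {}
        e_by: dict[str, np.ndarray] = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            s_by[str(chrom)] = np.sort(grp["start"].to_numpy(dtype=np.int64))
            e_by[str(chrom)] = np.sort(grp["end"].to_numpy(dtype=np.int64))
        return cls(starts=s_by, ends=e_by, total=len(df))

    @classmethod
    def from_bed(cls, path: str | os.PathLike) -> "ReadTrack":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            comment="#",
        )
        return cls.from_intervals(df["chrom"], df["start"], df["end"])

    @property
    def chromosomes(self) -> set[str]:
        return set(self.starts)

    def count(self, chrom: str, start: int, end: int) -> int:
        """Number of reads overlapping ``[start, end)`` by >= 1 bp."""
        if chrom not in self.starts or end <= start:
            return 0
        n_start_before_end = int(
            np.searchsorted(self.starts[chrom], end, side="left")
        )
        n_end_at_or_before_start = int(
            np.searchsorted(self.ends[chrom], start, side="right")
        )
        return n_start_before_end - n_end_at_or_before_start


def write_reads_bed(
    path: str | os.PathLike,
    chroms: Sequence[str],
    starts: Sequence[int],
    ends: Sequence[int],
) -> None:
    with open(path, "w") as fh:
        for i, (c, s, e) in enumerate(zip(chroms, starts, ends)):
            fh.write(f"{c}\t{s}\t{e}\tread{i}\t0\t+\n")


# ---------------------------------------------------------------------------
# peaks (narrowPeak)
# ---------------------------------------------------------------------------

def read_narrowpeak(path: str | os.PathLike):
    """Read ENCODE narrowPeak; returns a list of :class:`chipdeg.peaks.Peak`."""
    from chipdeg.peaks import Peak

    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            peaks.append(
                Peak(
                    chromosome=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    name=f[3] if len(f) > 3 else ".",
                    fold_enrichment=float(f[6]) if len(f) > 6 else 1.0,
                )
            )
    return peaks


def write_narrowpeak(peaks, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chromosome}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                f"{p.fold_enrichment:.5f}\t-1\t-1\t-1\n"
            )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Expression TSV with columns ``gene_id`` and ``rpkm_rep{i}_{cond}``."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene_id")


def write_expression(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="gene_id", float_format="%.6g")


def read_label_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("gene_id")


def write_label_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="gene_id", float_format="%.6g")


def write_segments_bed(
    segment_sets: Iterable[SegmentSet], path: str | os.PathLike
) -> None:
    """Per-gene segment table as BED with name ``{gene_id}|{segment_kind}``."""
    rows = []
    for ss in segment_sets:
        for kind in SEGMENT_KINDS:
            ivs = ss.intervals(kind)
            if ivs is None:
                continue
            for s, e in ivs:
                rows.append((ss.chromosome, s, e, f"{ss.gene_id}|{kind}", ss.strand))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, s, e, name, strand in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t{strand}\n")
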