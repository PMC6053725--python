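"""Normalized read signal over gene segments and the named feature matrix.

Feature naming follows the ``{genotype}{mark}{quantity}_{segment}`` scheme,
e.g. ``CK9A_UTR5`` (wild-type H3K9Ac density in air over the 5' UTR),
``CK9diff_UTR5`` (scaled difference between conditions) and
``CK9log2FC_UTR5`` (log2 fold change between conditions).
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from chipdeg.io import ReadTrack
from chipdeg.segments import SEGMENT_KINDS, SegmentSet

#: differential quantity tags appended after the condition-specific ones
DIFF_QUANTITIES = ("diff", "log2FC")

DEFAULT_PSEUDOCOUNT = 1e-3


def count_reads(track: ReadTrack, chrom: str, start: int, end: int) -> int:
    """Reads overlapping ``[start, end)`` by >= 1 bp (multicov semantics).

    A chromosome absent from the track yields 0, not an error.
    """
    return track.count(chrom, start, end)


def normalize_density(
    count: int, segment_length: int, total_reads: int
) -> Optional[float]:
    """Reads per kilobase of segment per million track reads.

    Returns None (missing) for zero-length segments.
    """
    if segment_length <= 0:
        return None
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return count / ((segment_length / 1000.0) * (total_reads / 1e6))


def diff_metric(x_air: float, x_eth: float) -> float:
    """Difference scaled by the mean: ``(eth - air) / ((eth + air) / 2)``.

    Bounded in [-2, 2]; defined as 0 when both inputs are 0.
    """
    if x_air < 0 or x_eth < 0:
        raise ValueError("diff_metric inputs must be nonnegative")
    if x_air == 0 and x_eth == 0:
        return 0.0
    return (x_eth - x_air) / ((x_eth + x_air) / 2.0)


def log2fc(x_air: float, x_eth: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """``log2((eth + pseudocount) / (air + pseudocount))``."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return math.log2((x_eth + pseudocount) / (x_air + pseudocount))


def build_feature_name(
    genotype: str,
    mark: str,
    quantity: str,
    segment: str,
    genotypes: Sequence[str],
    marks: Sequence[str],
    conditions: Sequence[str],
) -> str:
    """Validate vocabulary entries and return ``{genotype}{mark}{quantity}_{segment}``."""
    if genotype not in genotypes:
        raise ValueError(f"unknown genotype {genotype!r}")
    if mark not in marks:
        raise ValueError(f"unknown mark {mark!r}")
    if quantity not in tuple(conditions) + DIFF_QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}")
    if segment not in SEGMENT_KINDS:
        raise ValueError(f"unknown segment kind {segment!r}")
    return f"{genotype}{mark}{quantity}_{segment}"


def segment_feature_columns(
    genotypes: Sequence[str],
    marks: Sequence[str],
    conditions: Sequence[str],
    segment_kinds: Sequence[str] = SEGMENT_KINDS,
) -> list[str]:
    """Deterministic column order of the segment feature matrix."""
    cols = []
    for g in genotypes:
        for m in marks:
            for q in tuple(conditions) + DIFF_QUANTITIES:
                for seg in segment_kinds:
                    cols.append(f"{g}{m}{q}_{seg}")
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate feature names in the configured schema")
    return cols


def build_segment_feature_matrix(
    tracks: Mapping[tuple[str, str, str], ReadTrack],
    segment_sets: Mapping[str, SegmentSet],
    genotypes: Sequence[str],
    marks: Sequence[str],
    conditions: Sequence[str],
    segment_kinds: Sequence[str] = SEGMENT_KINDS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Genes x named features: per-condition densities plus diff and log2FC.

    ``tracks`` maps ``(genotype, mark, condition)`` to a :class:`ReadTrack`;
    both conditions of every genotype x mark pair must be present. Missing
    segments (and genes whose chromosome is absent from both condition
    tracks of a pair) yield missing values; such genes remain as rows.
    """
    if len(conditions) != 2:
        raise ValueError("exactly two conditions are required")
    cond_a, cond_c = conditions
    columns = segment_feature_columns(genotypes, marks, conditions, segment_kinds)
    gene_ids = sorted(segment_sets)
    data = np.full((len(gene_ids), len(columns)), np.nan)
    col_index = {name: j for j, name in enumerate(columns)}

    for g in genotypes:
        for m in marks:
            try:
                track_a = tracks[(g, m, cond_a)]
                track_c = tracks[(g, m, cond_c)]
            except KeyError as exc:
                raise KeyError(f"missing track for genotype={g} mark={m}") from exc
            for i, gid in enumerate(gene_ids):
                ss = segment_sets[gid]
                chrom = ss.chromosome
                if (
                    chrom not in track_a.chromosomes
                    and chrom not in track_c.chromosomes
                ):
                    continue  # gene absent from this track pair -> missing
                for seg in segment_kinds:
                    ivs = ss.intervals(seg)
                    if ivs is None:
                        continue
                    length = sum(e - s for s, e in ivs)
                    cnt_a = sum(track_a.count(chrom, s, e) for s, e in ivs)
                    cnt_c = sum(track_c.count(chrom, s, e) for s, e in ivs)
                    da = normalize_density(cnt_a, length, track_a.total)
                    dc = normalize_density(cnt_c, length, track_c.total)
                    if da is None or dc is None:
                        continue
                    data[i, col_index[f"{g}{m}{cond_a}_{seg}"]] = da
                    data[i, col_index[f"{g}{m}{cond_c}_{seg}"]] = dc
                    data[i, col_index[f"{g}{m}diff_{seg}"]] = diff_metric(da, dc)
                    data[i, col_index[f"{g}{m}log2FC_{seg}"]] = log2fc(
                        da, dc, pseudocount
                    )
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"), columns=columns)


def impute_missing(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Missing -> 0 (absent segments carry "no signal" semantics).

    Returns the imputed matrix and a per-column missingness fraction report.
    """
    report = matrix.isna().mean(axis=0)
    return matrix.fillna(0.0), report
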