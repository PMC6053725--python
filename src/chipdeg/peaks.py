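"""Peak-derived gene features and differential (M-value) peaks.

Peaks are assigned to the nearest gene within 5 kb of the peak region; from
the assignment four per-gene features are computed per track: number of
peaks, average peak size, average fold enrichment and average distance.
Differential peaks between the two conditions are selected by the M value
(log2 density ratio) after a median-M rescaling of the second condition,
with a conditional binomial test for equality of the two counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from chipdeg.io import ReadTrack

logger = logging.getLogger(__name__)

PEAK_FEATURE_PREFIXES = ("numberpeaks", "avg_peaksize", "avg_FE", "avg_distance")


@dataclass(frozen=True)
class Peak:
    """One called peak; densities are filled in for differential analysis."""

    chromosome: str
    start: int
    end: int
    name: str = "."
    fold_enrichment: float = 1.0
    density_air: Optional[float] = None
    density_eth: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty peak interval [{self.start}, {self.end})")
        if self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be positive")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DifferentialPeak:
    peak: Peak
    m: float
    p_value: float


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Distance between two half-open intervals; 0 when they overlap."""
    return max(0, b_start - a_end, a_start - b_end)


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    gene_intervals: Mapping[str, tuple[str, int, int]],
    max_distance: int = 5000,
) -> dict[str, list[tuple[Peak, int]]]:
    """Assign each peak to the single nearest gene within ``max_distance`` bp.

    Distance is the gap between the peak and the full-gene interval (0 when
    overlapping); equidistant genes are broken by lexicographically smallest
    gene_id. Peaks with no gene within range are logged and dropped.
    """
    by_chrom: dict[str, tuple[list[str], np.ndarray, np.ndarray]] = {}
    for gid in sorted(gene_intervals):
        chrom, s, e = gene_intervals[gid]
        by_chrom.setdefault(chrom, ([], [], []))  # type: ignore[arg-type]
        by_chrom[chrom][0].append(gid)
        by_chrom[chrom][1].append(s)  # type: ignore[union-attr]
        by_chrom[chrom][2].append(e)  # type: ignore[union-attr]
    indexed = {
        chrom: (ids, np.asarray(ss, dtype=np.int64), np.asarray(ee, dtype=np.int64))
        for chrom, (ids, ss, ee) in by_chrom.items()
    }

    assignment: dict[str, list[tuple[Peak, int]]] = {}
    n_unassigned = 0
    for peak in peaks:
        entry = indexed.get(peak.chromosome)
        if entry is None:
            n_unassigned += 1
            continue
        ids, starts, ends = entry
        gaps = np.maximum(0, np.maximum(starts - peak.end, peak.start - ends))
        best = int(gaps.min())
        if best > max_distance:
            n_unassigned += 1
            continue
        # tie-break: ids are sorted, argmin returns the first (smallest id)
        gid = ids[int(np.argmin(gaps))]
        assignment.setdefault(gid, []).append((peak, best))
    if n_unassigned:
        logger.info("%d peaks had no gene within %d bp", n_unassigned, max_distance)
    return assignment


def peak_gene_features(
    assignment: Mapping[str, Sequence[tuple[Peak, int]]],
    track_label: str,
    fold_enrichments: Optional[Mapping[Peak, float]] = None,
) -> pd.DataFrame:
    """Per-gene ``numberpeaks/avg_peaksize/avg_FE/avg_distance`` features.

    Column names carry the track label, e.g. ``numberpeaks_CK9A``. Genes
    with no assigned peaks are absent (missing when merged into the matrix).
    """
    rows = {}
    for gid, items in assignment.items():
        sizes = [p.size for p, _ in items]
        fes = [
            fold_enrichments[p] if fold_enrichments is not None else p.fold_enrichment
            for p, _ in items
        ]
        dists = [d for _, d in items]
        rows[gid] = (
            len(items),
            float(np.mean(sizes)),
            float(np.mean(fes)),
            float(np.mean(dists)),
        )
    df = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=[f"{p}_{track_label}" for p in PEAK_FEATURE_PREFIXES],
    )
    df.index.name = "gene_id"
    return df.sort_index()


def m_value(density_eth: float, density_air: float) -> float:
    """``log2(density_eth / density_air)``; inputs must be positive."""
    if density_eth <= 0 or density_air <= 0:
        raise ValueError("m_value requires positive densities")
    return math.log2(density_eth / density_air)


def normalize_densities(peaks: Sequence[Peak]) -> tuple[list[Peak], float]:
    """Rescale condition-2 (ethylene) densities so the median M over common
    peaks is exactly 0.

    Common peaks are those with positive density in both conditions. With no
    common peaks the factor is 1 and a warning is logged.
    """
    ms = [
        m_value(p.density_eth, p.density_air)
        for p in peaks
        if p.density_air and p.density_eth and p.density_air > 0 and p.density_eth > 0
    ]
    if not ms:
        logger.warning("no common peaks; density normalization skipped")
        factor = 1.0
    else:
        factor = 2.0 ** (-float(np.median(ms)))
    rescaled = [
        replace(p, density_eth=(p.density_eth * factor if p.density_eth is not None else None))
        for p in peaks
    ]
    return rescaled, factor


def call_differential_peaks(
    peaks: Sequence[Peak],
    m_threshold: float = 0.4,
    p_threshold: float = 0.05,
    pseudocount: float = 0.5,
) -> list[DifferentialPeak]:
    """Keep peaks with ``|M| >= m_threshold`` and binomial ``p <= p_threshold``.

    M is the log2 ratio of the (normalized) densities; ``pseudocount`` is
    added to both densities only when either is zero. The p-value is the
    two-sided conditional binomial test that the two rounded counts come
    from equal Poisson means.
    """
    out: list[DifferentialPeak] = []
    for p in peaks:
        if p.density_air is None or p.density_eth is None:
            continue
        a, c = p.density_air, p.density_eth
        if min(a, c) <= 0:
            a, c = a + pseudocount, c + pseudocount
        m = m_value(c, a)
        if abs(m) < m_threshold:
            continue
        k = int(round(p.density_eth))
        n = k + int(round(p.density_air))
        if n == 0:
            continue
        pval = float(stats.binomtest(k, n, 0.5).pvalue)
        if pval <= p_threshold:
            out.append(DifferentialPeak(peak=p, m=m, p_value=pval))
    return out


def differential_peak_gene_features(
    differential_peaks: Sequence[DifferentialPeak],
    gene_intervals: Mapping[str, tuple[str, int, int]],
    track_label: str,
    max_distance: int = 5000,
) -> pd.DataFrame:
    """Per-gene features over differential peaks (label e.g. ``CK9diff``).

    ``avg_FE`` here is the mean ethylene-vs-air enrichment ``2**M`` over the
    gene's differential peaks.
    """
    by_peak = {dp.peak: 2.0 ** dp.m for dp in differential_peaks}
    assignment = assign_peaks_to_genes(
        [dp.peak for dp in differential_peaks], gene_intervals, max_distance
    )
    return peak_gene_features(assignment, track_label, fold_enrichments=by_peak)


def merge_condition_peaks(
    peaks_air: Sequence[Peak],
    peaks_eth: Sequence[Peak],
    reads_air: ReadTrack,
    reads_eth: ReadTrack,
) -> list[Peak]:
    """Union-merge peak regions of the two conditions and attach per-region
    read counts as densities (count scale; the median-M rescaling makes the
    two conditions comparable)."""
    intervals = sorted(
        [(p.chromosome, p.start, p.end) for p in peaks_air]
        + [(p.chromosome, p.start, p.end) for p in peaks_eth]
    )
    merged: list[list] = []
    for chrom, s, e in intervals:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([chrom, s, e])
    out = []
    for i, (chrom, s, e) in enumerate(merged):
        out.append(
            Peak(
                chromosome=chrom,
                start=s,
                end=e,
                name=f"region{i}",
                fold_enrichment=1.0,
                density_air=float(reads_air.count(chrom, s, e)),
                density_eth=float(reads_eth.count(chrom, s, e)),
            )
        )
    return out
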