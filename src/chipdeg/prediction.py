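"""Probability-ranked candidate selection and evaluation.

Candidate genes are ranked by class-probability estimate (the probability of
the predicted class), grouped into fixed-size bins, and the selection keeps
the longest prefix of bins whose cumulative precision against the known
labels stays at or above the threshold (0.95 by default) — so the selected
set size is always a whole multiple of the bin size, or the full list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def rank_and_bin(
    prob_up: Mapping[str, float] | pd.Series,
    bin_size: int = 200,
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Sort genes by max-class probability (descending, ties by gene_id) and
    cut into consecutive bins of ``bin_size`` (last bin may be smaller).

    Returns the ranked table (columns ``prob_up``, ``probability``,
    ``direction``, ``bin``) and the list of bins as gene-id lists.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    series = pd.Series(dict(prob_up) if not isinstance(prob_up, pd.Series) else prob_up)
    if series.empty:
        raise ValueError("no genes to rank")
    df = pd.DataFrame({"prob_up": series})
    df.index.name = "gene_id"
    df["direction"] = np.where(df["prob_up"] >= 0.5, "up", "down")
    df["probability"] = np.maximum(df["prob_up"], 1.0 - df["prob_up"])
    order = sorted(range(len(df)), key=lambda i: (-df["probability"].iloc[i], df.index[i]))
    df = df.iloc[order]
    df["bin"] = np.arange(len(df)) // bin_size
    bins = [list(grp.index) for _, grp in df.groupby("bin", sort=True)]
    return df, bins


def bin_precision(
    ranked: pd.DataFrame,
    bins: Sequence[Sequence[str]],
    known_labels: Mapping[str, str],
) -> pd.DataFrame:
    """Per-bin and cumulative direction-match precision among known genes.

    Precision of a bin = matched / known over the known-labeled genes in that
    bin; bins with no known genes have missing precision and leave the
    cumulative value unchanged. Matched and known counts are emitted so
    alternative definitions can be recomputed downstream.
    """
    direction = ranked["direction"]
    rows = []
    cum_known = cum_match = 0
    for b, gene_bin in enumerate(bins):
        known_in_bin = [g for g in gene_bin if g in known_labels]
        matched = sum(1 for g in known_in_bin if direction[g] == known_labels[g])
        cum_known += len(known_in_bin)
        cum_match += matched
        rows.append(
            {
                "bin": b,
                "size": len(gene_bin),
                "n_known": len(known_in_bin),
                "n_matched": matched,
                "precision": matched / len(known_in_bin) if known_in_bin else np.nan,
                "cum_known": cum_known,
                "cum_matched": cum_match,
                "cum_precision": cum_match / cum_known if cum_known else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def precision_cutoff(
    bins: Sequence[Sequence[str]],
    bin_stats: pd.DataFrame,
    threshold: float = 0.95,
) -> list[str]:
    """Genes of the longest bin prefix with cumulative precision >= threshold.

    The selected set is a union of whole bins. An empty selection (first
    informative bin already below threshold) is returned with a warning.
    """
    cum = bin_stats["cum_precision"]
    last_ok = -1
    for b in range(len(bins)):
        value = cum.iloc[b]
        if not np.isnan(value) and value >= threshold:
            last_ok = b
    selected: list[str] = []
    for b in range(last_ok + 1):
        selected.extend(bins[b])
    if not selected:
        logger.warning("no bin prefix reaches cumulative precision %.3f", threshold)
    return selected


def direction_agreement(
    predicted: Mapping[str, str],
    evaluation: Mapping[str, str],
) -> tuple[int, int]:
    """(TP, FP) of predicted directions against an evaluation label set.

    Genes absent from the evaluation set contribute to neither count.
    """
    tp = fp = 0
    for gid, direction in predicted.items():
        truth = evaluation.get(gid)
        if truth is None or truth == "none":
            continue
        if direction == truth:
            tp += 1
        else:
            fp += 1
    return tp, fp


def overlap_test(
    selected_size: int,
    overlap: int,
    known_size: int,
    population_size: int,
) -> float:
    """Hypergeometric upper-tail p-value ``P(X >= overlap)``."""
    if not (0 <= overlap <= min(selected_size, known_size)):
        raise ValueError("overlap exceeds the selected or known set size")
    if max(selected_size, known_size) > population_size:
        raise ValueError("set sizes exceed the population")
    return float(
        stats.hypergeom.sf(overlap - 1, population_size, known_size, selected_size)
    )


@dataclass
class PredictionReport:
    """Ranked predictions plus the precision-based selection and evaluation."""

    ranked: pd.DataFrame
    bin_size: int
    bin_stats: pd.DataFrame
    selected: list[str]
    threshold: float
    tp: Optional[int] = None
    fp: Optional[int] = None
    overlap_p_value: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def selected_cum_precision(self) -> Optional[float]:
        """Cumulative precision at the last selected bin (None if nothing
        selected or no known gene fell in the selected prefix)."""
        if not self.selected:
            return None
        sizes = self.bin_stats["size"].cumsum()
        b = int(np.searchsorted(sizes.to_numpy(), len(self.selected)))
        value = self.bin_stats["cum_precision"].iloc[b]
        return None if np.isnan(value) else float(value)

    def summary(self) -> dict:
        out = {
            "n_candidates": int(len(self.ranked)),
            "bin_size": self.bin_size,
            "precision_threshold": self.threshold,
            "n_selected": len(self.selected),
            "selected_cum_precision": self.selected_cum_precision(),
        }
        if self.tp is not None:
            out["tp"] = self.tp
            out["fp"] = self.fp
        if self.overlap_p_value is not None:
            out["overlap_p_value"] = self.overlap_p_value
        out.update(self.extras)
        return out


def build_prediction_report(
    prob_up: Mapping[str, float] | pd.Series,
    known_labels: Mapping[str, str],
    bin_size: int = 200,
    threshold: float = 0.95,
    evaluation_labels: Optional[Mapping[str, str]] = None,
    population_size: Optional[int] = None,
) -> PredictionReport:
    """Rank, bin, cut at the precision threshold and (optionally) evaluate."""
    ranked, bins = rank_and_bin(prob_up, bin_size)
    stats_df = bin_precision(ranked, bins, known_labels)
    selected = precision_cutoff(bins, stats_df, threshold)
    report = PredictionReport(
        ranked=ranked,
        bin_size=bin_size,
        bin_stats=stats_df,
        selected=selected,
        threshold=threshold,
    )
    if evaluation_labels is not None and selected:
        pred_dirs = {g: ranked["direction"][g] for g in selected}
        report.tp, report.fp = direction_agreement(pred_dirs, evaluation_labels)
    if population_size is not None and selected:
        known_in_pop = [g for g in known_labels if known_labels[g] != "none"]
        overlap = len(set(selected) & set(known_in_pop))
        report.overlap_p_value = overlap_test(
            len(selected), overlap, len(known_in_pop), population_size
        )
        report.extras["overlap"] = overlap
        report.extras["known_size"] = len(known_in_pop)
    return report
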