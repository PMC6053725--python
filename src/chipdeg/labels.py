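"""DEG labels and candidate pools from per-condition RPKM tables.

A gene is labeled ``up`` when the ethylene/air fold change of the condition
means exceeds the threshold (1.5 by default), ``down`` for the reciprocal,
and ``none`` otherwise; in either direction the larger condition mean must
exceed the expression floor (RPKM > 1 by default, interpretation of "RPKM
value larger than 1" as the max over the two condition means).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from chipdeg.util import round_half_up

LABELS = ("up", "down", "none")


def condition_means(
    expression: pd.DataFrame, conditions: Sequence[str] = ("A", "C")
) -> pd.DataFrame:
    """Mean RPKM per condition from ``rpkm_rep{i}_{cond}`` columns."""
    out = {}
    for cond in conditions:
        cols = [c for c in expression.columns if c.endswith(f"_{cond}")]
        if not cols:
            raise ValueError(f"no replicate columns found for condition {cond!r}")
        out[cond] = expression[cols].mean(axis=1)
    return pd.DataFrame(out)


def call_degs(
    expression: pd.DataFrame,
    conditions: Sequence[str] = ("A", "C"),
    fc_threshold: float = 1.5,
    rpkm_threshold: float = 1.0,
) -> pd.DataFrame:
    """Label genes up/down/none by fold change and expression floor.

    Returns a DataFrame indexed by gene_id with columns ``label`` and
    ``fold_change`` (ethylene/air ratio of condition means; inf when the
    air mean is 0 and the ethylene mean positive, 1.0 when both are 0).
    """
    means = condition_means(expression, conditions)
    cond_a, cond_c = conditions
    a = means[cond_a].to_numpy(dtype=float)
    c = means[cond_c].to_numpy(dtype=float)
    both_zero = (a == 0) & (c == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(both_zero, 1.0, np.where(a == 0, np.inf, c / np.where(a == 0, 1.0, a)))
        rfc = np.where(both_zero, 1.0, np.where(c == 0, np.inf, a / np.where(c == 0, 1.0, c)))
    expressed = np.maximum(a, c) > rpkm_threshold
    up = expressed & (fc > fc_threshold)
    down = expressed & (rfc > fc_threshold)
    label = np.where(up, "up", np.where(down, "down", "none"))
    return pd.DataFrame(
        {"label": label, "fold_change": fc}, index=expression.index
    )


def replicate_correlation(
    rep1: Sequence[float],
    rep2: Sequence[float],
    pseudocount: float = 1e-3,
    log_transform: bool = True,
) -> Optional[float]:
    """Pearson r between ``log2(RPKM + pseudocount)`` replicate vectors.

    With ``log_transform=False`` the inputs are taken to be on the log2
    scale already. Returns None when either vector has zero variance.
    """
    if log_transform:
        x = np.log2(np.asarray(rep1, dtype=float) + pseudocount)
        y = np.log2(np.asarray(rep2, dtype=float) + pseudocount)
    else:
        x = np.asarray(rep1, dtype=float)
        y = np.asarray(rep2, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 genes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def select_top_expressed(
    expression: pd.DataFrame,
    fraction: float = 0.60,
    conditions: Sequence[str] = ("A", "C"),
) -> list[str]:
    """Top ``round(fraction * N)`` genes by max condition-mean RPKM.

    Ties (including at the cutoff) are broken by gene_id, so the returned
    set is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    means = condition_means(expression, conditions)
    score = means.max(axis=1)
    order = sorted(score.index, key=lambda gid: (-score[gid], gid))
    n = round_half_up(fraction * len(order))
    return order[:n]


def abs_fc_filter(deg_table: pd.DataFrame, min_abs_fc: float = 4.0) -> pd.DataFrame:
    """Genes whose fold change exceeds ``min_abs_fc`` in either direction.

    ``deg_table`` is the output of :func:`call_degs`; infinite fold changes
    (expression in one condition only) are retained.
    """
    fc = deg_table["fold_change"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        mag = np.where(fc == 0, math.inf, np.maximum(fc, 1.0 / fc))
    return deg_table.loc[mag > min_abs_fc]
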