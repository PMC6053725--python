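"""Supervised discretization of continuous features.

Implements recursive entropy minimization with the minimum-description-length
stopping criterion (Fayyad & Irani style), the default binning behind the
information-gain and correlation-based selectors. An equal-frequency fallback
is available for degenerate cases where no cut is accepted but a binning is
still required.
"""

from __future__ import annotations

import numpy as np


def entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _row_entropy(count_rows: np.ndarray) -> np.ndarray:
    """Entropy in bits of each row of a counts matrix."""
    totals = count_rows.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, count_rows / totals, 0.0)
        logp = np.where(p > 0, np.log2(p), 0.0)
    return -(p * logp).sum(axis=1)


def mdl_cut_points(values, labels) -> list[float]:
    """Cut points accepted by recursive entropy minimization with MDL stop.

    Returns a sorted list of thresholds (possibly empty); a value ``x`` falls
    in bin ``searchsorted(cuts, x, side='right')``.
    """
    values = np.asarray(values, dtype=float)
    _, y = np.unique(np.asarray(labels), return_inverse=True)
    if values.shape != y.shape:
        raise ValueError("values and labels must have the same length")
    n = len(values)
    k_total = y.max() + 1 if n else 0
    if n < 2 or k_total < 2:
        return []

    order = np.argsort(values, kind="mergesort")
    v = values[order]
    ys = y[order]
    # cumulative class counts: cum[i] = counts among the first i items
    cum = np.zeros((n + 1, k_total), dtype=np.int64)
    np.add.at(cum, (np.arange(1, n + 1), ys), 1)
    cum = np.cumsum(cum, axis=0)

    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        size = hi - lo
        if size < 2:
            return
        # candidate boundaries: positions where the value changes
        cand = np.arange(lo + 1, hi)[v[lo + 1 : hi] != v[lo : hi - 1]]
        if cand.size == 0:
            return
        total_counts = cum[hi] - cum[lo]
        h_s = entropy_bits(total_counts)
        left = cum[cand] - cum[lo]
        right = total_counts - left
        n1 = left.sum(axis=1)
        n2 = right.sum(axis=1)
        h1 = _row_entropy(left)
        h2 = _row_entropy(right)
        weighted = (n1 * h1 + n2 * h2) / size
        best = int(np.argmin(weighted))
        gain = h_s - weighted[best]
        k = int((total_counts > 0).sum())
        k1 = int((left[best] > 0).sum())
        k2 = int((right[best] > 0).sum())
        delta = np.log2(3.0**k - 2.0) - (
            k * h_s - k1 * h1[best] - k2 * h2[best]
        )
        threshold = (np.log2(size - 1) + delta) / size
        if gain <= threshold:
            return
        i = int(cand[best])
        cuts.append(float((v[i - 1] + v[i]) / 2.0))
        recurse(lo, i)
        recurse(i, hi)

    recurse(0, n)
    return sorted(cuts)


def equal_frequency_cuts(values, bins: int = 10) -> list[float]:
    """Interior quantile cut points (duplicates collapsed)."""
    values = np.asarray(values, dtype=float)
    qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    return sorted(set(float(q) for q in qs))


def discretize_values(values, labels, fallback_bins: int | None = None) -> np.ndarray:
    """Integer bin codes from MDL cuts.

    When MDL accepts no cut the feature collapses to a single bin (code 0),
    which makes its information gain exactly 0; with ``fallback_bins`` set an
    equal-frequency binning is used instead in that degenerate case.
    """
    values = np.asarray(values, dtype=float)
    cuts = mdl_cut_points(values, labels)
    if not cuts and fallback_bins:
        cuts = equal_frequency_cuts(values, fallback_bins)
    return np.searchsorted(np.asarray(cuts), values, side="right")
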