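"""Firing-rate and connectivity readouts.

The connectivity of a population (or an ordered pair of populations) is the
normalized synapse count

    Gamma = (1 / (|P| * |Q|)) * sum_{i in Q, j in P} A[i, j]

with presynaptic group P (columns) and postsynaptic group Q (rows).  For a
single group of size n this is the (1/n^2) * sum(A) readout used for the
engram, with the structurally-zero diagonal included in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RateSeries", "population_rate", "block_connectivity",
    "engram_partition_metrics", "final_value", "rank_compare",
]


@dataclass
class RateSeries:
    """Mean firing rate of one group per contiguous recording window."""
    rates_hz: np.ndarray
    edges_s: np.ndarray      # (n_windows, 2) start/stop


def population_rate(spikes, group, t_start: float, t_stop: float,
                    window_s: float = 5.0) -> RateSeries:
    """Group-averaged firing rate per recording window.

    ``spikes`` is a :class:`hspsim.network.SpikeRecord` (or anything with
    ``ids``/``times``).  Each neuron's spike count per window is divided by
    the window length and averaged over the group.
    """
    group = np.asarray(group)
    if group.size == 0:
        raise ValueError("group must not be empty")
    n_win = int(round((t_stop - t_start) / window_s))
    edges = t_start + window_s * np.arange(n_win + 1)
    sel = np.isin(spikes.ids, group)
    t = np.asarray(spikes.times)[sel]
    t = t[(t > t_start) & (t <= t_stop)]
    counts, _ = np.histogram(t, bins=edges)
    rates = counts / (window_s * group.size)
    return RateSeries(rates, np.column_stack([edges[:-1], edges[1:]]))


def block_connectivity(A: np.ndarray, pre_group, post_group) -> float:
    """Normalized synapse count from ``pre_group`` onto ``post_group``."""
    pre = np.asarray(pre_group)
    post = np.asarray(post_group)
    if pre.size == 0 or post.size == 0:
        raise ValueError("groups must not be empty")
    if pre.max() >= A.shape[1] or post.max() >= A.shape[0]:
        raise ValueError("group ids exceed matrix bounds")
    block = A[np.ix_(post, pre)]
    return float(block.sum()) / (pre.size * post.size)


def engram_partition_metrics(A: np.ndarray, partition: dict) -> pd.DataFrame:
    """All ordered-pair block connectivities over a disjoint E partition.

    ``partition`` maps group names (engram_overlap, engram_rest, dc_only,
    background_E, ...) to id arrays; empty groups are omitted.  Returns a
    tidy frame with columns (pre, post, gamma).  The within-engram sub-block
    pattern (overlap-overlap / overlap-rest / rest-rest) used to assess
    engram distortion is the subset of rows with engram groups on both axes.
    """
    groups = {k: np.asarray(v) for k, v in partition.items() if len(v)}
    all_ids = np.concatenate(list(groups.values())) if groups else np.empty(0)
    if np.unique(all_ids).size != all_ids.size:
        raise ValueError("partition groups must be disjoint")
    rows = [
        {"pre": p, "post": q,
         "gamma": block_connectivity(A, groups[p], groups[q])}
        for p in groups for q in groups
    ]
    return pd.DataFrame(rows)


def final_value(series, n_windows: int = 10) -> float:
    """Mean of the trailing readouts of a time series (fluctuation smoothing)."""
    series = np.asarray(series)
    return float(series[-n_windows:].mean())


def rank_compare(x, y, alternative: str = "greater"):
    """One-sided Mann-Whitney rank test between two seed samples.

    Returns (statistic, p-value); ``alternative='greater'`` tests whether
    values in ``x`` tend to exceed those in ``y``.
    """
    return stats.mannwhitneyu(x, y, alternative=alternative)
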