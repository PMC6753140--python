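"""Interval arithmetic on sorted, non-overlapping, 0-based half-open intervals.

All genomic tables in this package (domains, windows, gene models) are kept
sorted and non-overlapping per chromosome, so membership and gap queries
reduce to ``numpy.searchsorted`` over the start/end arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def validate_sorted_nonoverlapping(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` unless intervals are sorted and disjoint per chromosome."""
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"empty or inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if not np.all(np.diff(starts) >= 0):
            raise ValueError(f"intervals not sorted on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping intervals on {chrom}")


def points_in_intervals(
    pos: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Index of the interval containing each point, or -1.

    ``starts``/``ends`` must be sorted and non-overlapping; a point belongs to
    ``[start, end)``.
    """
    pos = np.asarray(pos)
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
    return np.where(inside, idx, -1)


def overlap_lengths(
    q_start: int, q_end: int, starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of intervals overlapping ``[q_start, q_end)`` and the overlap bp."""
    lo = np.searchsorted(ends, q_start, side="right")
    hi = np.searchsorted(starts, q_end, side="left")
    idx = np.arange(lo, hi)
    if idx.size == 0:
        return idx, np.zeros(0, dtype=np.int64)
    ov = np.minimum(ends[idx], q_end) - np.maximum(starts[idx], q_start)
    keep = ov > 0
    return idx[keep], ov[keep]


def gap_to_nearest(
    q_start: int, q_end: int, starts: np.ndarray, ends: np.ndarray
) -> float:
    """Minimum gap in bp between ``[q_start, q_end)`` and any interval (0 if touching/overlapping)."""
    if starts.size == 0:
        return np.inf
    i = np.searchsorted(ends, q_start, side="right")  # intervals[i:] end after q_start
    best = np.inf
    if i < starts.size:
        if starts[i] < q_end:  # its end > q_start by construction => overlap
            return 0.0
        best = float(starts[i] - q_end)
    if i > 0:
        best = min(best, float(q_start - ends[i - 1]))
    return float(max(best, 0.0))
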