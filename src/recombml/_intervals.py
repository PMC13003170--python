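"""Low-level interval arithmetic on numpy arrays.

All coordinates are 0-based half-open. These kernels back the coverage and
CO-assignment operations; they are deliberately dependency-free so that they
can be checked against per-base boolean-mask oracles in the tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["merge_intervals", "subtract_intervals", "distribute_to_bins"]


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of a set of intervals: sorted, non-overlapping, non-adjacent-merged."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, s.size):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def subtract_intervals(
    starts: np.ndarray, ends: np.ndarray, mask_starts: np.ndarray, mask_ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Remove ``mask`` regions from the (already merged) ``starts/ends`` set.

    Used for cross-type trimming: e.g. removing gene-overlapping stretches
    from TE intervals before computing TE coverage.
    """
    ms, me = merge_intervals(mask_starts, mask_ends)
    out_s: list[int] = []
    out_e: list[int] = []
    j = 0
    for s, e in zip(starts, ends):
        cur = int(s)
        while j < ms.size and me[j] <= cur:
            j += 1
        k = j
        while cur < e:
            if k >= ms.size or ms[k] >= e:
                out_s.append(cur)
                out_e.append(int(e))
                break
            if ms[k] > cur:
                out_s.append(cur)
                out_e.append(int(ms[k]))
            cur = int(me[k])
            k += 1
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def distribute_to_bins(
    starts: np.ndarray,
    ends: np.ndarray,
    weights: np.ndarray,
    bin_width: int,
    n_bins: int,
) -> np.ndarray:
    """Spread each interval over the fixed-width bins it overlaps.

    Interval ``i`` adds ``weights[i] * overlap(i, b) / len(i)`` to bin ``b``;
    with unit weights the contributions of one interval sum to exactly 1 as
    long as the interval lies within the binned range. Vectorized over
    intervals by looping over the (small) maximum bin span.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.float64)
    out = np.zeros(n_bins, dtype=np.float64)
    if starts.size == 0:
        return out
    lengths = (ends - starts).astype(np.float64)
    if np.any(lengths <= 0):
        raise ValueError("intervals must satisfy start < end")
    first = starts // bin_width
    last = (ends - 1) // bin_width
    max_span = int((last - first).max()) + 1
    for k in range(max_span):
        b = first + k
        live = b <= last
        if not live.any():
            break
        b_live = b[live]
        lo = np.maximum(starts[live], b_live * bin_width)
        hi = np.minimum(ends[live], (b_live + 1) * bin_width)
        frac = (hi - lo) / lengths[live]
        np.add.at(out, np.minimum(b_live, n_bins - 1), weights[live] * frac)
    return out
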