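"""Dataset partitioning.

The splitter allocates ``floor(n * ratio)`` items to each partition and
assigns every remainder item to the first (training) partition.  With
7,256 items at 7:2:1 this yields (5,080, 1,451, 725): plain floor gives
(5079, 1451, 725) and the single leftover goes to train — neither plain
floor nor largest-remainder rounding reproduces that triple.
"""

from __future__ import annotations

import numpy as np

__all__ = ["split_counts", "split_dataset"]


def split_counts(n: int, ratios) -> tuple[int, ...]:
    """Partition sizes under the floor + remainder-to-train rule."""
    ratios = tuple(float(r) for r in ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    if any(r < 0 for r in ratios):
        raise ValueError("ratios must be non-negative")
    counts = [int(np.floor(n * r)) for r in ratios]
    counts[0] += n - sum(counts)
    return tuple(counts)


def split_dataset(ids, ratios, seed: int | None = None, shuffle: bool = True):
    """Split ``ids`` into disjoint partitions covering the whole list.

    A seeded shuffle precedes allocation (deterministic given the seed);
    partition sizes follow :func:`split_counts`.
    """
    ids = list(ids)
    counts = split_counts(len(ids), ratios)
    if shuffle:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(ids))
        ids = [ids[i] for i in order]
    parts = []
    start = 0
    for c in counts:
        parts.append(ids[start : start + c])
        start += c
    return parts
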