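"""Computed ABC analysis: data-driven categorization of positive items.

Items are sorted by decreasing value and the cumulative-contribution curve
(effort x_i = i/n against yield y_i = cumulative share) is partitioned into
the "important few" (subset A), an intermediate subset B and the "trivial
many" (subset C):

* the A|B boundary is the curve point closest to the ideal point (0, 1) —
  maximal yield at minimal effort;
* the B|C boundary is the first subsequent point whose discrete slope drops
  to the break-even rate of 1 (an item contributing no more than the
  average item), clipped to n - 1 when no such point exists.

Ties in the sort are broken by original position (stable sort) and
zero-valued items always land in C, so the partition is deterministic and
invariant to positive rescaling of the values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ABCPartition", "abc_partition", "abc_plot_data"]


@dataclass(frozen=True)
class ABCPartition:
    """Ordered three-way partition of positive items.

    ``order`` holds the original indices sorted by decreasing value;
    ``x``/``y`` are the cumulative-curve coordinates (one point per sorted
    item); ``ab_index``/``bc_index`` are 1-based boundary positions on the
    sorted axis; ``a``/``b``/``c`` are original indices of the subsets.
    """

    values: np.ndarray
    order: np.ndarray
    x: np.ndarray
    y: np.ndarray
    ab_index: int
    bc_index: int
    a: tuple
    b: tuple
    c: tuple
    labels: tuple | None = None

    def subset_labels(self, subset: str) -> list:
        idx = {"A": self.a, "B": self.b, "C": self.c}[subset]
        if self.labels is None:
            return list(idx)
        return [self.labels[i] for i in idx]


def abc_partition(values, labels=None) -> ABCPartition:
    """Partition non-negative item values into subsets A, B and C."""
    vals = np.asarray(values, float)
    if vals.ndim != 1 or vals.size < 3:
        raise ValueError("need a 1-D collection of at least 3 items")
    if np.isnan(vals).any():
        raise ValueError("missing values not allowed")
    if (vals < 0).any():
        raise ValueError("negative item values not allowed")
    if not (vals > 0).any():
        raise ValueError("at least one item must be strictly positive")
    if labels is not None and len(labels) != vals.size:
        raise ValueError("labels length mismatch")

    n = vals.size
    order = np.argsort(-vals, kind="stable")
    sorted_vals = vals[order]
    total = sorted_vals.sum()
    y = np.cumsum(sorted_vals) / total
    x = np.arange(1, n + 1) / n

    dist = np.sqrt(x**2 + (1.0 - y) ** 2)
    # first minimum wins ties; a relative tolerance keeps the tie rule
    # stable under rescaling of the input values
    ab_index = int(np.flatnonzero(dist <= dist.min() * (1 + 1e-9))[0]) + 1

    # Discrete slope of point i is n * value_i / total; break even at 1.
    slopes = sorted_vals * n / total
    after = np.flatnonzero(slopes[ab_index:] <= 1.0 + 1e-9)
    bc_index = int(after[0]) + ab_index + 1 if after.size else n - 1
    bc_index = max(bc_index, ab_index)

    a = list(order[:ab_index])
    b = list(order[ab_index:bc_index])
    c = list(order[bc_index:])
    # Zero-valued items are never informative: force them into C.
    zeros_a = [i for i in a if vals[i] == 0]
    zeros_b = [i for i in b if vals[i] == 0]
    a = [i for i in a if vals[i] > 0]
    b = [i for i in b if vals[i] > 0]
    c = zeros_a + zeros_b + c
    return ABCPartition(values=vals, order=order, x=x, y=y,
                        ab_index=ab_index, bc_index=bc_index,
                        a=tuple(a), b=tuple(b), c=tuple(c),
                        labels=tuple(labels) if labels is not None else None)


def abc_plot_data(partition: ABCPartition) -> pd.DataFrame:
    """Cumulative-curve rows (x, y, subset) for plotting or serialization."""
    n = partition.x.size
    subset = np.empty(n, dtype=object)
    pos_of = {int(idx): k for k, idx in enumerate(partition.order)}
    for name, members in (("A", partition.a), ("B", partition.b), ("C", partition.c)):
        for idx in members:
            subset[pos_of[int(idx)]] = name
    return pd.DataFrame({"x": partition.x, "y": partition.y, "subset": subset})
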