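"""Seeded train/test splitting, optionally grouped by animal.

Real recordings contain several images of each physical bird; letting
them straddle the split leaks appearance information from train to test.
When group identifiers are provided, whole groups are assigned to one
side, approximating the requested train fraction as closely as the group
sizes allow.
"""

from __future__ import annotations

import numpy as np

__all__ = ["train_test_split"]


def train_test_split(
    n: int,
    train_fraction: float = 0.7,
    seed: int = 0,
    groups=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split record indices 0..n-1 into (train, test) index arrays.

    Without groups: a seeded shuffle followed by a ``floor(n·fraction)``
    cut.  With groups: unique group labels are shuffled and whole groups
    are moved to the training side until it holds at least the target
    number of records, so no group is ever split across sides.  The two
    sides are disjoint and exhaustive.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    target = int(n * train_fraction + 1e-9)
    target = min(max(target, 1), n - 1)
    if groups is None:
        perm = rng.permutation(n)
        return np.sort(perm[:target]), np.sort(perm[target:])
    groups = np.asarray(groups)
    if len(groups) != n:
        raise ValueError("groups must have one label per record")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups to split by group")
    order = rng.permutation(len(uniq))
    train_mask = np.zeros(n, dtype=bool)
    taken = 0
    for g in uniq[order]:
        if taken >= target:
            break
        sel = groups == g
        # never let the test side become empty
        if taken + int(sel.sum()) >= n:
            continue
        train_mask |= sel
        taken += int(sel.sum())
    if taken == 0:  # first group alone exceeded n-1; take the smallest group
        sizes = [(int((groups == g).sum()), g) for g in uniq]
        _, g = min(sizes)
        train_mask = groups == g
    idx = np.arange(n)
    return idx[train_mask], idx[~train_mask]
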