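"""Neighbor-joining tree construction and rooting utilities.

Classical NJ (Saitou & Nei) with the Studier-Keppler criterion: at each
step join the pair (i, j) minimizing

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

Branch lengths follow the standard formulas; negative estimates are clamped
to zero (UniFrac requires nonnegative lengths).  Ties in Q are broken by
the lowest (row, column) position in the current matrix, so the tree is
deterministic.  The unrooted result is midpoint-rooted by default, the
convention used before feeding trees to UniFrac when no outgroup is
available.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from .distances import DistanceMatrix

__all__ = ["neighbor_joining", "midpoint_root"]


def neighbor_joining(dm: DistanceMatrix, root: bool = True) -> TreeNode:
    """Build an NJ tree from a distance matrix (>= 3 labels, no sentinels).

    With ``root=True`` (default) the unrooted tree is midpoint-rooted.
    """
    if len(dm) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dm.has_undefined:
        raise ValueError(
            f"distance matrix contains undefined pairs: {dm.undefined_pairs()[:5]}"
        )
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) among minima, row-major
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((n - 1, n - 1))
        d2[: n - 2, : n - 2] = d[np.ix_(keep, keep)]
        d2[n - 2, : n - 2] = d2[: n - 2, n - 2] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final three lineages as a star (exact closed form)
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lens = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    for node, ln in zip(nodes, lens):
        node.length = max(ln, 0.0)
    tree = TreeNode(children=list(nodes))
    tree.length = None
    return midpoint_root(tree) if root else tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest tip-to-tip path."""
    rooted = tree.root_at_midpoint()
    rooted.length = None
    return rooted
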