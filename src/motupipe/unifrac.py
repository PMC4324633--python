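"""Unweighted UniFrac between samples on a rooted tree.

For two samples a and b, unweighted UniFrac is the fraction of the branch
length leading to tips of a or b that is *unique* to one of the two
samples:

    U(a, b) = (branch length subtending tips of exactly one sample)
              / (branch length subtending tips of either sample)

Branches subtending no tip of a or b are ignored, and branches above the
lowest common ancestor of the present tips are excluded from numerator and
denominator alike (they subtend every present tip, carrying no contrast).
If the samples split at the basal-most node U = 1; if every lineage is
shared U = 0.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence, Set

import numpy as np
from skbio import TreeNode

from .distances import DistanceMatrix

__all__ = ["TipIncidence", "unweighted_unifrac_pair", "unifrac_matrix"]

#: mapping tip id -> set of sample ids containing it
TipIncidence = Mapping[str, Set[str]]


def _validate(tree: TreeNode, inc: TipIncidence) -> None:
    for tip in tree.tips():
        if tip.name not in inc:
            raise KeyError(f"tip {tip.name!r} missing from incidence")
        if tip.length is None:
            raise ValueError(f"tip {tip.name!r} has no branch length")
    for node in tree.non_tips(include_self=False):
        if node.length is None:
            raise ValueError("internal node without branch length")


def unweighted_unifrac_pair(
    tree: TreeNode, inc: TipIncidence, a: str, b: str, validate: bool = True
) -> float:
    """Unweighted UniFrac distance between samples ``a`` and ``b`` in [0, 1]."""
    if validate:
        _validate(tree, inc)
    # postorder: for each node, whether its subtree holds a tip of a / of b
    state: dict[int, tuple[bool, bool]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            samples = inc[node.name]
            state[id(node)] = (a in samples, b in samples)
        else:
            ia = ib = False
            for child in node.children:
                ca, cb = state[id(child)]
                ia |= ca
                ib |= cb
            state[id(node)] = (ia, ib)
    root_a, root_b = state[id(tree)]
    if not (root_a or root_b):
        raise ValueError(f"samples {a!r} and {b!r} contain no tips of this tree")
    # LCA of all present tips: deepest node containing every present tip
    lca = tree
    while True:
        present_children = [
            c for c in lca.children if state[id(c)][0] or state[id(c)][1]
        ]
        if len(present_children) == 1 and not present_children[0].is_tip():
            lca = present_children[0]
        else:
            break
    unique = total = 0.0
    for node in lca.postorder(include_self=False):
        ia, ib = state[id(node)]
        if not (ia or ib):
            continue
        length = node.length or 0.0
        total += length
        if ia != ib:
            unique += length
    if total == 0.0:
        return 0.0
    return unique / total


def unifrac_matrix(
    tree: TreeNode, inc: TipIncidence, samples: Sequence[str]
) -> DistanceMatrix:
    """Pairwise unweighted UniFrac over ``samples``.

    Samples containing no tips are dropped with a warning.
    """
    _validate(tree, inc)
    present = set()
    for tips in inc.values():
        present |= set(tips)
    kept = [s for s in samples if s in present]
    dropped = [s for s in samples if s not in present]
    if dropped:
        warnings.warn(f"samples with zero tips dropped from UniFrac: {dropped}")
    if len(kept) < 2:
        raise ValueError("need at least 2 non-empty samples")
    n = len(kept)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            u = unweighted_unifrac_pair(tree, inc, kept[i], kept[j], validate=False)
            vals[i, j] = vals[j, i] = u
    return DistanceMatrix(kept, vals, metric_name="unweighted_unifrac")
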