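"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's dynamic programming and tree
traversal code paths: alignment scores come from exhaustive enumeration of
monotone matchings, Dollo states from explicit path unions, and tree
generation from a direct leaf-insertion construction.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def _gap_cost(g: int, open_: float, extend: float) -> float:
    return 0.0 if g == 0 else open_ + (g - 1) * extend


def brute_force_align(a: str, b: str, mode: str = "local",
                      open_: float = 11.0, extend: float = 1.0) -> float:
    """Optimal affine-gap alignment score by enumerating monotone matchings.

    A matching is a set of aligned residue pairs (i1<i2<..., j1<j2<...).
    Unmatched residues between consecutive pairs form one gap run per
    sequence, each charged open + (len-1)*extend; in local mode residues
    outside the matched span are free and the empty matching scores 0.
    """
    la, lb = len(a), len(b)
    best = 0.0 if mode == "local" else -np.inf
    if mode == "global":
        best = -(_gap_cost(la, open_, extend) + _gap_cost(lb, open_, extend))
    for k in range(1, min(la, lb) + 1):
        for ii in combinations(range(la), k):
            for jj in combinations(range(lb), k):
                s = 0.0
                for x, y in zip(ii, jj):
                    s += _B62[a[x], b[y]]
                for t in range(1, k):
                    s -= _gap_cost(ii[t] - ii[t - 1] - 1, open_, extend)
                    s -= _gap_cost(jj[t] - jj[t - 1] - 1, open_, extend)
                if mode == "global":
                    s -= _gap_cost(ii[0], open_, extend) + _gap_cost(jj[0], open_, extend)
                    s -= _gap_cost(la - 1 - ii[-1], open_, extend)
                    s -= _gap_cost(lb - 1 - jj[-1], open_, extend)
                if s > best:
                    best = s
    return float(best)


def dollo_oracle(tree, bearers) -> set:
    """Dollo state as the explicit union of focal-to-bearer paths."""
    focal = tree.focal_leaf
    state = {focal}
    for b in bearers:
        if b == focal:
            continue
        state |= set(tree.path(focal, b))
    return state


def all_rooted_binary_trees(leaves):
    """Every rooted binary labeled tree over the given leaves, as Newick."""
    leaves = list(leaves)

    def build(nested):
        if isinstance(nested, str):
            return nested
        return f"({build(nested[0])},{build(nested[1])})"

    def grow(tree, leaf):
        # insert `leaf` on every edge, including above the current root
        yield (tree, leaf)
        if not isinstance(tree, str):
            left, right = tree
            for t in grow(left, leaf):
                yield (t, right)
            for t in grow(right, leaf):
                yield (left, t)

    trees = [leaves[0]]
    for leaf in leaves[1:]:
        trees = [t2 for t in trees for t2 in grow(t, leaf)]
    return [build(t) + ";" for t in trees]
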