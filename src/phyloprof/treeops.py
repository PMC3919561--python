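"""Rooted species trees, taxon metadata and MRCA/path primitives.

The pipeline works on a rooted (possibly multifurcating) species tree with a
designated *focal leaf* — the species whose protein inventory seeds every
search.  All dating is topological: ancestral nodes are identified, not
calibrated in time, and branch lengths present in the input are accepted but
ignored.  Internal nodes keep their Newick labels when given; unlabeled nodes
receive deterministic post-order ids (``N1``, ``N2``, ...) so that repeated
runs on the same input name the same nodes.

Taxon metadata maps every leaf to a genus, a supertaxon (a monophyletic group
of species summarized as one unit) and a domain of life.  Supertaxon
monophyly is validated at load time; a violation is a hard error.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "SpeciesTree",
    "parse_newick",
    "read_taxon_meta",
    "validate_tree_meta",
    "collapse_to_supertaxa",
    "taxa_by_distance",
]

DOMAINS_OF_LIFE = ("eukaryote", "archaeon", "bacterium")
META_COLUMNS = ("taxon_id", "genus", "supertaxon", "domain_of_life")


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Tree/metadata inconsistency (duplicate leaves, non-monophyly, ...)."""


@dataclass
class SpeciesTree:
    """A rooted tree held as parent/children maps over string node ids.

    Leaf ids are taxon ids.  ``focal_leaf`` names the query species and may
    be unset for trees used purely as topologies.
    """

    parent: dict = field(default_factory=dict)   # node -> parent (root -> None)
    children: dict = field(default_factory=dict)  # node -> ordered list
    root: str = ""
    focal_leaf: str | None = None
    auto_ids: set = field(default_factory=set)   # generated internal ids, not written out
    _depth: dict = field(default_factory=dict, repr=False)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_maps(cls, parent: Mapping[str, str | None], children: Mapping[str, Sequence[str]],
                  root: str, focal_leaf: str | None = None,
                  auto_ids: set | None = None) -> "SpeciesTree":
        t = cls(dict(parent), {k: list(v) for k, v in children.items()}, root,
                focal_leaf, set(auto_ids or ()))
        t._validate()
        return t

    def _validate(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1 or roots[0] != self.root:
            raise TreeValidationError("tree must have exactly one root")
        if self.focal_leaf is not None:
            if self.focal_leaf not in self.parent or not self.is_leaf(self.focal_leaf):
                raise TreeValidationError(f"focal leaf {self.focal_leaf!r} is not a leaf")
        # cycle check via depth computation
        self._depth = {}
        self.depth(self.root)
        for n in self.parent:
            self.depth(n)

    # -- basic queries -----------------------------------------------------

    @property
    def nodes(self) -> list:
        return list(self.parent)

    @property
    def leaves(self) -> list:
        return [n for n in self.parent if not self.children.get(n)]

    def is_leaf(self, node: str) -> bool:
        self._check(node)
        return not self.children.get(node)

    def _check(self, node: str) -> None:
        if node not in self.parent:
            raise KeyError(f"unknown node {node!r}")

    def depth(self, node: str) -> int:
        """Number of edges from the root (root has depth 0)."""
        self._check(node)
        d = self._depth.get(node)
        if d is not None:
            return d
        chain = []
        n = node
        while n is not None and n not in self._depth:
            chain.append(n)
            if len(chain) > len(self.parent):
                raise TreeValidationError("cycle detected in parent map")
            n = self.parent[n]
        base = -1 if n is None else self._depth[n]
        for m in reversed(chain):
            base += 1
            self._depth[m] = base
        return self._depth[node]

    def root_path(self, node: str) -> list:
        """Nodes from ``node`` up to and including the root."""
        self._check(node)
        out = [node]
        while self.parent[out[-1]] is not None:
            out.append(self.parent[out[-1]])
        return out

    def mrca(self, nodes: Iterable[str]) -> str:
        """Most recent common ancestor of a nonempty set of nodes."""
        nodes = list(nodes)
        if not nodes:
            raise ValueError("mrca of an empty set is undefined")
        current = nodes[0]
        self._check(current)
        for other in nodes[1:]:
            self._check(other)
            a, b = current, other
            while self.depth(a) > self.depth(b):
                a = self.parent[a]
            while self.depth(b) > self.depth(a):
                b = self.parent[b]
            while a != b:
                a, b = self.parent[a], self.parent[b]
            current = a
        return current

    def path(self, a: str, b: str) -> list:
        """The unique simple path a..b (inclusive) through their MRCA."""
        m = self.mrca([a, b])
        up = []
        n = a
        while n != m:
            up.append(n)
            n = self.parent[n]
        down = []
        n = b
        while n != m:
            down.append(n)
            n = self.parent[n]
        return up + [m] + list(reversed(down))

    def focal_root_path(self) -> list:
        """Nodes from the focal leaf to the root — the admissible strata."""
        if self.focal_leaf is None:
            raise TreeValidationError("no focal leaf set")
        return self.root_path(self.focal_leaf)

    def leaves_under(self, node: str) -> list:
        self._check(node)
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            kids = self.children.get(n)
            if kids:
                stack.extend(reversed(kids))
            else:
                out.append(n)
        return out

    def descends_from(self, node: str, ancestor: str) -> bool:
        self._check(node)
        self._check(ancestor)
        n = node
        while n is not None:
            if n == ancestor:
                return True
            n = self.parent[n]
        return False

    def branches(self) -> list:
        """All branches, each identified by its child node."""
        return [n for n in self.parent if self.parent[n] is not None]

    def postorder(self) -> list:
        out, stack = [], [(self.root, False)]
        while stack:
            n, seen = stack.pop()
            if seen or not self.children.get(n):
                out.append(n)
            else:
                stack.append((n, True))
                for c in reversed(self.children[n]):
                    stack.append((c, False))
        return out

    # -- output ------------------------------------------------------------

    def to_newick(self, internal_labels: bool = True) -> str:
        def rec(n):
            kids = self.children.get(n)
            if not kids:
                return n
            inner = ",".join(rec(c) for c in kids)
            label = n if (internal_labels and n not in self.auto_ids) else ""
            return f"({inner}){label}"
        return rec(self.root) + ";"


def parse_newick(text: str, focal_leaf: str | None = None) -> SpeciesTree:
    """Parse a rooted Newick string into a :class:`SpeciesTree`.

    Unlabeled internal nodes are numbered ``N1..Nk`` in post-order; labeled
    internal nodes keep their label.  Branch lengths are discarded.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from None
    parent: dict = {}
    children: dict = {}
    counter = 0
    names: dict = {}
    seen: set = set()
    auto: set = set()
    for nd in dt.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if label is None:
                raise NewickParseError("leaf without a label")
        else:
            label = nd.label
            if label is None:
                counter += 1
                label = f"N{counter}"
                auto.add(label)
        if label in seen:
            raise TreeValidationError(f"duplicate node label {label!r}")
        seen.add(label)
        names[nd] = label
    for nd in dt.postorder_node_iter():
        label = names[nd]
        children[label] = [names[c] for c in nd.child_nodes()]
        parent[label] = None if nd.parent_node is None else names[nd.parent_node]
    root = names[dt.seed_node]
    return SpeciesTree.from_maps(parent, children, root, focal_leaf, auto_ids=auto)


# -- taxon metadata ---------------------------------------------------------

def read_taxon_meta(source) -> pd.DataFrame:
    """Read the taxon metadata TSV (taxon_id, genus, supertaxon, domain_of_life)."""
    meta = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise TreeValidationError(f"metadata missing columns: {missing}")
    bad = set(meta["domain_of_life"]) - set(DOMAINS_OF_LIFE)
    if bad:
        raise TreeValidationError(f"unknown domain_of_life values: {sorted(bad)}")
    if meta["taxon_id"].duplicated().any():
        dupes = meta.loc[meta["taxon_id"].duplicated(), "taxon_id"].tolist()
        raise TreeValidationError(f"duplicate taxon ids in metadata: {dupes}")
    return meta[list(META_COLUMNS)]


def validate_tree_meta(tree: SpeciesTree, meta: pd.DataFrame) -> None:
    """Check leaf/metadata agreement and supertaxon monophyly (hard errors)."""
    leaves = set(tree.leaves)
    listed = set(meta["taxon_id"])
    if leaves != listed:
        raise TreeValidationError(
            f"leaf/metadata mismatch: only in tree {sorted(leaves - listed)}, "
            f"only in metadata {sorted(listed - leaves)}")
    for st, group in meta.groupby("supertaxon"):
        members = set(group["taxon_id"])
        under = set(tree.leaves_under(tree.mrca(members)))
        if under != members:
            raise TreeValidationError(
                f"supertaxon {st!r} is not monophyletic: clade also contains "
                f"{sorted(under - members)}")


def collapse_to_supertaxa(tree: SpeciesTree, meta: pd.DataFrame) -> SpeciesTree:
    """Collapse each supertaxon into a single leaf, keeping the induced topology.

    The focal leaf of the result is the focal species' supertaxon.
    """
    validate_tree_meta(tree, meta)
    mrca_of = {st: tree.mrca(set(g["taxon_id"]))
               for st, g in meta.groupby("supertaxon")}
    leaf_for_node = {v: k for k, v in mrca_of.items()}
    parent: dict = {}
    children: dict = {}
    counter = 0

    def rec(node):
        nonlocal counter
        if node in leaf_for_node:
            st = leaf_for_node[node]
            children[st] = []
            return st
        kids = [r for r in (rec(c) for c in tree.children.get(node, [])) if r]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        counter += 1
        name = f"S{counter}"
        children[name] = kids
        for k in kids:
            parent[k] = name
        return name

    new_root = rec(tree.root)
    parent[new_root] = None
    focal_st = None
    if tree.focal_leaf is not None:
        focal_st = meta.set_index("taxon_id")["supertaxon"][tree.focal_leaf]
    auto = {n for n in children if n.startswith("S") and children[n]}
    return SpeciesTree.from_maps(parent, children, new_root, focal_st, auto_ids=auto)


def taxa_by_distance(tree: SpeciesTree, reference: str | None = None) -> list:
    """Non-reference leaves ordered by increasing evolutionary distance.

    Distance is topological: leaves whose MRCA with the reference is deeper
    (closer to the reference) come first; ties break lexicographically.
    """
    ref = reference if reference is not None else tree.focal_leaf
    if ref is None:
        raise TreeValidationError("no reference leaf")
    others = [x for x in tree.leaves if x != ref]
    return sorted(others, key=lambda x: (-tree.depth(tree.mrca([ref, x])), x))
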