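"""Presence matrices, supertaxon aggregation, Dollo parsimony and strata.

Dollo parsimony assumes a gene is gained once and only lost thereafter, so
finding an ortholog in any non-focal species implies the gene was present
in the common ancestor of that species and the focal species.  The Dollo
state of a gene is therefore the spanning set of nodes on the paths from
the focal leaf to every bearer; the gene's *phylostratum* is the node of
that state on the focal-root path farthest from the focal leaf — a minimum
age, never an overestimate under the Dollo assumption.

Supertaxon aggregation offers three stringencies: presence in at least one
subsumed species ("any"), in strictly more than 25%, and in strictly more
than 50% of them.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .treeops import SpeciesTree, collapse_to_supertaxa

__all__ = [
    "build_presence_matrix", "supertaxon_profile", "supertaxon_counts",
    "dollo_state", "ancestral_inventories", "assign_stratum", "assign_strata",
    "coortholog_stats", "repertoire_setops", "STRINGENCIES",
]

STRINGENCIES = ("any", "gt25", "gt50")


def build_presence_matrix(assignments: pd.DataFrame, rbf_ids: Sequence[str],
                          taxa: Sequence[str], focal_taxon: str) -> pd.DataFrame:
    """Integer copy-count matrix (query x taxon) from an assignment table.

    A cell counts representative + co-orthologs.  The focal column is at
    least 1 for every query — the query protein itself exists by definition.
    """
    matrix = pd.DataFrame(0, index=sorted(rbf_ids), columns=sorted(taxa), dtype=int)
    for row in assignments.itertuples(index=False):
        if row.rbf_id in matrix.index and row.taxon_id in matrix.columns:
            matrix.at[row.rbf_id, row.taxon_id] = int(row.n_copies)
    matrix[focal_taxon] = matrix[focal_taxon].clip(lower=1)
    return matrix


def supertaxon_profile(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per (query, supertaxon) bearer fraction and the three stringency calls.

    Thresholds are strict: ``gt25`` needs > 25% of the subsumed species,
    ``gt50`` > 50%; ``any`` needs at least one.
    """
    st_of = dict(zip(meta["taxon_id"], meta["supertaxon"]))
    unmapped = [t for t in matrix.columns if t not in st_of]
    if unmapped:
        raise ValueError(f"taxa without a supertaxon: {unmapped}")
    presence = matrix > 0
    rows = []
    for st, group in meta.groupby("supertaxon"):
        members = [t for t in group["taxon_id"] if t in presence.columns]
        if not members:
            continue
        frac = presence[members].sum(axis=1) / len(members)
        for rbf, f in frac.items():
            rows.append({"rbf_id": rbf, "supertaxon": st, "fraction": float(f),
                         "any": f > 0, "gt25": f > 0.25, "gt50": f > 0.50})
    return pd.DataFrame(rows, columns=["rbf_id", "supertaxon", "fraction",
                                       "any", "gt25", "gt50"])


def supertaxon_counts(profile: pd.DataFrame) -> pd.DataFrame:
    """Queries represented per supertaxon at each stringency (wide table)."""
    out = profile.groupby("supertaxon")[list(STRINGENCIES)].sum().astype(int)
    return out


def dollo_state(tree: SpeciesTree, bearers: Iterable[str]) -> set:
    """Nodes where the gene must have been present under Dollo parsimony.

    The focal leaf is always a bearer.  A node is in the state iff it lies
    on the path from the focal leaf to some non-focal bearer; with no other
    bearers the state is the focal leaf alone.
    """
    focal = tree.focal_leaf
    if focal is None:
        raise ValueError("tree has no focal leaf")
    state = {focal}
    for b in set(bearers):
        if b == focal:
            continue
        if not tree.is_leaf(b):
            raise ValueError(f"bearer {b!r} is not a leaf")
        state.update(tree.path(focal, b))
    return state


def ancestral_inventories(tree: SpeciesTree, presence: pd.DataFrame,
                          meta: pd.DataFrame | None = None,
                          level: str = "species", stringency: str = "any") -> dict:
    """Dollo inventory (set of queries) for every node of the tree.

    ``level='species'`` reads a query x taxon matrix directly;
    ``level='supertaxon'`` first collapses the tree and calls a supertaxon a
    bearer when it passes the chosen stringency.
    """
    if level == "species":
        work_tree = tree
        bearer_matrix = presence > 0
    elif level == "supertaxon":
        if meta is None:
            raise ValueError("supertaxon level needs taxon metadata")
        if stringency not in STRINGENCIES:
            raise ValueError(f"unknown stringency {stringency!r}")
        work_tree = collapse_to_supertaxa(tree, meta)
        prof = supertaxon_profile(presence, meta)
        bearer_matrix = prof.pivot(index="rbf_id", columns="supertaxon",
                                   values=stringency).fillna(False)
    else:
        raise ValueError(f"unknown level {level!r}")
    missing = [t for t in bearer_matrix.columns if t not in set(work_tree.leaves)]
    if missing:
        raise ValueError(f"matrix columns not in the tree: {missing}")
    inventories: dict = {n: set() for n in work_tree.nodes}
    for rbf, row in bearer_matrix.iterrows():
        bearers = [t for t, p in row.items() if p]
        if work_tree.focal_leaf not in bearers:
            bearers.append(work_tree.focal_leaf)
        for node in dollo_state(work_tree, bearers):
            inventories[node].add(rbf)
    return inventories


def assign_stratum(tree: SpeciesTree, bearers: Iterable[str]) -> str:
    """The query's phylostratum: deepest MRCA with any bearer, toward the root."""
    focal = tree.focal_leaf
    state = dollo_state(tree, bearers)
    # oldest focal-path node contained in the Dollo state
    for node in reversed(tree.focal_root_path()):
        if node in state:
            return node
    return focal


def assign_strata(tree: SpeciesTree, presence: pd.DataFrame) -> pd.Series:
    """Stratum per query from a presence (or count) matrix."""
    out = {}
    bool_presence = presence > 0
    for rbf, row in bool_presence.iterrows():
        bearers = [t for t, p in row.items() if p]
        out[rbf] = assign_stratum(tree, bearers)
    return pd.Series(out, name="stratum").sort_index()


def coortholog_stats(matrix: pd.DataFrame, meta: pd.DataFrame,
                     include_absent: bool = False) -> pd.DataFrame:
    """Median copy number per (query, supertaxon).

    By default only bearer species count; ``include_absent`` adds zeros for
    species without the ortholog.  Even-cardinality medians take the lower
    central value, a deterministic convention.
    """
    st_of = dict(zip(meta["taxon_id"], meta["supertaxon"]))
    rows = []
    for st, group in meta.groupby("supertaxon"):
        members = [t for t in group["taxon_id"] if t in matrix.columns]
        if not members:
            continue
        sub = matrix[members]
        for rbf, counts in sub.iterrows():
            values = list(counts) if include_absent else [c for c in counts if c > 0]
            if values:
                values.sort()
                med = values[(len(values) - 1) // 2]   # lower median
            else:
                med = 0
            rows.append({"rbf_id": rbf, "supertaxon": st, "median_copies": int(med)})
    return pd.DataFrame(rows, columns=["rbf_id", "supertaxon", "median_copies"])


def repertoire_setops(matrix: pd.DataFrame, taxa: Sequence[str]) -> dict:
    """Per-taxon repertoire sizes plus intersection and union cardinalities."""
    if not taxa:
        raise ValueError("need at least one taxon")
    unknown = [t for t in taxa if t not in matrix.columns]
    if unknown:
        raise KeyError(f"unknown taxa: {unknown}")
    sets = {t: set(matrix.index[matrix[t] > 0]) for t in taxa}
    inter = set.intersection(*sets.values())
    union = set.union(*sets.values())
    return {"per_taxon": {t: len(s) for t, s in sets.items()},
            "intersection": len(inter), "union": len(union)}
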