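"""Within-query-set paralog detection, duplication dating and lineage collapse.

Two focal-species queries that arose by duplication of one ancestral gene
share part of their history.  If both appear as co-orthologs to a single
protein of a second species, the duplication postdates the split between
that species and the focal lineage.  Screening comparison species in order
of increasing evolutionary distance, the *closest* species that co-clusters
the pair dates the duplication: it happened, at the latest, just below the
MRCA of the focal leaf and that species.

Co-clustering uses reciprocal-best-hit seed pairs with in-paralog
attachment (the classic two-species orthologous-group clustering): a focal
protein joins a seed group iff its distance to the focal seed is strictly
smaller than the distance between the two seeds.

A complementary route pairs queries with identical domain composition and
confirms them by a sequence-distance ceiling; such pairs carry domain
evidence and no witness-based dating of their own.

Paralog pairs are finally collapsed into lineages (union–find closure) so
that each phylostratum counts evolutionarily distinct lineages rather than
contemporary genes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .align import ScoreCache
from .architecture import FeatureArchitecture
from .sequences import ProteinRecord
from .treeops import SpeciesTree, taxa_by_distance

__all__ = ["OrthoGroup", "ParalogPair", "Lineage", "inparanoid_groups",
           "detect_pairs", "domain_composition_pairs", "collapse_lineages"]


@dataclass
class OrthoGroup:
    seed_a: str
    seed_b: str
    inparalogs_a: list
    inparalogs_b: list
    seed_distance: float

    def side_a(self) -> set:
        return {self.seed_a, *self.inparalogs_a}

    def side_b(self) -> set:
        return {self.seed_b, *self.inparalogs_b}


@dataclass
class ParalogPair:
    rbf_a: str
    rbf_b: str
    duplication_node: str | None    # focal-path node; None until dated
    evidence: str                   # witness taxon id or 'domain'

    def key(self) -> tuple:
        return tuple(sorted((self.rbf_a, self.rbf_b)))


@dataclass
class Lineage:
    lineage_id: str
    members: list
    origin_node: str


def inparanoid_groups(side_a: Sequence[ProteinRecord], side_b: Sequence[ProteinRecord],
                      cache: ScoreCache | None = None,
                      min_seed_score: float = 100.0) -> list:
    """Two-species orthologous groups: reciprocal-best seeds plus in-paralogs.

    A reciprocal-best pair only seeds a group if its alignment score reaches
    ``min_seed_score`` — a reciprocal best hit always exists, even between
    unrelated proteomes, so an unfiltered seed is not evidence of homology.
    Deterministic: best hits break ties lexicographically, and a protein
    eligible for several groups joins the one whose seed it is closest to.
    """
    if not side_a or not side_b:
        raise ValueError("both proteomes must be nonempty")
    if cache is None:
        cache = ScoreCache()
    ids_a = {r.protein_id: r for r in side_a}
    ids_b = {r.protein_id: r for r in side_b}

    def best(rec, others):
        return min(((-cache.score(rec, o), o.protein_id) for o in others))[1]

    best_b = {a.protein_id: best(a, side_b) for a in side_a}
    best_a = {b.protein_id: best(b, side_a) for b in side_b}
    seeds = [(a, best_b[a]) for a in sorted(best_b)
             if best_a[best_b[a]] == a
             and cache.score(ids_a[a], ids_b[best_b[a]]) >= min_seed_score]
    groups = [OrthoGroup(a, b, [], [], cache.distance(ids_a[a], ids_b[b]))
              for a, b in seeds]
    seed_members = {a for a, _ in seeds} | {b for _, b in seeds}

    def attach(records, ids_self, seed_attr, bucket_attr):
        for rec in sorted(records, key=lambda r: r.protein_id):
            if rec.protein_id in seed_members:
                continue
            candidates = []
            for g in groups:
                seed = ids_self[getattr(g, seed_attr)]
                d = cache.distance(rec, seed)
                if d < g.seed_distance:
                    candidates.append((d, getattr(g, seed_attr), g))
            if candidates:
                _, _, g = min(candidates, key=lambda c: (c[0], c[1]))
                getattr(g, bucket_attr).append(rec.protein_id)

    attach(side_a, ids_a, "seed_a", "inparalogs_a")
    attach(side_b, ids_b, "seed_b", "inparalogs_b")
    return groups


def _dup_node_below_mrca(tree: SpeciesTree, witness_taxon: str) -> str:
    """Focal-path node immediately below mrca(focal, witness)."""
    focal = tree.focal_leaf
    m = tree.mrca([focal, witness_taxon])
    path = tree.focal_root_path()
    if m == focal:
        return focal
    idx = path.index(m)
    return path[idx - 1]


def detect_pairs(rbf_records: Sequence[ProteinRecord],
                 proteomes: Mapping[str, Sequence[ProteinRecord]],
                 tree: SpeciesTree, cache: ScoreCache | None = None,
                 min_seed_score: float = 100.0) -> list:
    """Co-orthology-based paralog pairs with witness dating.

    Comparison species are visited in order of increasing distance from the
    focal leaf; a pair keeps the dating from its first (closest)
    co-clustering witness — more distant witnesses only confirm it.
    """
    if cache is None:
        cache = ScoreCache()
    rbf_ids = {r.protein_id for r in rbf_records}
    found: dict = {}
    for taxon in taxa_by_distance(tree):
        if taxon not in proteomes or not proteomes[taxon]:
            continue
        for group in inparanoid_groups(rbf_records, proteomes[taxon], cache,
                                       min_seed_score=min_seed_score):
            members = sorted(group.side_a() & rbf_ids)
            for a, b in combinations(members, 2):
                if (a, b) not in found:
                    found[(a, b)] = ParalogPair(a, b, _dup_node_below_mrca(tree, taxon),
                                                evidence=taxon)
    return [found[k] for k in sorted(found)]


def domain_composition_pairs(rbf_records: Sequence[ProteinRecord],
                             architectures: Mapping[str, FeatureArchitecture],
                             existing: Sequence[ParalogPair] = (),
                             distance_ceiling: float = 0.7,
                             min_score: float | None = None,
                             cache: ScoreCache | None = None) -> list:
    """Pairs with identical (nonempty) domain composition, distance-confirmed.

    Pairs already found by co-orthology are skipped.  The distance ceiling
    replaces a full phylogenetic confirmation: architectures can coincide by
    chance, so a pair must also be closer in sequence than the ceiling.
    """
    if cache is None:
        cache = ScoreCache()
    seen = {p.key() for p in existing}
    by_id = {r.protein_id: r for r in rbf_records}
    comps = {}
    for pid in sorted(by_id):
        arch = architectures.get(pid)
        comp = arch.domain_ids(min_score) if arch is not None else Counter()
        if comp:
            comps[pid] = frozenset(comp.items())
    pairs = []
    for a, b in combinations(sorted(comps), 2):
        if comps[a] != comps[b] or (a, b) in seen:
            continue
        if cache.distance(by_id[a], by_id[b]) < distance_ceiling:
            pairs.append(ParalogPair(a, b, None, evidence="domain"))
    return pairs


def collapse_lineages(strata: Mapping[str, str], pairs: Sequence[ParalogPair],
                      tree: SpeciesTree):
    """Union–find closure of paralog pairs into lineages, with stratum counts.

    A lineage's origin is the oldest member stratum.  Returns
    ``(lineages, per-stratum counts DataFrame, pair layer table)``; the pair
    table gives each pair's older layer (minimum age of the shared lineage)
    and younger layer (the duplication node; for undated domain-evidence
    pairs, the younger member's stratum as the latest consistent point).
    """
    strata = dict(strata)
    parent = {r: r for r in strata}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in pairs:
        for r in (p.rbf_a, p.rbf_b):
            if r not in parent:
                raise ValueError(f"pair references unknown query {r!r}")
        ra, rb = find(p.rbf_a), find(p.rbf_b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    members: dict = {}
    for r in sorted(strata):
        members.setdefault(find(r), []).append(r)
    lineages = []
    for i, root in enumerate(sorted(members), start=1):
        mem = members[root]
        origin = min((strata[m] for m in mem), key=tree.depth)
        lineages.append(Lineage(f"lin_{i:04d}", mem, origin))

    focal_path = tree.focal_root_path()
    counts = pd.DataFrame(0, index=focal_path, columns=["lineages", "rbfs"])
    for lin in lineages:
        counts.at[lin.origin_node, "lineages"] += 1
    for r, s in strata.items():
        counts.at[s, "rbfs"] += 1

    layer_rows = []
    for p in pairs:
        older = min((strata[p.rbf_a], strata[p.rbf_b]), key=tree.depth)
        younger = p.duplication_node
        if younger is None:
            younger = max((strata[p.rbf_a], strata[p.rbf_b]), key=tree.depth)
        layer_rows.append({"rbf_a": p.rbf_a, "rbf_b": p.rbf_b,
                           "older_layer": older, "younger_layer": younger,
                           "evidence": p.evidence})
    layers = pd.DataFrame(layer_rows, columns=["rbf_a", "rbf_b", "older_layer",
                                               "younger_layer", "evidence"])
    return lineages, counts, layers
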