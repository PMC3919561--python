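"""Synthetic species trees, planted gene histories and evolved proteomes.

The generator emulates the data a phylogenomic profiling study consumes:

* a rooted species tree whose leaves fall into monophyletic supertaxa and
  consecutive-sibling genera, optionally with archaeal and bacterial clades
  so the topology mirrors a three-domains tree of life;
* per-gene histories under a Dollo-style model — one origin on the focal
  lineage, irreversible losses sampled per branch, occasional duplications
  whose daughter copies evolve as separately labeled lineages;
* protein sequences with conserved domain blocks and faster-evolving
  linkers, evolved by Poisson-distributed uniform substitutions along each
  branch (a Jukes–Cantor-like model on amino acids, no indels), plus decoy
  proteins with their own disjoint domain namespace;
* complete ground-truth tables from which the expected presence matrix,
  origins and duplication nodes can be recomputed exactly.

Losses are never sampled on the origin → focal path, so every planted gene
is guaranteed a focal copy (every query exists in the focal species) without
biasing loss rates elsewhere.  Daughter copies created by a duplication
share the fate of the primary copy below the duplication node; they are not
lost independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequences import AMINO_ACIDS, ProteinRecord, write_fasta
from .treeops import SpeciesTree, parse_newick

__all__ = [
    "GeneHistory", "SyntheticTruth", "SyntheticDataset",
    "generate_species_tree", "plant_gene_histories", "evolve_proteomes",
    "make_dataset", "write_dataset",
]


@dataclass
class GeneHistory:
    """Planted history of one gene family (a 'lineage')."""

    lineage_id: str
    origin_node: str
    loss_branches: set          # branch = child node id
    duplication_events: list    # (node, daughter_label)

    def label_origins(self) -> dict:
        out = {self.lineage_id: self.origin_node}
        for node, label in self.duplication_events:
            out[label] = node
        return out


@dataclass
class SyntheticTruth:
    histories: dict                     # lineage_id -> GeneHistory
    label_presence: pd.DataFrame        # label x taxon, 0/1
    copy_number: pd.DataFrame           # lineage x taxon, int
    label_origin: dict                  # label -> origin node
    provenance: pd.DataFrame = None     # protein_id, taxon_id, label ('decoy' for decoys)

    def recompute_presence(self, tree: SpeciesTree) -> pd.DataFrame:
        """Re-derive the per-label presence matrix from the history fields."""
        return _presence_from_histories(tree, self.histories)


@dataclass
class SyntheticDataset:
    tree: SpeciesTree
    meta: pd.DataFrame
    truth: SyntheticTruth
    proteomes: dict                     # taxon -> [ProteinRecord]
    domains: pd.DataFrame               # protein_id, feature_id, class, start, end, score
    queries: pd.DataFrame               # protein_id, rbf_id, stage
    params: dict = field(default_factory=dict)

    @property
    def focal_taxon(self) -> str:
        return self.tree.focal_leaf

    def query_records(self) -> list:
        wanted = set(self.queries["protein_id"])
        return [r for r in self.proteomes[self.focal_taxon] if r.protein_id in wanted]


# -- species tree -----------------------------------------------------------

def _random_join(parts: list, rng: np.random.Generator) -> str:
    parts = list(parts)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        merged = f"({parts[i]},{parts[j]})"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    return parts[0]


def generate_species_tree(n_species: int, n_supertaxa: int, genus_size: int = 2,
                          seed: int = 0, n_archaeal: int = 0, n_bacterial: int = 0):
    """Random rooted species tree with monophyletic supertaxa and genera.

    Supertaxa are laid out as eukaryotic, then archaeal, then bacterial
    clades; with prokaryotic clades present the root splits bacteria from
    (archaea, eukaryotes).  The focal leaf is the first leaf of the first
    (eukaryotic) supertaxon.  Returns ``(SpeciesTree, meta DataFrame)``.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    if not (1 <= n_supertaxa <= n_species):
        raise ValueError("n_supertaxa must be between 1 and n_species")
    if genus_size < 1:
        raise ValueError("genus_size must be >= 1")
    if n_archaeal + n_bacterial >= n_supertaxa:
        raise ValueError("need at least one eukaryotic supertaxon")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_species, n_supertaxa)
    sizes = [base + (1 if i < extra else 0) for i in range(n_supertaxa)]
    n_euk = n_supertaxa - n_archaeal - n_bacterial
    rows = []
    subtrees = []
    leaf_no = 0
    genus_no = 0
    for st_idx, size in enumerate(sizes):
        st = f"ST{st_idx + 1:02d}"
        if st_idx < n_euk:
            dom = "eukaryote"
        elif st_idx < n_euk + n_archaeal:
            dom = "archaeon"
        else:
            dom = "bacterium"
        leaves = []
        for k in range(size):
            if k % genus_size == 0:
                genus_no += 1
            leaf_no += 1
            leaf = f"t{leaf_no:03d}"
            leaves.append(leaf)
            rows.append({"taxon_id": leaf, "genus": f"g{genus_no:03d}",
                         "supertaxon": st, "domain_of_life": dom})
        subtrees.append(_random_join(leaves, rng) if len(leaves) > 1 else leaves[0])
    euk = _random_join(subtrees[:n_euk], rng)
    arc = _random_join(subtrees[n_euk:n_euk + n_archaeal], rng) if n_archaeal else None
    bac = _random_join(subtrees[n_euk + n_archaeal:], rng) if n_bacterial else None
    if arc is not None and bac is not None:
        newick = f"(({euk},{arc}),{bac});"
    elif arc is not None:
        newick = f"({euk},{arc});"
    elif bac is not None:
        newick = f"({euk},{bac});"
    else:
        newick = euk + ";"
    meta = pd.DataFrame(rows)
    tree = parse_newick(newick, focal_leaf="t001")
    return tree, meta


# -- gene histories ---------------------------------------------------------

def _presence_from_histories(tree: SpeciesTree, histories: Mapping[str, GeneHistory]) -> pd.DataFrame:
    taxa = sorted(tree.leaves)
    rows = {}
    for lid in sorted(histories):
        h = histories[lid]
        primary = {}
        for leaf in taxa:
            if not tree.descends_from(leaf, h.origin_node):
                primary[leaf] = 0
                continue
            chain = tree.path(h.origin_node, leaf)[1:]  # nodes below origin
            primary[leaf] = 0 if any(n in h.loss_branches for n in chain) else 1
        rows[lid] = primary
        for node, label in h.duplication_events:
            rows[label] = {leaf: (primary[leaf] if tree.descends_from(leaf, node) else 0)
                           for leaf in taxa}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=taxa).astype(int)
    return df.sort_index()


def plant_gene_histories(tree: SpeciesTree, n_lineages: int,
                         origin_weights: Mapping[str, float] | Sequence[float] | None = None,
                         loss_rate: float = 0.1, dup_rate: float = 0.02,
                         seed: int = 0,
                         forced_origins: Mapping[int, str] | None = None,
                         forced_duplications: Mapping[int, str] | None = None) -> SyntheticTruth:
    """Sample per-lineage origins, Dollo losses and duplications.

    ``origin_weights`` is a weight per focal-root-path node (mapping or a
    sequence ordered leaf → root); the default is uniform.  ``forced_*`` pin
    the origin / add one duplication for selected lineage indices, for
    constructed-fixture tests.
    """
    if not (0.0 <= loss_rate <= 1.0 and 0.0 <= dup_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    fpath = tree.focal_root_path()
    if origin_weights is None:
        weights = np.ones(len(fpath))
    elif isinstance(origin_weights, Mapping):
        weights = np.array([float(origin_weights.get(n, 0.0)) for n in fpath])
    else:
        weights = np.asarray(list(origin_weights), dtype=float)
        if len(weights) != len(fpath):
            raise ValueError("origin_weights length must match the focal-root path")
    if weights.sum() <= 0 or (weights < 0).any():
        raise ValueError("origin weights must be nonnegative with positive sum")
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    focal_chain = set(fpath)
    histories = {}
    for i in range(n_lineages):
        lid = f"L{i + 1:04d}"
        if forced_origins and i in forced_origins:
            origin = forced_origins[i]
            if origin not in focal_chain:
                raise ValueError(f"forced origin {origin!r} is not on the focal-root path")
        else:
            origin = fpath[int(rng.choice(len(fpath), p=probs))]
        below = [b for b in tree.branches() if tree.descends_from(tree.parent[b], origin)]
        loss_eligible = [b for b in below if b not in focal_chain]
        losses = {b for b in loss_eligible if rng.random() < loss_rate}
        dups = []
        dup_nodes = [b for b in below if rng.random() < dup_rate]
        if forced_duplications and i in forced_duplications:
            node = forced_duplications[i]
            if not tree.descends_from(node, origin):
                raise ValueError("forced duplication must lie below the origin")
            if node not in dup_nodes:
                dup_nodes.append(node)
        for k, node in enumerate(sorted(dup_nodes, key=tree.depth)):
            dups.append((node, f"{lid}.{k + 1}"))
        histories[lid] = GeneHistory(lid, origin, losses, dups)
    label_presence = _presence_from_histories(tree, histories)
    fam_of = {label: label.split(".")[0] for label in label_presence.index}
    copy_number = label_presence.groupby(label_presence.index.map(fam_of)).sum()
    label_origin = {}
    for h in histories.values():
        label_origin.update(h.label_origins())
    return SyntheticTruth(histories, label_presence, copy_number, label_origin)


# -- proteome evolution -----------------------------------------------------

def _domain_layout(seq_length: int, n_blocks: int, span: int) -> list:
    if n_blocks == 0:
        return []
    gap = (seq_length - n_blocks * span) // (n_blocks + 1)
    if gap < 1:
        raise ValueError("seq_length too short for the requested domain blocks")
    layout = []
    pos = gap
    for _ in range(n_blocks):
        layout.append((pos, pos + span))  # half-open
        pos += span + gap
    return layout


def _mutate(seq: np.ndarray, sites: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0 or sites.size == 0:
        return
    n_sub = rng.poisson(rate * sites.size)
    for _ in range(n_sub):
        pos = sites[rng.integers(sites.size)]
        new = rng.integers(19)
        if new >= seq[pos]:
            new += 1
        seq[pos] = new


def evolve_proteomes(tree: SpeciesTree, truth: SyntheticTruth, seq_length: int = 200,
                     domain_blocks: int = 2, domain_span: int = 40,
                     linker_rate: float = 0.05, domain_rate: float = 0.01,
                     n_decoys: int = 5, seed: int = 0,
                     decoy_pool: int = 20, domain_score: float = 50.0):
    """Evolve sequences for every planted lineage and emit decoys.

    Returns ``(proteomes, domains, queries, provenance)``; the provenance
    table is also stored on ``truth``.
    """
    if domain_rate > linker_rate:
        raise ValueError("domains must evolve no faster than linkers")
    layout = _domain_layout(seq_length, domain_blocks, domain_span)
    dom_sites = np.concatenate([np.arange(a, b) for a, b in layout]) if layout \
        else np.empty(0, dtype=int)
    link_sites = np.setdiff1d(np.arange(seq_length), dom_sites)
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    proteomes: dict = {t: [] for t in sorted(tree.leaves)}
    dom_rows: list = []
    prov_rows: list = []

    def emit(taxon: str, label: str, seq: np.ndarray, family: str) -> None:
        pid = f"{taxon}_{label}"
        proteomes[taxon].append(ProteinRecord(pid, taxon, bytes(aa[seq]).decode()))
        fam_idx = int(family[1:])
        for bi, (a, b) in enumerate(layout):
            dom_rows.append((pid, f"PFS{fam_idx:04d}{chr(65 + bi)}", "domain",
                             a + 1, b, domain_score))
        prov_rows.append((pid, taxon, label))

    for lid in sorted(truth.histories):
        h = truth.histories[lid]
        root_seq = rng.integers(0, 20, size=seq_length).astype(np.int16)
        dups_at: dict = {}
        for node, label in h.duplication_events:
            dups_at.setdefault(node, []).append(label)

        def down(node, seqs: dict) -> None:
            if not tree.children.get(node):  # leaf
                for label, s in seqs.items():
                    if truth.label_presence.at[label, node]:
                        emit(node, label, s, lid)
                return
            for child in tree.children[node]:
                if child in h.loss_branches:
                    continue
                child_seqs = {}
                for label, s in seqs.items():
                    cs = s.copy()
                    _mutate(cs, link_sites, linker_rate, rng)
                    _mutate(cs, dom_sites, domain_rate, rng)
                    child_seqs[label] = cs
                for label in dups_at.get(child, ()):
                    child_seqs[label] = child_seqs[lid].copy()
                down(child, child_seqs)

        origin = h.origin_node
        if tree.children.get(origin):
            down(origin, {lid: root_seq})
        else:  # origin is the focal leaf itself
            seqs = {lid: root_seq}
            for label in dups_at.get(origin, ()):
                seqs[label] = root_seq.copy()
            for label, s in seqs.items():
                emit(origin, label, s, lid)

    pool = [f"DEC{j + 1:03d}" for j in range(decoy_pool)]
    for taxon in sorted(tree.leaves):
        for j in range(n_decoys):
            pid = f"{taxon}_X{j + 1:02d}"
            seq = rng.integers(0, 20, size=seq_length).astype(np.int16)
            proteomes[taxon].append(ProteinRecord(pid, taxon, bytes(aa[seq]).decode()))
            prov_rows.append((pid, taxon, "decoy"))
            for d in range(int(rng.integers(1, 3))):
                did = pool[int(rng.integers(len(pool)))]
                start = int(rng.integers(1, seq_length - 30))
                dom_rows.append((pid, did, "domain", start, start + 29, domain_score))

    domains = pd.DataFrame(dom_rows, columns=["protein_id", "feature_id", "class",
                                              "start", "end", "score"])
    provenance = pd.DataFrame(prov_rows, columns=["protein_id", "taxon_id", "label"])
    truth.provenance = provenance
    focal = tree.focal_leaf
    stages = ["90S", "pre-60S", "pre-40S", "unassigned"]
    q_rows = []
    for rec in proteomes[focal]:
        label = provenance.set_index("protein_id")["label"].get(rec.protein_id)
        if label and label != "decoy":
            q_rows.append((rec.protein_id, label, stages[int(rng.integers(len(stages)))]))
    queries = pd.DataFrame(q_rows, columns=["protein_id", "rbf_id", "stage"])
    return proteomes, domains, queries, provenance


def make_dataset(n_species: int = 40, n_supertaxa: int = 6, genus_size: int = 2,
                 n_archaeal: int = 1, n_bacterial: int = 1, n_lineages: int = 50,
                 loss_rate: float = 0.1, dup_rate: float = 0.02,
                 seq_length: int = 200, domain_blocks: int = 2, domain_span: int = 40,
                 linker_rate: float = 0.05, domain_rate: float = 0.01,
                 n_decoys: int = 5, seed: int = 0, origin_weights=None,
                 forced_origins=None, forced_duplications=None) -> SyntheticDataset:
    """One-call generator: tree + histories + proteomes + annotations + truth."""
    tree, meta = generate_species_tree(n_species, n_supertaxa, genus_size, seed,
                                       n_archaeal, n_bacterial)
    truth = plant_gene_histories(tree, n_lineages, origin_weights, loss_rate,
                                 dup_rate, seed + 1, forced_origins, forced_duplications)
    proteomes, domains, queries, _ = evolve_proteomes(
        tree, truth, seq_length, domain_blocks, domain_span, linker_rate,
        domain_rate, n_decoys, seed + 2)
    params = dict(n_species=n_species, n_supertaxa=n_supertaxa, genus_size=genus_size,
                  n_archaeal=n_archaeal, n_bacterial=n_bacterial, n_lineages=n_lineages,
                  loss_rate=loss_rate, dup_rate=dup_rate, seq_length=seq_length,
                  domain_blocks=domain_blocks, domain_span=domain_span,
                  linker_rate=linker_rate, domain_rate=domain_rate,
                  n_decoys=n_decoys, seed=seed)
    return SyntheticDataset(tree, meta, truth, proteomes, domains, queries, params)


def write_dataset(ds: SyntheticDataset, outdir, force: bool = False) -> Path:
    """Write FASTA, TSVs, truth tables and a checksum manifest."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force to overwrite)")
    (outdir / "fasta").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    files = []

    def save_tsv(df: pd.DataFrame, rel: str, index: bool = False) -> None:
        p = outdir / rel
        df.to_csv(p, sep="\t", index=index)
        files.append(rel)

    (outdir / "tree.nwk").write_text(ds.tree.to_newick() + "\n")
    files.append("tree.nwk")
    save_tsv(ds.meta, "meta.tsv")
    save_tsv(ds.queries, "queries.tsv")
    save_tsv(ds.domains, "domains.tsv")
    for taxon in sorted(ds.proteomes):
        rel = f"fasta/{taxon}.fa"
        write_fasta(outdir / rel, ds.proteomes[taxon])
        files.append(rel)
    origins = pd.DataFrame(sorted(ds.truth.label_origin.items()),
                           columns=["label", "origin_node"])
    save_tsv(origins, "truth/origins.tsv")
    losses = [(lid, b) for lid, h in sorted(ds.truth.histories.items())
              for b in sorted(h.loss_branches)]
    save_tsv(pd.DataFrame(losses, columns=["lineage", "lost_branch"]), "truth/losses.tsv")
    dups = [(lid, node, label) for lid, h in sorted(ds.truth.histories.items())
            for node, label in h.duplication_events]
    save_tsv(pd.DataFrame(dups, columns=["lineage", "node", "daughter"]),
             "truth/duplications.tsv")
    save_tsv(ds.truth.label_presence, "truth/presence.tsv", index=True)
    save_tsv(ds.truth.copy_number, "truth/copy_number.tsv", index=True)
    save_tsv(ds.truth.provenance, "truth/provenance.tsv")
    manifest = {
        "focal_taxon": ds.focal_taxon,
        "params": ds.params,
        "files": {rel: hashlib.sha256((outdir / rel).read_bytes()).hexdigest()
                  for rel in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
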