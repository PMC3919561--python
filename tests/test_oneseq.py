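"""Core-group compilation, reciprocal final search and the co-ortholog rule."""

import random

import pandas as pd
import pytest

from phyloprof.align import ScoreCache
from phyloprof.oneseq import (SearchConfig, assign_coorthologs,
                              compile_core_group, final_search,
                              run_ortholog_survey)
from phyloprof.sequences import AMINO_ACIDS, ProteinRecord


def _rand_seq(rng, n=120):
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(n))


def _mutated(rng, seq, k):
    s = list(seq)
    for pos in rng.sample(range(len(s)), k):
        s[pos] = rng.choice([c for c in AMINO_ACIDS if c != s[pos]])
    return "".join(s)


def _meta(rows):
    return pd.DataFrame(rows, columns=["taxon_id", "genus", "supertaxon",
                                       "domain_of_life"])


class TestCompile:
    def test_gene_only_in_focal_taxon(self):
        rng = random.Random(0)
        query = ProteinRecord("f_q", "f", _rand_seq(rng))
        proteomes = {
            "f": [query],
            "x": [ProteinRecord("x_1", "x", _rand_seq(rng))],
            "y": [ProteinRecord("y_1", "y", _rand_seq(rng))],
        }
        meta = _meta([("f", "gf", "s1", "eukaryote"), ("x", "gx", "s1", "eukaryote"),
                      ("y", "gy", "s1", "eukaryote")])
        group = compile_core_group(query, proteomes, meta)
        assert [m.protein_id for m in group.members] == ["f_q"]
        assert group.profile is not None

    def test_genus_filter_blocks_second_taxon(self):
        rng = random.Random(1)
        base = _rand_seq(rng)
        query = ProteinRecord("f_q", "f", base)
        proteomes = {
            "f": [query],
            "x1": [ProteinRecord("x1_1", "x1", _mutated(rng, base, 5))],
            "x2": [ProteinRecord("x2_1", "x2", _mutated(rng, base, 6))],
        }
        meta = _meta([("f", "gf", "s1", "eukaryote"), ("x1", "gx", "s1", "eukaryote"),
                      ("x2", "gx", "s1", "eukaryote")])
        group = compile_core_group(query, proteomes, meta)
        taxa = {m.taxon_id for m in group.members}
        assert len(taxa & {"x1", "x2"}) == 1  # same genus: only one ever joins

    def test_missing_focal_proteome(self):
        rng = random.Random(2)
        query = ProteinRecord("f_q", "f", _rand_seq(rng))
        with pytest.raises(ValueError):
            compile_core_group(query, {"x": []}, _meta([]))

    def test_members_are_true_lineage_members(self, small_dataset, small_survey):
        """Compiled groups contain only proteins of the query's own lineage."""
        prov = small_dataset.truth.provenance.set_index("protein_id")["label"]
        clean = 0
        for rbf, group in small_survey.groups.items():
            labels = {prov[m.protein_id] for m in group.members}
            if labels == {prov[rbf]}:
                clean += 1
        assert clean / len(small_survey.groups) >= 0.95

    def test_group_invariants_hold_each_iteration(self, small_survey):
        for group in small_survey.groups.values():
            group.validate()
            assert len(group.members) <= 1 + 5
            genera = [m.taxon_id for m in group.members[1:]]
            assert len(genera) == len(set(genera))


class TestFinalSearch:
    def test_query_accepted_in_focal_proteome(self, small_dataset, small_survey):
        ds = small_dataset
        cache = ScoreCache()
        for rbf in list(small_survey.groups)[:2]:
            group = small_survey.groups[rbf]
            accepted = final_search(group, ds.proteomes[ds.focal_taxon],
                                    ds.proteomes[ds.focal_taxon], cache=cache)
            assert rbf in {r.protein_id for r in accepted}

    def test_near_duplicate_focal_gene_breaks_reciprocity(self):
        """A candidate closest to a different focal protein is rejected."""
        rng = random.Random(3)
        base = _rand_seq(rng, 150)
        query = ProteinRecord("f_q", "f", base)
        paralog = ProteinRecord("f_p", "f", _mutated(rng, base, 40))
        # candidate derived from the paralog: profile finds it, reciprocity kills it
        cand = ProteinRecord("x_c", "x", _mutated(rng, paralog.sequence, 5))
        proteomes = {"f": [query, paralog], "x": [cand]}
        meta = _meta([("f", "gf", "s1", "eukaryote"), ("x", "gx", "s2", "eukaryote")])
        cache = ScoreCache()
        group = compile_core_group(query, proteomes, meta, cache=cache)
        accepted = final_search(group, proteomes["x"], proteomes["f"], cache=cache)
        assert accepted == []

    def test_order_invariance(self, small_dataset, small_survey):
        ds = small_dataset
        cache = ScoreCache()
        rbf = sorted(small_survey.groups)[0]
        group = small_survey.groups[rbf]
        taxon = sorted(t for t in ds.proteomes if t != ds.focal_taxon)[0]
        fwd = final_search(group, ds.proteomes[taxon], ds.proteomes[ds.focal_taxon],
                           cache=cache)
        rev = final_search(group, ds.proteomes[taxon][::-1],
                           ds.proteomes[ds.focal_taxon][::-1], cache=cache)
        assert {r.protein_id for r in fwd} == {r.protein_id for r in rev}

    def test_raising_floor_never_adds_candidates(self, small_dataset, small_survey):
        ds = small_dataset
        cache = ScoreCache()
        rbf = sorted(small_survey.groups)[0]
        group = small_survey.groups[rbf]
        for taxon in sorted(ds.proteomes)[:4]:
            lo = final_search(group, ds.proteomes[taxon], ds.proteomes[ds.focal_taxon],
                              SearchConfig(score_floor=50.0), cache)
            hi = final_search(group, ds.proteomes[taxon], ds.proteomes[ds.focal_taxon],
                              SearchConfig(score_floor=120.0), cache)
            assert {r.protein_id for r in hi} <= {r.protein_id for r in lo}


class TestCoorthologRule:
    def test_single_candidate(self):
        rng = random.Random(4)
        q = ProteinRecord("f_q", "f", _rand_seq(rng))
        c = ProteinRecord("x_c", "x", _mutated(rng, q.sequence, 10))
        a = assign_coorthologs([c], q)
        assert a.representative.protein_id == "x_c"
        assert a.co_orthologs == []
        assert a.copy_count == 1

    def test_strict_inequality_boundary(self):
        """Hand-set distances: 0.20 < 0.30 accepts, 0.30 == 0.30 rejects."""
        rng = random.Random(5)
        q = ProteinRecord("f_q", "f", _rand_seq(rng))
        rep = ProteinRecord("x_a", "x", _mutated(rng, q.sequence, 5))
        c2 = ProteinRecord("x_b", "x", _mutated(rng, q.sequence, 8))
        table = {("x_a", "f_q"): 0.30, ("x_b", "x_a"): 0.20, ("x_b", "f_q"): 0.50}

        def dist(a, b):
            return table.get((a.protein_id, b.protein_id),
                             table.get((b.protein_id, a.protein_id), 1.0))

        a = assign_coorthologs([rep, c2], q, distance=dist)
        assert [c.protein_id for c, _ in a.co_orthologs] == ["x_b"]
        table[("x_b", "x_a")] = 0.30   # exactly equal: strict rule rejects
        a = assign_coorthologs([rep, c2], q, distance=dist)
        assert a.co_orthologs == []

    def test_planted_duplication_yields_coortholog(self):
        """Both copies of a duplication below the target taxon come back."""
        from phyloprof.simulate import make_dataset
        recovered = 0
        n = 12
        for seed in range(n):
            root, dup_at = _root_and_nonfocal_node(seed)
            ds = make_dataset(n_species=8, n_supertaxa=2, n_archaeal=0,
                              n_bacterial=0, n_lineages=2, loss_rate=0.0,
                              dup_rate=0.0, seq_length=150, seed=100 + seed,
                              forced_origins={0: root},
                              forced_duplications={0: dup_at})
            res = run_ortholog_survey(ds.query_records(), ds.proteomes, ds.meta)
            frame = res.frame()
            prov = ds.truth.provenance.set_index("protein_id")["label"]
            dup_node, _ = ds.truth.histories["L0001"].duplication_events[0]
            taxa_with_two = [t for t in ds.tree.leaves
                             if ds.truth.copy_number.at["L0001", t] == 2]
            hits = frame[(frame.rbf_id == "t001_L0001")
                         & frame.taxon_id.isin(taxa_with_two)]
            if len(hits) and (hits.n_copies == 2).all():
                recovered += 1
        assert recovered / n >= 0.9


def _root_and_nonfocal_node(seed):
    """The tree root and a non-focal-path internal node for dup planting."""
    from phyloprof.simulate import generate_species_tree
    tree, _ = generate_species_tree(8, 2, seed=100 + seed)
    fpath = set(tree.focal_root_path())
    for node in tree.postorder():
        if node in fpath or tree.is_leaf(node):
            continue
        if len(tree.leaves_under(node)) >= 2:
            return tree.root, node
    raise AssertionError("no suitable node")


class TestSurvey:
    def test_zero_queries(self, small_dataset):
        ds = small_dataset
        res = run_ortholog_survey([], ds.proteomes, ds.meta)
        assert res.frame().empty

    def test_focal_taxon_rows(self, small_dataset, small_survey):
        ds = small_dataset
        frame = small_survey.frame()
        focal_rows = frame[frame.taxon_id == ds.focal_taxon]
        assert set(focal_rows.rbf_id) == set(q.protein_id for q in ds.query_records())
        assert (focal_rows.representative_id == focal_rows.rbf_id).all()

    def test_survey_deterministic(self, small_dataset, small_survey):
        ds = small_dataset
        again = run_ortholog_survey(ds.query_records(), ds.proteomes, ds.meta)
        pd.testing.assert_frame_equal(again.frame(), small_survey.frame())
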