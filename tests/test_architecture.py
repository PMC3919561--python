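"""Domain I/O, shared-domain filter, similarity score, curation, rescue."""

import io
import random

import pandas as pd
import pytest

from phyloprof.align import ScoreCache
from phyloprof.architecture import (CurationThresholds, Feature,
                                    FeatureArchitecture, architecture_similarity,
                                    curate_candidate, flag_xenologs,
                                    level_from_evidence, read_domain_table,
                                    rescue_search, shared_domain_filter)
from phyloprof.sequences import AMINO_ACIDS, ProteinRecord

HEADER = "protein_id\tfeature_id\tclass\tstart\tend\tscore\n"


def _arch(pid, ids, length=100, cls="domain"):
    feats = [Feature(fid, cls, 10 * i + 1, 10 * i + 9, 50.0)
             for i, fid in enumerate(ids)]
    return FeatureArchitecture(pid, feats, length)


class TestDomainTable:
    def test_empty_file(self):
        archs = read_domain_table(io.StringIO(HEADER), lengths={"P1": 100})
        assert archs["P1"].features == []

    def test_single_row(self):
        archs = read_domain_table(io.StringIO(HEADER + "P1\tPF_A\tdomain\t10\t90\t50\n"))
        assert [f.feature_id for f in archs["P1"].features] == ["PF_A"]

    def test_shuffled_rows_identical(self):
        rows = [f"P{i % 3}\tPF_{j}\tdomain\t{j * 10 + 1}\t{j * 10 + 9}\t50"
                for i, j in enumerate([(x, y) for x in range(3) for y in range(4)])
                for j in [i % 4]]
        rng = random.Random(0)
        shuffled = rows[:]
        rng.shuffle(shuffled)
        a = read_domain_table(io.StringIO(HEADER + "\n".join(rows) + "\n"))
        b = read_domain_table(io.StringIO(HEADER + "\n".join(shuffled) + "\n"))
        for pid in a:
            assert [f.feature_id for f in a[pid].features] == \
                   [f.feature_id for f in b[pid].features]

    def test_bad_coordinates_report_line(self):
        with pytest.raises(ValueError, match="line 2"):
            read_domain_table(io.StringIO(HEADER + "P1\tPF_A\tdomain\t90\t10\t50\n"))

    def test_end_beyond_length(self):
        with pytest.raises(ValueError, match="beyond"):
            read_domain_table(io.StringIO(HEADER + "P1\tPF_A\tdomain\t10\t120\t50\n"),
                              lengths={"P1": 100})


def _assignment_row(rbf, taxon, accepted, scores):
    ids = ",".join(accepted)
    return {"rbf_id": rbf, "taxon_id": taxon, "representative_id": accepted[0],
            "representative_score": scores[0], "rep_query_distance": 0.2,
            "co_ortholog_ids": ",".join(accepted[1:]),
            "co_ortholog_distances": ",".join("0.1" for _ in accepted[1:]),
            "accepted_ids": ids,
            "accepted_scores": ",".join(str(s) for s in scores),
            "n_copies": len(accepted)}


class TestSharedDomainFilter:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_candidate_sharing_domain_retained(self):
        archs = {"Q": _arch("Q", ["PF_A"]), "C": _arch("C", ["PF_A", "PF_B"])}
        df = self._table([_assignment_row("Q", "x", ["C"], [100.0])])
        filtered, excl = shared_domain_filter(df, archs)
        assert len(filtered) == 1 and excl.empty

    def test_decoy_domains_excluded(self):
        archs = {"Q": _arch("Q", ["PF_A"]), "C": _arch("C", ["DEC_1"])}
        df = self._table([_assignment_row("Q", "x", ["C"], [100.0])])
        filtered, excl = shared_domain_filter(df, archs)
        assert filtered.empty and excl["Q"] == 1

    def test_domainless_query_bypasses(self):
        archs = {"Q": _arch("Q", []), "C": _arch("C", ["DEC_1"])}
        df = self._table([_assignment_row("Q", "x", ["C"], [100.0])])
        filtered, _ = shared_domain_filter(df, archs)
        assert len(filtered) == 1

    def test_focal_protein_never_removed(self):
        archs = {"Q": _arch("Q", ["PF_A"])}
        df = self._table([_assignment_row("Q", "f", ["Q"], [500.0])])
        filtered, _ = shared_domain_filter(df, archs)
        assert list(filtered.representative_id) == ["Q"]

    def test_surviving_coortholog_promoted(self):
        archs = {"Q": _arch("Q", ["PF_A"]), "C1": _arch("C1", ["DEC_1"]),
                 "C2": _arch("C2", ["PF_A"])}
        df = self._table([_assignment_row("Q", "x", ["C1", "C2"], [100.0, 80.0])])
        filtered, excl = shared_domain_filter(df, archs)
        assert list(filtered.representative_id) == ["C2"]
        assert excl["Q"] == 1

    def test_fixture_decoys_removed_true_members_kept(self, small_dataset,
                                                      small_survey,
                                                      small_architectures):
        ds = small_dataset
        prov = ds.truth.provenance.set_index("protein_id")["label"]
        filtered, _ = shared_domain_filter(small_survey.frame(),
                                           small_architectures, min_score=10.0)
        for row in filtered.itertuples(index=False):
            for pid in row.accepted_ids.split(","):
                assert prov[pid] != "decoy"
        # no true member lost relative to the raw survey
        raw_true = {(r.rbf_id, pid) for r in small_survey.frame().itertuples(index=False)
                    for pid in r.accepted_ids.split(",")
                    if prov[pid] == prov[r.rbf_id]}
        kept_true = {(r.rbf_id, pid) for r in filtered.itertuples(index=False)
                     for pid in r.accepted_ids.split(",")}
        assert raw_true <= kept_true


class TestArchitectureSimilarity:
    def test_identical_is_one(self):
        a = _arch("a", ["PF1", "PF2"], 120)
        b = _arch("b", ["PF1", "PF2"], 120)
        assert architecture_similarity(a, b) == pytest.approx(1.0)

    def test_hand_computed_subset(self):
        a = _arch("a", ["PF1", "PF2"], 100)
        b = _arch("b", ["PF1"], 100)
        assert architecture_similarity(a, b, (0.5, 0.3, 0.2)) == pytest.approx(0.60)

    def test_hand_computed_disjoint(self):
        a = _arch("a", ["PF1"], 100)
        b = _arch("b", ["PF2"], 400)
        assert architecture_similarity(a, b, (0.5, 0.3, 0.2)) == pytest.approx(0.05)

    def test_empty_vs_empty_scores_length_only(self):
        a = FeatureArchitecture("a", [], 100)
        b = FeatureArchitecture("b", [], 100)
        assert architecture_similarity(a, b) == pytest.approx(1.0)
        c = FeatureArchitecture("c", [], 50)
        assert architecture_similarity(a, c) == pytest.approx(0.5)

    def test_symmetry_and_bounds(self):
        rng = random.Random(1)
        pool = [f"PF{i}" for i in range(6)]
        for _ in range(50):
            a = _arch("a", [rng.choice(pool) for _ in range(rng.randint(0, 5))],
                      rng.randint(50, 300))
            b = _arch("b", [rng.choice(pool) for _ in range(rng.randint(0, 5))],
                      rng.randint(50, 300))
            sab = architecture_similarity(a, b)
            assert 0.0 <= sab <= 1.0
            assert sab == pytest.approx(architecture_similarity(b, a))

    def test_weight_validation(self):
        a = _arch("a", ["PF1"], 100)
        with pytest.raises(ValueError):
            architecture_similarity(a, a, (-0.1, 0.6, 0.5))


def _focal_set(rng, n=6, length=120):
    return [ProteinRecord(f"f_p{i}", "f",
                          "".join(rng.choice(AMINO_ACIDS) for _ in range(length)))
            for i in range(n)]


class TestCuration:
    def test_identical_candidate_level_1(self):
        rng = random.Random(2)
        focal = _focal_set(rng)
        rbf = focal[0]
        cand = ProteinRecord("x_c", "x", rbf.sequence)
        archs = {rbf.protein_id: _arch(rbf.protein_id, ["PF_Q"], 120)}
        rec = curate_candidate(cand, rbf.protein_id, focal, archs,
                               candidate_arch=_arch("x_c", ["PF_Q"], 120))
        assert rec.level == 1
        assert rec.best_hit_id == rbf.protein_id

    def test_comparable_runner_up_gives_level_2(self):
        rng = random.Random(3)
        focal = _focal_set(rng)
        # make f_p1 nearly identical to the query so scores are comparable
        twin = ProteinRecord("f_twin", "f", focal[0].sequence[:-1] + "A")
        focal = focal + [twin]
        cand = ProteinRecord("x_c", "x", focal[0].sequence)
        archs = {focal[0].protein_id: _arch(focal[0].protein_id, ["PF_Q"], 120)}
        rec = curate_candidate(cand, focal[0].protein_id, focal, archs,
                               candidate_arch=_arch("x_c", ["PF_Q"], 120))
        assert rec.level == 2
        assert rec.n_comparable >= 1

    def test_level_from_evidence_matrix(self):
        t = CurationThresholds()
        assert level_from_evidence(True, True, 0, 1, t) == 1
        assert level_from_evidence(True, True, 0, 5, t) == 2   # arch in (r_high, r_mid]
        assert level_from_evidence(True, False, 2, 1, t) == 2  # few comparable
        assert level_from_evidence(True, False, 6, 9, t) == 3  # many comparable
        assert level_from_evidence(True, False, 6, 11, t) == 4
        assert level_from_evidence(False, False, 0, 1, t) == 4

    def test_unknown_rbf_rejected(self):
        rng = random.Random(4)
        focal = _focal_set(rng)
        cand = ProteinRecord("x_c", "x", focal[0].sequence)
        with pytest.raises(KeyError):
            curate_candidate(cand, "nope", focal, {})

    def test_levels_recomputable_from_evidence(self, small_dataset, small_survey):
        """Stored level always equals the rubric applied to the stored evidence."""
        ds = small_dataset
        prok = set(ds.meta.loc[ds.meta.domain_of_life != "eukaryote", "taxon_id"])
        cache = ScoreCache()
        by_id = {r.protein_id: r for recs in ds.proteomes.values() for r in recs}
        import io as _io
        from phyloprof.architecture import read_domain_table
        lengths = {r.protein_id: len(r) for recs in ds.proteomes.values() for r in recs}
        archs = read_domain_table(_io.StringIO(ds.domains.to_csv(sep="\t", index=False)),
                                  lengths=lengths)
        n = 0
        for row in small_survey.frame().itertuples(index=False):
            if row.taxon_id not in prok:
                continue
            for pid in row.accepted_ids.split(","):
                rec = curate_candidate(by_id[pid], row.rbf_id,
                                       ds.proteomes[ds.focal_taxon], archs,
                                       cache=cache)
                assert rec.level == level_from_evidence(
                    rec.rbf_is_best, rec.rbf_is_unique_best, rec.n_comparable,
                    rec.arch_rank)
                n += 1
        assert n > 0


class TestRescue:
    def test_empty_missing_list(self):
        rng = random.Random(5)
        focal = _focal_set(rng)
        out = rescue_search([], [], focal, {})
        assert out.empty

    def test_architecture_only_candidate_tagged_F(self):
        rng = random.Random(6)
        focal = _focal_set(rng)
        rbf = focal[0]
        archs = {rbf.protein_id: _arch(rbf.protein_id, ["PF_Q", "PF_R"], 120),
                 "x_far": _arch("x_far", ["PF_Q", "PF_R"], 120)}
        # sequence unrelated, architecture identical
        far = ProteinRecord("x_far", "x",
                            "".join(rng.choice(AMINO_ACIDS) for _ in range(120)))
        out = rescue_search([far], [rbf.protein_id], focal, archs)
        assert list(out.evidence) == ["F"]

    def test_true_ortholog_recovered_with_both_tags(self):
        rng = random.Random(7)
        focal = _focal_set(rng)
        rbf = focal[0]
        seq = list(rbf.sequence)
        for pos in rng.sample(range(len(seq)), 15):
            seq[pos] = rng.choice([c for c in AMINO_ACIDS if c != seq[pos]])
        ortho = ProteinRecord("x_o", "x", "".join(seq))
        archs = {rbf.protein_id: _arch(rbf.protein_id, ["PF_Q"], 120),
                 "x_o": _arch("x_o", ["PF_Q"], 120)}
        out = rescue_search([ortho], [rbf.protein_id], focal, archs)
        assert list(out.evidence) == ["F/B"]


class TestXenologs:
    META = pd.DataFrame({
        "taxon_id": ["e1", "e2", "a1", "b1"],
        "genus": ["g1", "g2", "g3", "g4"],
        "supertaxon": ["SE", "SE", "SA", "SB"],
        "domain_of_life": ["eukaryote", "eukaryote", "archaeon", "bacterium"],
    })

    def _presence(self, **cols):
        return pd.DataFrame({t: {"Q": v} for t, v in cols.items()})

    def test_euk_plus_bacteria_flagged(self):
        p = self._presence(e1=1, e2=0, a1=0, b1=1)
        assert flag_xenologs(p, self.META) == {"Q"}

    def test_all_three_domains_not_flagged(self):
        p = self._presence(e1=1, e2=0, a1=1, b1=1)
        assert flag_xenologs(p, self.META) == set()

    def test_eukaryote_only_not_flagged(self):
        p = self._presence(e1=1, e2=1, a1=0, b1=0)
        assert flag_xenologs(p, self.META) == set()

    def test_untrusted_bacterial_candidate_ignored(self):
        p = self._presence(e1=1, e2=0, a1=0, b1=1)
        cur = pd.DataFrame({"rbf_id": ["Q"], "taxon_id": ["b1"], "level": [4],
                            "candidate_id": ["b1_c"]})
        assert flag_xenologs(p, self.META, cur) == set()
        cur["level"] = [2]
        assert flag_xenologs(p, self.META, cur) == {"Q"}
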