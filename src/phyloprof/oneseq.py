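"""Iterative core-ortholog-group compilation and the final ortholog survey.

For every focal-species query protein the search proceeds in two phases.

Phase 1 — core group compilation.  The group starts as the query alone; its
single-sequence profile is searched against every other proteome and the
candidate aligning best to the query joins the group (iteration 1).  In
iterations 2..n the group is re-aligned, the profile re-trained, and only
taxa not yet in the reference set are searched; candidates from genera
already represented are dropped (this drives taxonomic diversity into the
group), and the candidate with the highest average pairwise alignment score
against the current members is added.  Iterations with no surviving
candidate are skipped.  A final profile is trained on the finished group.

Phase 2 — ortholog search.  The final profile is searched against each
proteome; hits above the score floor are accepted only if reciprocal: the
hit's best local-alignment partner in the focal proteome must be the query
itself (ties count, provided the query is among the tied best).  Among
accepted candidates the one scoring highest against the query is the
*representative*; any other candidate c is kept as a co-ortholog iff

    d(c, representative) < d(representative, query)      (strictly),

with d the normalized score distance — the classic in-paralog rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from .align import (ProfileModel, ScoreCache, build_msa, build_profile,
                    profile_search)
from .sequences import ProteinRecord

__all__ = ["SearchConfig", "CoreOrthologGroup", "OrthologAssignment",
           "compile_core_group", "final_search", "assign_coorthologs",
           "run_ortholog_survey", "SurveyResult", "assignments_frame"]


@dataclass(frozen=True)
class SearchConfig:
    n_iterations: int = 5
    score_floor: float = 50.0         # log2-odds bits a profile hit must exceed
    max_hits_per_taxon: int = 5       # candidate shortlist per proteome
    pseudocount: float = 1.0
    max_gap_fraction: float = 0.5
    gap_open: float = 11.0
    gap_extend: float = 1.0
    matrix: str = "BLOSUM62"

    def aligner_kw(self) -> dict:
        return dict(matrix=self.matrix, gap_open=self.gap_open,
                    gap_extend=self.gap_extend)


@dataclass
class CoreOrthologGroup:
    query: ProteinRecord
    members: list                     # query first
    reference_taxa: set
    profile: ProfileModel | None = None
    iteration_log: list = field(default_factory=list)

    def validate(self) -> None:
        assert self.members and self.members[0].protein_id == self.query.protein_id
        assert self.reference_taxa == {m.taxon_id for m in self.members}


@dataclass
class OrthologAssignment:
    rbf_id: str
    taxon_id: str
    representative: ProteinRecord
    representative_score: float       # local score vs the query
    rep_query_distance: float
    co_orthologs: list                # (ProteinRecord, distance to representative)
    accepted: list                    # (ProteinRecord, score vs query) all accepted

    @property
    def copy_count(self) -> int:
        return 1 + len(self.co_orthologs)


class ConfigurationError(ValueError):
    pass


def _train(members, config: SearchConfig, iteration: int) -> ProfileModel:
    msa = build_msa(members, **config.aligner_kw())
    return build_profile(msa, pseudocount_weight=config.pseudocount,
                         max_gap_fraction=config.max_gap_fraction,
                         gap_open=config.gap_open, gap_extend=config.gap_extend,
                         source_id=members[0].protein_id, iteration=iteration)


def compile_core_group(query: ProteinRecord, proteomes: Mapping[str, Sequence[ProteinRecord]],
                       meta: pd.DataFrame, config: SearchConfig = SearchConfig(),
                       cache: ScoreCache | None = None) -> CoreOrthologGroup:
    """Compile the core ortholog group for one query (see module docstring).

    The genus filter applies from iteration 2 onward; iteration 1 picks the
    globally best-aligning candidate regardless of genus.
    """
    focal = query.taxon_id
    if focal not in proteomes:
        raise ConfigurationError(f"no proteome for the focal taxon {focal!r}")
    if cache is None:
        cache = ScoreCache(**config.aligner_kw())
    genus_of = dict(zip(meta["taxon_id"], meta["genus"]))
    group = CoreOrthologGroup(query, [query], {focal})
    by_id = {rec.protein_id: rec
             for recs in proteomes.values() for rec in recs}
    for it in range(1, config.n_iterations + 1):
        profile = _train(group.members, config, it)
        candidates = []  # (record,) best profile hit per unsearched taxon
        for taxon in sorted(proteomes):
            if taxon in group.reference_taxa:
                continue
            if it > 1 and genus_of.get(taxon) in {genus_of.get(t) for t in group.reference_taxa}:
                continue
            hits = profile_search(profile, proteomes[taxon], top_k=1,
                                  score_floor=config.score_floor)
            if hits:
                candidates.append(by_id[hits[0][0]])
        entry = {"iteration": it, "n_candidates": len(candidates)}
        if not candidates:
            entry["added"] = None
            group.iteration_log.append(entry)
            continue
        if it == 1:
            scored = [(cache.score(c, query), c) for c in candidates]
        else:
            scored = [(sum(cache.score(c, m) for m in group.members) / len(group.members), c)
                      for c in candidates]
        # deterministic tie-break: highest score, then lexicographic id
        best_score = max(s for s, _ in scored)
        best = min((c for s, c in scored if s == best_score),
                   key=lambda c: c.protein_id)
        group.members.append(best)
        group.reference_taxa.add(best.taxon_id)
        entry["added"] = best.protein_id
        entry["score"] = best_score
        group.iteration_log.append(entry)
        group.validate()
    group.profile = _train(group.members, config, config.n_iterations + 1)
    return group


def final_search(group: CoreOrthologGroup, proteome: Sequence[ProteinRecord],
                 focal_proteome: Sequence[ProteinRecord],
                 config: SearchConfig = SearchConfig(),
                 cache: ScoreCache | None = None) -> list:
    """Profile hits in one proteome that are reciprocal to the query.

    Returns accepted :class:`ProteinRecord` objects ordered by profile score
    (descending, ties lexicographic).  An empty list means no ortholog.
    """
    if group.profile is None:
        raise ConfigurationError("core group has no trained profile")
    if cache is None:
        cache = ScoreCache(**config.aligner_kw())
    by_id = {r.protein_id: r for r in proteome}
    hits = profile_search(group.profile, proteome,
                          top_k=config.max_hits_per_taxon,
                          score_floor=config.score_floor)
    query = group.query
    accepted = []
    for pid, _score in hits:
        cand = by_id[pid]
        back = [(cache.score(cand, f), f.protein_id) for f in focal_proteome]
        best_back = max(s for s, _ in back)
        best_ids = {fid for s, fid in back if s == best_back}
        if query.protein_id in best_ids:
            accepted.append(cand)
    return accepted


def assign_coorthologs(accepted: Sequence[ProteinRecord], query: ProteinRecord,
                       cache: ScoreCache | None = None,
                       distance: Callable[[ProteinRecord, ProteinRecord], float] | None = None,
                       config: SearchConfig = SearchConfig()) -> OrthologAssignment:
    """Pick the representative and apply the strict co-ortholog rule."""
    if not accepted:
        raise ValueError("no accepted candidates")
    if cache is None:
        cache = ScoreCache(**config.aligner_kw())
    if distance is None:
        distance = cache.distance
    scored = sorted(((cache.score(c, query), c) for c in accepted),
                    key=lambda sc: (-sc[0], sc[1].protein_id))
    rep_score, rep = scored[0]
    d_rep_query = distance(rep, query)
    cos = []
    for s, c in scored[1:]:
        d = distance(c, rep)
        if d < d_rep_query:
            cos.append((c, d))
    return OrthologAssignment(query.protein_id, accepted[0].taxon_id, rep,
                              rep_score, d_rep_query, cos,
                              [(c, s) for s, c in scored])


@dataclass
class SurveyResult:
    assignments: list                 # OrthologAssignment
    groups: dict                      # rbf_id -> CoreOrthologGroup
    per_taxon_counts: pd.Series       # orthologous queries per taxon
    per_query_counts: pd.Series       # taxa with an ortholog per query

    def frame(self) -> pd.DataFrame:
        return assignments_frame(self.assignments)


def assignments_frame(assignments: Sequence[OrthologAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append({
            "rbf_id": a.rbf_id,
            "taxon_id": a.taxon_id,
            "representative_id": a.representative.protein_id,
            "representative_score": a.representative_score,
            "rep_query_distance": a.rep_query_distance,
            "co_ortholog_ids": ",".join(c.protein_id for c, _ in a.co_orthologs),
            "co_ortholog_distances": ",".join(f"{d:.6g}" for _, d in a.co_orthologs),
            "accepted_ids": ",".join(c.protein_id for c, _ in a.accepted),
            "accepted_scores": ",".join(f"{s:.6g}" for _, s in a.accepted),
            "n_copies": a.copy_count,
        })
    cols = ["rbf_id", "taxon_id", "representative_id", "representative_score",
            "rep_query_distance", "co_ortholog_ids", "co_ortholog_distances",
            "accepted_ids", "accepted_scores", "n_copies"]
    return pd.DataFrame(rows, columns=cols)


def run_ortholog_survey(queries: Sequence[ProteinRecord],
                        proteomes: Mapping[str, Sequence[ProteinRecord]],
                        meta: pd.DataFrame, config: SearchConfig = SearchConfig(),
                        progress: Callable[[str], None] | None = None) -> SurveyResult:
    """Full survey: one core group + search per query, across all proteomes.

    Deterministic given inputs and configuration; proteome iteration order
    is sorted and every tie-break is lexicographic.
    """
    focal_taxa = {q.taxon_id for q in queries}
    if len(focal_taxa) > 1:
        raise ConfigurationError(f"queries span several taxa: {sorted(focal_taxa)}")
    cache = ScoreCache(**config.aligner_kw())
    assignments = []
    groups = {}
    for query in sorted(queries, key=lambda q: q.protein_id):
        if progress:
            progress(query.protein_id)
        group = compile_core_group(query, proteomes, meta, config, cache)
        groups[query.protein_id] = group
        focal_proteome = proteomes[query.taxon_id]
        for taxon in sorted(proteomes):
            accepted = final_search(group, proteomes[taxon], focal_proteome,
                                    config, cache)
            if accepted:
                assignments.append(assign_coorthologs(accepted, query, cache,
                                                      config=config))
    frame = assignments_frame(assignments)
    if len(frame):
        per_taxon = frame.groupby("taxon_id")["rbf_id"].nunique()
        per_query = frame.groupby("rbf_id")["taxon_id"].nunique()
    else:
        per_taxon = pd.Series(dtype=int)
        per_query = pd.Series(dtype=int)
    return SurveyResult(assignments, groups, per_taxon, per_query)
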