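"""Feature architectures: domain I/O, shared-domain filter, similarity score,
curation rubric, rescue search and xenolog flagging.

A *feature architecture* is the linear arrangement of a protein's annotated
features — functional domains, transmembrane segments, low-complexity
regions, secondary-structure elements.  Orthology is an evolutionary
statement, not a functional one; the operations here add the functional
evidence layer: candidates that share no annotated domain with the focal
protein are excluded, and candidates in distant clades are scored by an
explicit curation rubric combining reverse sequence search ranks with
architecture-similarity ranks.

The architecture similarity is a three-term convex combination

    score = w_set * J + w_order * O + w_len * L

with J the multiset Jaccard index of feature ids, O the length of the
longest common subsequence of the two feature-id sequences divided by the
longer sequence, and L the ratio of the shorter to the longer protein
length.  Two proteins with no features at all are compared by length alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import ScoreCache
from .sequences import ProteinRecord

__all__ = [
    "Feature", "FeatureArchitecture", "read_domain_table",
    "shared_domain_filter", "architecture_similarity",
    "CurationThresholds", "CurationRecord", "curate_candidate",
    "level_from_evidence", "rescue_search", "flag_xenologs",
]

FEATURE_CLASSES = ("domain", "transmembrane", "low_complexity", "secondary_structure")


@dataclass(frozen=True)
class Feature:
    feature_id: str
    feature_class: str
    start: int      # 1-based inclusive
    end: int
    score: float = 0.0


@dataclass
class FeatureArchitecture:
    protein_id: str
    features: list = field(default_factory=list)   # sorted by (start, end)
    length: int | None = None

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.start > f.end:
                raise ValueError(f"{self.protein_id}: feature {f.feature_id} start > end")
            if self.length is not None and f.end > self.length:
                raise ValueError(f"{self.protein_id}: feature {f.feature_id} "
                                 f"ends beyond protein length")

    def domain_ids(self, min_score: float | None = None) -> Counter:
        """Multiset of domain-class feature ids (optionally significance-filtered)."""
        return Counter(f.feature_id for f in self.features
                       if f.feature_class == "domain"
                       and (min_score is None or f.score >= min_score))

    def feature_sequence(self) -> list:
        return [f.feature_id for f in self.features]


def read_domain_table(source, lengths: Mapping[str, int] | None = None) -> dict:
    """Read a feature-annotation TSV into per-protein architectures.

    Expected columns: protein_id, feature_id, class, start, end, score.
    Rows are validated individually; a bad coordinate reports its line.
    Proteins present in ``lengths`` but absent from the table get an empty
    architecture.
    """
    df = pd.read_csv(source, sep="\t")
    required = ["protein_id", "feature_id", "class", "start", "end", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"domain table missing columns: {missing}")
    df = df.rename(columns={"class": "feature_class"})
    archs: dict = {}
    lengths = dict(lengths or {})
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        start, end = int(row.start), int(row.end)
        if start > end:
            raise ValueError(f"domain table line {i}: start {start} > end {end}")
        plen = lengths.get(row.protein_id)
        if plen is not None and end > plen:
            raise ValueError(f"domain table line {i}: end {end} beyond protein "
                             f"length {plen} of {row.protein_id}")
        feat = Feature(str(row.feature_id), str(row.feature_class), start, end,
                       float(row.score))
        archs.setdefault(row.protein_id, []).append(feat)
    out = {pid: FeatureArchitecture(pid, feats, lengths.get(pid))
           for pid, feats in archs.items()}
    for pid, plen in lengths.items():
        if pid not in out:
            out[pid] = FeatureArchitecture(pid, [], plen)
    return out


def _arch_of(architectures: Mapping[str, FeatureArchitecture], pid: str,
             length: int | None = None) -> FeatureArchitecture:
    arch = architectures.get(pid)
    if arch is None:
        arch = FeatureArchitecture(pid, [], length)
    return arch


def shared_domain_filter(assignments: pd.DataFrame,
                         architectures: Mapping[str, FeatureArchitecture],
                         min_score: float | None = None):
    """Drop candidates that share no significant domain with their focal query.

    Queries whose focal protein carries no annotated (significant) domain
    bypass the filter entirely.  If a row's representative is excluded but a
    co-ortholog survives, the surviving candidate with the best recorded
    score against the query becomes the representative.  Returns
    ``(filtered assignments, per-query exclusion counts)``.
    """
    rows = []
    excluded: Counter = Counter()
    for row in assignments.to_dict("records"):
        rbf = row["rbf_id"]
        query_doms = set(_arch_of(architectures, rbf).domain_ids(min_score))
        if not query_doms:          # domain-less query: nothing to compare against
            rows.append(row)
            continue
        ids = row["accepted_ids"].split(",") if row["accepted_ids"] else []
        scores = [float(s) for s in row["accepted_scores"].split(",")] if row["accepted_scores"] else []
        keep = []
        for pid, s in zip(ids, scores):
            cand_doms = set(_arch_of(architectures, pid).domain_ids(min_score))
            if pid == rbf or (cand_doms & query_doms):
                keep.append((pid, s))
            else:
                excluded[rbf] += 1
        if not keep:
            continue
        keep_ids = {pid for pid, _ in keep}
        new = dict(row)
        best = max(s for _, s in keep)
        rep = min(pid for pid, s in keep if s == best)
        new["representative_id"], new["representative_score"] = rep, best
        if rep == row["representative_id"]:
            cos = [c for c in row["co_ortholog_ids"].split(",") if c and c in keep_ids]
            dists = [d for c, d in zip(row["co_ortholog_ids"].split(","),
                                       row["co_ortholog_distances"].split(","))
                     if c and c in keep_ids]
        else:
            # representative changed: keep surviving candidates, distances unknown
            cos = sorted(keep_ids - {rep})
            dists = []
        new["co_ortholog_ids"] = ",".join(cos)
        new["co_ortholog_distances"] = ",".join(dists)
        new["accepted_ids"] = ",".join(pid for pid, _ in keep)
        new["accepted_scores"] = ",".join(f"{s:.6g}" for _, s in keep)
        new["n_copies"] = 1 + len(cos)
        rows.append(new)
    filtered = pd.DataFrame(rows, columns=assignments.columns)
    return filtered, pd.Series(excluded, dtype=int).sort_index()


def _lcs_len(a: Sequence[str], b: Sequence[str]) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        curr = [0]
        for j, y in enumerate(b, start=1):
            curr.append(prev[j - 1] + 1 if x == y else max(prev[j], curr[j - 1]))
        prev = curr
    return prev[-1]


def architecture_similarity(a: FeatureArchitecture, b: FeatureArchitecture,
                            weights: tuple = (0.5, 0.3, 0.2)) -> float:
    """Three-term architecture similarity in [0, 1] (see module docstring)."""
    w_set, w_order, w_len = weights
    if min(weights) < 0:
        raise ValueError("weights must be nonnegative")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    la = a.length if a.length is not None else (a.features[-1].end if a.features else 0)
    lb = b.length if b.length is not None else (b.features[-1].end if b.features else 0)
    if la and lb:
        L = min(la, lb) / max(la, lb)
    else:
        L = 1.0 if la == lb else 0.0
    ca, cb = Counter(f.feature_id for f in a.features), Counter(f.feature_id for f in b.features)
    if not ca and not cb:
        return L
    inter = sum((ca & cb).values())
    union = sum((ca | cb).values())
    J = inter / union if union else 0.0
    sa, sb = a.feature_sequence(), b.feature_sequence()
    O = _lcs_len(sa, sb) / max(len(sa), len(sb)) if (sa or sb) else 0.0
    return float(w_set * J + w_order * O + w_len * L)


# -- curation ----------------------------------------------------------------

@dataclass(frozen=True)
class CurationThresholds:
    comparable_frac: float = 0.10   # within 10% of the best score is "comparable"
    r_high: int = 3                 # high-ranking architecture rank
    r_mid: int = 10                 # still-acceptable architecture rank
    f_max: int = 3                  # few comparable runner-ups


@dataclass
class CurationRecord:
    candidate_id: str
    taxon_id: str
    rbf_id: str
    best_hit_id: str
    best_score: float
    n_comparable: int               # non-query proteins within comparable_frac of best
    rbf_is_best: bool               # query reaches the maximal sequence score
    rbf_is_unique_best: bool        # ... and no other protein ties or comes close
    arch_rank: int                  # 1-based rank of the query by architecture similarity
    arch_top_score: float
    level: int
    evidence: str = ""              # 'B', 'F' or 'F/B' when set by a rescue search


def level_from_evidence(rbf_is_best: bool, rbf_is_unique_best: bool,
                        n_comparable: int, arch_rank: int,
                        thresholds: CurationThresholds = CurationThresholds()) -> int:
    """The deterministic 4-level confidence rubric.

    Level 1 (trust): unique best sequence hit and a high-ranking
    architecture.  Level 2 (possible): a handful of comparable sequence
    hits, or a slightly lower architecture rank.  Level 3 (questionable):
    many comparable hits while the architecture does not clearly vote for
    the query.  Level 4 (not trustworthy): everything else.
    """
    t = thresholds
    if rbf_is_unique_best and n_comparable == 0 and arch_rank <= t.r_high:
        return 1
    if rbf_is_best and 1 <= n_comparable <= t.f_max:
        return 2
    if rbf_is_best and n_comparable == 0 and t.r_high < arch_rank <= t.r_mid:
        return 2
    if rbf_is_best and n_comparable > t.f_max and arch_rank <= t.r_mid:
        return 3
    return 4


def curate_candidate(candidate: ProteinRecord, rbf_id: str,
                     focal_proteome: Sequence[ProteinRecord],
                     architectures: Mapping[str, FeatureArchitecture],
                     candidate_arch: FeatureArchitecture | None = None,
                     thresholds: CurationThresholds = CurationThresholds(),
                     arch_weights: tuple = (0.5, 0.3, 0.2),
                     cache: ScoreCache | None = None) -> CurationRecord:
    """Score one candidate against the whole focal proteome and assign a level."""
    if cache is None:
        cache = ScoreCache()
    focal_ids = {r.protein_id for r in focal_proteome}
    if rbf_id not in focal_ids:
        raise KeyError(f"{rbf_id!r} is not in the focal proteome")
    if candidate_arch is None:
        candidate_arch = _arch_of(architectures, candidate.protein_id, len(candidate))
    seq_scores = {r.protein_id: cache.score(candidate, r) for r in focal_proteome}
    best_score = max(seq_scores.values())
    best_ids = sorted(pid for pid, s in seq_scores.items() if s == best_score)
    floor = (1.0 - thresholds.comparable_frac) * best_score
    comparable = [pid for pid, s in seq_scores.items()
                  if pid != rbf_id and s >= floor]
    rbf_is_best = seq_scores[rbf_id] == best_score
    rbf_is_unique_best = rbf_is_best and best_ids == [rbf_id]
    lengths = {r.protein_id: len(r) for r in focal_proteome}
    arch_scores = {r.protein_id: architecture_similarity(
        candidate_arch, _arch_of(architectures, r.protein_id, lengths[r.protein_id]),
        arch_weights) for r in focal_proteome}
    rbf_arch = arch_scores[rbf_id]
    arch_rank = 1 + sum(1 for s in arch_scores.values() if s > rbf_arch)
    level = level_from_evidence(rbf_is_best, rbf_is_unique_best, len(comparable),
                                arch_rank, thresholds)
    return CurationRecord(candidate.protein_id, candidate.taxon_id, rbf_id,
                          best_ids[0], best_score, len(comparable), rbf_is_best,
                          rbf_is_unique_best, arch_rank, max(arch_scores.values()),
                          level)


def curation_frame(records: Iterable[CurationRecord]) -> pd.DataFrame:
    cols = ["candidate_id", "taxon_id", "rbf_id", "level", "best_hit_id", "best_score",
            "n_comparable", "rbf_is_best", "rbf_is_unique_best", "arch_rank",
            "arch_top_score", "evidence"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)


# -- rescue search -----------------------------------------------------------

def rescue_search(proteome: Sequence[ProteinRecord], missing_rbfs: Sequence[str],
                  focal_proteome: Sequence[ProteinRecord],
                  architectures: Mapping[str, FeatureArchitecture],
                  seq_min_score: float = 80.0, arch_min_sim: float = 0.7,
                  arch_weights: tuple = (0.5, 0.3, 0.2),
                  cache: ScoreCache | None = None) -> pd.DataFrame:
    """Joint sequence + architecture search for queries missing in one taxon.

    Two complementary routes: (B) reverse-validated sequence hits — the best
    forward hit above ``seq_min_score`` whose own best partner in the focal
    proteome is the query; (F) proteins whose architecture similarity to the
    query exceeds ``arch_min_sim``.  Candidates found by both routes are
    tagged F/B, as a joint architecture+sequence search reports them.
    """
    if cache is None:
        cache = ScoreCache()
    by_id = {r.protein_id: r for r in focal_proteome}
    rows = []
    for rbf in sorted(missing_rbfs):
        query = by_id.get(rbf)
        if query is None:
            raise KeyError(f"missing query {rbf!r} not in the focal proteome")
        qarch = _arch_of(architectures, rbf, len(query))
        seq_hits = set()
        fwd = sorted(((cache.score(query, p), p.protein_id) for p in proteome),
                     key=lambda sp: (-sp[0], sp[1]))
        for s, pid in fwd:
            if s < seq_min_score:
                break
            cand = next(p for p in proteome if p.protein_id == pid)
            back_best = max(cache.score(cand, f) for f in focal_proteome)
            back_ids = {f.protein_id for f in focal_proteome
                        if cache.score(cand, f) == back_best}
            if rbf in back_ids:
                seq_hits.add(pid)
        arch_hits = set()
        for p in proteome:
            parch = _arch_of(architectures, p.protein_id, len(p))
            if architecture_similarity(qarch, parch, arch_weights) > arch_min_sim:
                arch_hits.add(p.protein_id)
        for pid in sorted(seq_hits | arch_hits):
            tag = "F/B" if pid in (seq_hits & arch_hits) else ("B" if pid in seq_hits else "F")
            rows.append({"rbf_id": rbf, "candidate_id": pid, "evidence": tag})
    return pd.DataFrame(rows, columns=["rbf_id", "candidate_id", "evidence"])


# -- xenolog flagging ---------------------------------------------------------

def flag_xenologs(presence: pd.DataFrame, meta: pd.DataFrame,
                  curation: pd.DataFrame | None = None,
                  trusted_levels: tuple = (1, 2)) -> set:
    """Queries present in eukaryotes and bacteria but absent from archaea.

    ``presence`` is a boolean (or count) matrix query x taxon.  When a
    curation table is given, prokaryotic presence only counts through
    candidates curated at a trusted level; without one, raw presence is
    used.  Such eukaryote+bacteria patterns are candidate horizontal
    transfers rather than genes vertically inherited from the universal
    ancestor.
    """
    dom_of = dict(zip(meta["taxon_id"], meta["domain_of_life"]))
    trusted: dict = {}
    if curation is not None and len(curation):
        ok = curation[curation["level"].isin(trusted_levels)]
        for rbf, group in ok.groupby("rbf_id"):
            trusted[rbf] = set(group["taxon_id"])
    flagged = set()
    bool_presence = presence.astype(bool)
    for rbf, row in bool_presence.iterrows():
        euk = arc = bac = False
        for taxon, present in row.items():
            if not present:
                continue
            dom = dom_of[taxon]
            if dom == "eukaryote":
                euk = True
                continue
            if curation is not None and taxon not in trusted.get(rbf, ()):
                continue
            if dom == "archaeon":
                arc = True
            elif dom == "bacterium":
                bac = True
        if euk and bac and not arc:
            flagged.add(rbf)
    return flagged
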