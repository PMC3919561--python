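"""Pairwise alignment, score distances, star MSAs and position-specific profiles.

Pairwise alignment is standard Smith–Waterman / Needleman–Wunsch with
BLOSUM62 and affine gaps (open 11, extend 1 — the first gap residue costs
the open penalty, each further residue the extension), delegated to
Biopython's :class:`PairwiseAligner`.

The profile model replaces a profile HMM with a deterministic position-
specific log-odds matrix: per retained alignment column, log2 of the
pseudocount-smoothed residue frequency over a uniform 1/20 background.
Columns with more than 50% gaps are dropped.  Searching a profile against a
proteome is local alignment of the profile against each sequence with the
same affine gap penalties, implemented as a numba-compiled kernel.

The normalized score distance used throughout is

    d(a, b) = 1 - S(a, b) / min(S(a, a), S(b, b)),   clipped into [0, 1],

with S the local alignment score.  It satisfies identity and symmetry but
not the triangle inequality; it is a ranking device, not a metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from numba import njit

from .sequences import AMINO_ACIDS, ProteinRecord

__all__ = [
    "AlignmentResult", "pairwise_align", "alignment_score", "ScoreCache",
    "score_distance", "MSA", "build_msa", "ProfileModel", "build_profile",
    "profile_search",
]

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

_AA_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(AMINO_ACIDS):
    _AA_INDEX[ord(_c)] = _i


def encode(sequence: str) -> np.ndarray:
    """Map a sequence to 0..19 indices over the canonical alphabet."""
    idx = _AA_INDEX[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (idx < 0).any():
        raise ValueError("sequence contains residues outside the 20-letter alphabet")
    return idx


def _make_aligner(mode: str, matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load(matrix)
    al.open_gap_score = -float(gap_open)
    al.extend_gap_score = -float(gap_extend)
    if mode not in ("local", "global"):
        raise ValueError(f"mode must be 'local' or 'global', got {mode!r}")
    al.mode = mode
    return al


_ALIGNERS: dict = {}


def _aligner(mode: str, matrix: str = DEFAULT_MATRIX, gap_open: float = DEFAULT_GAP_OPEN,
             gap_extend: float = DEFAULT_GAP_EXTEND) -> Align.PairwiseAligner:
    key = (mode, matrix, gap_open, gap_extend)
    if key not in _ALIGNERS:
        _ALIGNERS[key] = _make_aligner(mode, matrix, gap_open, gap_extend)
    return _ALIGNERS[key]


def _seq_of(x) -> str:
    return x.sequence if isinstance(x, ProteinRecord) else str(x)


_ENCODED: dict = {}


def _encoded(rec: ProteinRecord) -> np.ndarray:
    """Per-record memo of the integer-encoded sequence.

    Keyed by the sequence content, not the record id: equal ids with
    different sequences (e.g. two synthetic datasets in one process) must
    never share an entry.
    """
    key = (rec.protein_id, hash(rec.sequence))
    arr = _ENCODED.get(key)
    if arr is None:
        arr = encode(rec.sequence)
        _ENCODED[key] = arr
    return arr


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    pairs: tuple  # ((i, j), ...) aligned 0-based coordinate pairs


def alignment_score(a, b, mode: str = "local", **kw) -> float:
    """Optimal alignment score only (fast path)."""
    sa, sb = _seq_of(a), _seq_of(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    return float(_aligner(mode, **kw).score(sa, sb))


def pairwise_align(a, b, mode: str = "local", **kw) -> AlignmentResult:
    """Optimal pairwise alignment: score plus aligned coordinate pairs."""
    sa, sb = _seq_of(a), _seq_of(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    al = _aligner(mode, **kw)
    score = float(al.score(sa, sb))
    pairs: list = []
    if mode == "local" and score <= 0:
        return AlignmentResult(max(score, 0.0), ())
    aln = al.align(sa, sb)[0]
    for (astart, aend), (bstart, bend) in zip(*aln.aligned):
        pairs.extend((i, j) for i, j in zip(range(astart, aend), range(bstart, bend)))
    return AlignmentResult(score, tuple(pairs))


class ScoreCache:
    """Memoizes symmetric local alignment scores between protein records."""

    def __init__(self, mode: str = "local", **kw):
        self.mode = mode
        self.kw = kw
        self._scores: dict = {}
        self._seqs: dict = {}

    def _key(self, a: ProteinRecord, b: ProteinRecord):
        # include sequence hashes: record ids alone are not unique across datasets
        ka = (a.protein_id, hash(a.sequence))
        kb = (b.protein_id, hash(b.sequence))
        return (ka, kb) if ka <= kb else (kb, ka)

    def score(self, a: ProteinRecord, b: ProteinRecord) -> float:
        key = self._key(a, b)
        s = self._scores.get(key)
        if s is None:
            s = alignment_score(a, b, self.mode, **self.kw)
            self._scores[key] = s
        return s

    def self_score(self, a: ProteinRecord) -> float:
        return self.score(a, a)

    def distance(self, a: ProteinRecord, b: ProteinRecord) -> float:
        return score_distance(a, b, cache=self)


def score_distance(a: ProteinRecord, b: ProteinRecord, cache: ScoreCache | None = None) -> float:
    """Normalized local-score distance in [0, 1]; 0 iff self-identical scoring."""
    if cache is None:
        cache = ScoreCache()
    s_ab = cache.score(a, b)
    s_min = min(cache.self_score(a), cache.self_score(b))
    if s_min <= 0:  # cannot happen for nonempty canonical sequences under BLOSUM62
        return 1.0
    return float(min(1.0, max(0.0, 1.0 - s_ab / s_min)))


# -- multiple alignment -----------------------------------------------------

@dataclass
class MSA:
    ids: list
    rows: list  # equal-length strings with '-' gaps

    def __post_init__(self):
        if not self.rows:
            raise ValueError("empty alignment")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("ragged alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


def build_msa(members: Sequence[ProteinRecord], **kw) -> MSA:
    """Star-progressive multiple alignment anchored on the first member.

    Every non-anchor member is globally aligned to the anchor; insertions
    relative to the anchor open new columns shared by all rows ("once a gap,
    always a gap").  Every input residue appears exactly once in its row.
    """
    if not members:
        raise ValueError("need at least one sequence")
    anchor = members[0].sequence
    la = len(anchor)
    # per member: residue-or-gap at each anchor position, plus insertions keyed
    # by the anchor position they precede (la = after the last position)
    aligned_rows: list = []
    insert_rows: list = []
    for m in members[1:]:
        res = pairwise_align(anchor, m.sequence, mode="global", **kw)
        row = ["-"] * la
        ins: dict = {}
        prev_a = prev_b = 0
        seq = m.sequence
        blocks = list(res.pairs)
        # walk matched coordinate pairs; unmatched member residues become insertions
        for i, j in blocks:
            if j > prev_b:
                ins[i] = ins.get(i, "") + seq[prev_b:j]
            row[i] = seq[j]
            prev_a, prev_b = i + 1, j + 1
        if prev_b < len(seq):
            ins[la] = ins.get(la, "") + seq[prev_b:]
        aligned_rows.append(row)
        insert_rows.append(ins)
    ins_width = [0] * (la + 1)
    for ins in insert_rows:
        for pos, s in ins.items():
            ins_width[pos] = max(ins_width[pos], len(s))
    out_rows = []
    # anchor row
    parts = []
    for p in range(la + 1):
        parts.append("-" * ins_width[p])
        if p < la:
            parts.append(anchor[p])
    out_rows.append("".join(parts))
    for row, ins in zip(aligned_rows, insert_rows):
        parts = []
        for p in range(la + 1):
            s = ins.get(p, "")
            parts.append(s + "-" * (ins_width[p] - len(s)))
            if p < la:
                parts.append(row[p])
        out_rows.append("".join(parts))
    return MSA([m.protein_id for m in members], out_rows)


# -- profile model ----------------------------------------------------------

@dataclass
class ProfileModel:
    """Position-specific log-odds matrix over the 20 amino acids."""

    matrix: np.ndarray          # (n_columns, 20) log2-odds
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    source_id: str = ""
    iteration: int = 0

    @property
    def n_columns(self) -> int:
        return int(self.matrix.shape[0])

    def max_score(self) -> float:
        """Upper bound: per-column best residue, summed (gap-free)."""
        return float(self.matrix.max(axis=1).sum())

    def score(self, sequence) -> float:
        if isinstance(sequence, ProteinRecord):
            seq = _encoded(sequence)
        else:
            seq = encode(str(sequence))
        if seq.size == 0:
            return 0.0
        return float(_sw_profile(self.matrix, seq,
                                 float(self.gap_open), float(self.gap_extend)))


def build_profile(msa: MSA, pseudocount_weight: float = 1.0,
                  max_gap_fraction: float = 0.5,
                  gap_open: float = DEFAULT_GAP_OPEN,
                  gap_extend: float = DEFAULT_GAP_EXTEND,
                  source_id: str = "", iteration: int = 0) -> ProfileModel:
    """Log-odds profile from an alignment, uniform background, pseudocounts.

    Columns whose gap fraction exceeds ``max_gap_fraction`` are dropped.
    """
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    nrow = len(msa.rows)
    bg = 1.0 / 20.0
    cols = []
    for c in range(msa.n_columns):
        column = [r[c] for r in msa.rows]
        gaps = column.count("-")
        if gaps / nrow > max_gap_fraction:
            continue
        counts = np.zeros(20, dtype=np.float64)
        for ch in column:
            if ch != "-":
                counts[_AA_INDEX[ord(ch)]] += 1
        n_obs = counts.sum()
        # blend the observed column frequencies with the background so the
        # profile depends on row proportions, not on row multiplicity
        freqs = (counts / n_obs + pseudocount_weight * bg) / (1.0 + pseudocount_weight)
        cols.append(np.log2(freqs / bg))
    if not cols:
        raise ValueError("degenerate profile: every column exceeded the gap threshold")
    return ProfileModel(np.asarray(cols, dtype=np.float64), gap_open, gap_extend,
                        source_id, iteration)


@njit(cache=True)
def _sw_profile(M, seq, gap_open, gap_extend):  # pragma: no cover - jit body
    L = M.shape[0]
    n = seq.shape[0]
    h_prev = np.zeros(n + 1, dtype=np.float64)
    e_col = np.full(n + 1, -1e30)   # gap in sequence (profile column consumed)
    best = 0.0
    for i in range(1, L + 1):
        h_curr = np.zeros(n + 1, dtype=np.float64)
        f = -1e30                   # gap in profile (sequence residue consumed)
        Mi = M[i - 1]
        for j in range(1, n + 1):
            e = h_prev[j] - gap_open
            e2 = e_col[j] - gap_extend
            if e2 > e:
                e = e2
            e_col[j] = e
            f2 = h_curr[j - 1] - gap_open
            f3 = f - gap_extend
            if f3 > f2:
                f2 = f3
            f = f2
            h = h_prev[j - 1] + Mi[seq[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            h_curr[j] = h
            if h > best:
                best = h
        h_prev = h_curr
    return best


def profile_search(profile: ProfileModel, proteome: Sequence[ProteinRecord],
                   top_k: int | None = None, score_floor: float | None = None) -> list:
    """Score every protein against the profile; ranked (protein_id, score).

    Descending by score, ties broken lexicographically by protein id.  An
    empty proteome yields an empty list.
    """
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    hits = [(rec.protein_id, profile.score(rec)) for rec in proteome]
    if score_floor is not None:
        hits = [h for h in hits if h[1] > score_floor]
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits if top_k is None else hits[:top_k]
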