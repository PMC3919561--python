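# Methods

## Overview

`phyloprof` reconstructs the evolutionary history of a protein pathway from
the perspective of one *focal species* (the motivating case is the ~255
ribosome biogenesis factors, RBFs, of *Saccharomyces cerevisiae* traced
across eukaryotes, archaea and bacteria).  The pipeline has five inference
layers, each exposed as a library module and as a CLI stage:

1. **Ortholog survey** (`oneseq`): per query, an iteratively compiled core
   ortholog group trains a position-specific profile; the profile is
   searched against every proteome and hits are accepted if reciprocal.
2. **Domain-architecture filtering and curation** (`architecture`):
   candidates must share at least one annotated domain with the query;
   prokaryotic candidates receive a 4-level confidence rating from a
   reproducible rubric.
3. **Profiling** (`profiling`): presence/copy-number matrices, supertaxon
   aggregation at three stringencies, Dollo-parsimony ancestral
   inventories, phylostratum assignment.
4. **Paralogy** (`paralogy`): in-paralog clustering against species of
   increasing distance detects paralogous query pairs and dates their
   duplications; union–find collapses queries into lineages.
5. **Synthetic data** (`simulate`): a generative model with planted gene
   histories that makes every inference step testable against ground truth.

## The ortholog search model

**Core group compilation.** Iteration 1 initializes the group with the query
and searches all other proteomes with the single-sequence profile; the
candidate with the best local alignment to the query joins.  Iterations
2..5 re-align the group (star-progressive MSA anchored on the query),
re-train the profile, search only taxa outside the reference set, discard
candidates whose genus is already represented (this forces taxonomic
breadth), and add the candidate with the highest *average* pairwise score
against all current members.  Iterations that produce no candidate above
the score floor are skipped, so groups for young genes stay small — a gene
confined to the focal genus legitimately yields a group of size 1.

**Profile model.** The profile HMM of HMMER-based pipelines is replaced by
a deterministic log-odds matrix: per retained alignment column (columns
with > 50% gaps are dropped), the observed residue frequencies are blended
with a uniform 1/20 background,

    f(a) = (freq_obs(a) + w/20) / (1 + w),      score(a) = log2(20 * f(a)),

with pseudocount weight `w = 1` by default.  Blending *frequencies* rather
than counts makes the profile invariant to duplicated alignment rows.
Profile-to-sequence search is local Smith–Waterman with affine gaps (open
11, extend 1), implemented as a numba kernel; scores are in log2-odds units
("bits").

**Score floor.** Profile hits must exceed `score_floor = 50` bits.  Some
floor is essential: a local alignment of *any* sequence to *any* profile
has a nonnegative optimum, so with a floor of zero every proteome returns a
"best hit" and core groups absorb random proteins for every young gene.  On
the default synthetic conditions unrelated proteins score ≤ ~30 bits while
true orthologs — even at the largest planted divergences — score several
hundred, so 50 separates the two regimes with a wide margin on either side.
This plays the role of the E-value significance threshold that an
hmmsearch-based pipeline applies implicitly.  It is configurable, and the
survey is monotone in it: raising the floor never adds an accepted
candidate.

**Reciprocity.** A profile hit is accepted only if its best local-alignment
partner in the focal proteome is the query itself (ties allowed when the
query is among the tied best) — best-reciprocal-hit-to-the-seed, the
classic guard against capturing a different family's members.

**Representative and co-orthologs.** Among accepted candidates of one
taxon, the highest scorer against the query is the representative.  Another
candidate c is a co-ortholog iff d(c, rep) < d(rep, query) *strictly*, with

    d(a, b) = 1 − S(a, b) / min(S(a, a), S(b, b))  ∈ [0, 1]

the normalized local-score distance (S = BLOSUM62 local score).  d
satisfies identity and symmetry but not the triangle inequality; it is a
ranking device.  The underlying distance notion in the literature this rule
comes from is not pinned to a formula, so this concrete stand-in is a
documented choice and the rule accepts any injected distance function for
sensitivity analysis.

## Domain filter, curation rubric, rescue, xenologs

The shared-domain filter keeps a candidate iff its significant domain-class
feature ids intersect the query's; queries with no (significant) annotated
domain bypass the filter, matching the treatment of domain-less proteins in
comparable studies.  Domain hits below `domain_min_score = 10` are ingested
but ignored by the filter.

Architecture similarity is `0.5·J + 0.3·O + 0.2·L`: multiset Jaccard of
feature ids, longest-common-subsequence fraction of the feature order, and
the shorter/longer protein length ratio.  Two featureless proteins are
compared by length alone, so identical architectures of equal length always
score 1.

The curation rubric replaces case-by-case visual judgment with fixed
thresholds (all configurable): "comparable" = within 10% of the best
reverse-search score; architecture ranks `R_high = 3`, `R_mid = 10`; at most
`F_max = 3` comparable runner-ups.  Level 1 = unique best sequence hit and
architecture rank ≤ R_high; level 2 = few comparable runner-ups, or best
sequence hit with architecture rank in (R_high, R_mid]; level 3 = many
comparable hits with architecture rank still ≤ R_mid; level 4 = everything
else.  Levels are a pure function of the recorded evidence, so every stored
level can be re-derived from its `CurationRecord`.

The rescue search unions (B) reverse-validated sequence hits above a raw
score of 80 — random same-length pairs score ~40–55, true orthologs
hundreds — with (F) proteins whose architecture similarity to the missing
query exceeds 0.7, tagging candidates B, F or F/B.

Xenolog flagging marks queries present in eukaryotes and bacteria with no
trusted (level-1/2) archaeal candidate: the pattern expected from a
horizontal acquisition rather than vertical descent from the universal
ancestor.

## Dollo parsimony and strata

Under Dollo parsimony a gene is gained once and only lost thereafter, so an
ortholog in any species implies presence in that species' common ancestor
with the focal species.  The Dollo state is the union of focal-to-bearer
paths; the phylostratum is the state's oldest node on the focal-root path.
This is a *minimum* age: losses can hide the oldest witnesses but can never
make a gene look older.  Supertaxon aggregation is strict (> 25%, > 50% of
subsumed species; "any" means ≥ 1), and the even-cardinality median of copy
numbers takes the lower central value — both deterministic conventions.
Presence for profiling uses post-domain-filter assignments by default; a
flag (`prefilter_profiles`) recomputes profiles from the raw survey for
comparison.  Stratum assignment additionally drops prokaryotic bearers
without a trusted curation level, mirroring the age adjustment that
curation exists for.

## Paralogy

In-paralog clustering between the query set and one other proteome seeds
groups with reciprocal best hits and attaches a protein to a seed group iff
its distance to the same-side seed is strictly below the seed-pair
distance.  Seed pairs must additionally reach an alignment score of 100
(configurable): a reciprocal best hit always exists, even between unrelated
proteomes, so an unfiltered seed is not evidence of homology — the original
two-species clustering tools apply exactly such a bit-score cutoff.

Comparison species are visited in order of increasing topological distance
(decreasing depth of the MRCA with the focal leaf).  The *first* species
that co-clusters two queries dates their duplication: it must have happened
after that split, so the recorded node is the focal-path node immediately
below the MRCA — the latest point consistent with the evidence.  More
distant witnesses only confirm the pair and never re-date it, which makes
the dating trivially monotone.  Domain-composition pairs (identical domain
multisets, confirmed by a sequence-distance ceiling of 0.7 in place of a
full phylogenetic reconstruction) carry no witness and are layered at the
younger member's stratum.

## The synthetic-data model

`simulate` is first-class, tested code, not a fixture dump.  It emulates:

* a random rooted species tree (default 40 species, 6 supertaxa, genera of
  2 consecutive siblings, 1 archaeal + 1 bacterial clade arranged as
  (bacteria, (archaea, eukaryotes)));
* per-lineage origins drawn from the focal-root path (uniform by default),
  losses sampled independently per branch below the origin at
  `loss_rate = 0.1` (never on the origin→focal path, so the focal copy is
  guaranteed without biasing other branches), duplications at
  `dup_rate = 0.02` whose daughters evolve as separately labeled lineages
  below the duplication node and share the primary copy's loss fate;
* sequences of 200 residues with two 40-residue domain blocks, evolved by
  Poisson-distributed uniform substitutions (linkers 0.05/site/branch,
  domains 0.01 — a Jukes–Cantor-like model on amino acids, no indels, no
  rate heterogeneity);
* 5 decoy proteins per taxon with domains from a disjoint namespace, so the
  expected behavior of the shared-domain filter is computable exactly.

What the generator does **not** emulate — realistic substitution matrices,
indels, domain gain/loss, rate variation across lineages, annotation error
— bounds what green tests mean: they validate the inference logic under a
clean signal, not performance on real proteomes.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` recompute, from scratch:

* **Dollo oracle equivalence** — `dollo_state` vs an explicit path-union
  oracle on all bearer subsets of 6-leaf trees (the test suite enumerates
  every rooted binary 6-leaf topology) and 200 random 12-leaf cases.
* **Alignment oracle equivalence** — the DP score vs exhaustive enumeration
  of monotone matchings with affine gap charges, on all length combinations
  up to 8 over a reduced alphabet, local and global.
* **End-to-end origin recovery** — the default 40-species / 50-lineage
  study, `loss_rate` 0 and 0.2 (duplications off so each query labels one
  lineage): with no losses the detected presence matrix must equal the
  planted truth cell-for-cell and every stratum the planted origin; with
  losses, strata must never be older than the origin and mostly equal it.
  Detection in these conditions is exact, so any shortfall at loss 0.2 is
  the irreducible Dollo effect: lost witnesses cannot be counted.  The
  fixed test seed is 7; across seeds the Dollo-on-truth recovery spans
  roughly 68–84%.
* **Co-ortholog rule** — hand-computed accept/reject triads including the
  strict-inequality boundary, exercised through an injected distance.
* **Duplication recovery** — 20 replicates with a duplication planted on
  the focal terminal branch of a 12-species tree; the pair must be found,
  dated to that node, and be the only pair reported.
* **Stringency monotonicity** and the strict 4/16-species boundary, and
  **curation determinism** (stored level == rubric(evidence)) on every
  curated synthetic candidate.

Problem sizes were chosen so the full suite and the acceptance script each
run comfortably on a single CPU: the two full surveys are the dominant cost
(a few minutes each); all other checks are seconds.

## Numerical and degenerate-input conventions

* All tie-breaks are lexicographic by protein/taxon id; iteration orders
  are sorted; the pipeline is deterministic given inputs and configuration.
* Local alignment scores are floored at 0 (the empty alignment); gap cost
  is open + (len−1)·extend, matching the alignment backend.
* The distance is clipped into [0, 1]; self-scores are always positive for
  nonempty canonical sequences under BLOSUM62.
* Single-leaf trees, single-sequence groups, empty proteomes, empty
  assignment tables and featureless architectures are all defined, not
  errors; malformed Newick, duplicate labels, non-monophyletic supertaxa,
  invalid coordinates and unknown configuration keys fail loudly at load
  time.

## Known limitations

* The profile model has no insert/delete states or E-value statistics; the
  score floor is a raw-bits heuristic calibrated to the synthetic regime
  and should be revisited for real proteomes with heterogeneous lengths.
* The score distance is not metric; co-ortholog and in-paralog decisions
  near the strict boundary are sensitive to alignment score granularity.
* Duplication dating is topological and bounded by taxon sampling: with no
  sampled species between two focal-path nodes, those dates are
  indistinguishable.
* The curation rubric deliberately omits the visual dot-plot judgment used
  in manual curation practice; borderline level-2/3 assignments will differ
  from a human curator's.
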