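"""Stage orchestration: load inputs, run stages, persist every intermediate.

Each stage writes plain TSV files under the output directory and can be
re-run from the previous stage's files, so partial re-runs reproduce
identical downstream results.  All stage functions are deterministic given
inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import ScoreCache
from .architecture import (curate_candidate, curation_frame, flag_xenologs,
                           read_domain_table, shared_domain_filter)
from .config import PipelineConfig
from .oneseq import run_ortholog_survey
from .paralogy import collapse_lineages, detect_pairs, domain_composition_pairs
from .profiling import (ancestral_inventories, assign_strata,
                        build_presence_matrix, coortholog_stats,
                        supertaxon_counts, supertaxon_profile)
from .sequences import read_proteome_dir
from .treeops import parse_newick, read_taxon_meta, validate_tree_meta

log = logging.getLogger("phyloprof")

__all__ = ["PipelineInputs", "load_inputs", "run_pipeline",
           "stage_survey", "stage_filter", "stage_curate", "stage_profile",
           "stage_strata", "stage_paralogs", "stage_report"]


@dataclass
class PipelineInputs:
    tree: object
    meta: pd.DataFrame
    proteomes: dict
    queries: pd.DataFrame
    architectures: dict
    config: PipelineConfig
    cache: ScoreCache = field(default=None)

    @property
    def focal_taxon(self) -> str:
        return self.tree.focal_leaf

    def query_records(self) -> list:
        wanted = set(self.queries["protein_id"])
        return [r for r in self.proteomes[self.focal_taxon] if r.protein_id in wanted]


def load_inputs(config: PipelineConfig, basedir: str | Path = ".") -> PipelineInputs:
    basedir = Path(basedir)
    meta = read_taxon_meta(basedir / config.meta_file)
    queries = pd.read_csv(basedir / config.query_file, sep="\t", dtype=str)
    if "protein_id" not in queries.columns:
        raise ValueError("query table needs a protein_id column")
    proteomes = read_proteome_dir(basedir / config.proteome_dir)
    focal = config.focal_taxon
    if not focal:
        qids = set(queries["protein_id"])
        candidates = [t for t, recs in proteomes.items()
                      if qids & {r.protein_id for r in recs}]
        if len(candidates) != 1:
            raise ValueError("cannot infer the focal taxon; set focal_taxon")
        focal = candidates[0]
    tree = parse_newick((basedir / config.tree_file).read_text(), focal_leaf=focal)
    validate_tree_meta(tree, meta)
    lengths = {r.protein_id: len(r) for recs in proteomes.values() for r in recs}
    architectures = read_domain_table(basedir / config.domain_file, lengths=lengths)
    cache = ScoreCache(matrix=config.matrix, gap_open=config.gap_open,
                       gap_extend=config.gap_extend)
    return PipelineInputs(tree, meta, proteomes, queries, architectures, config, cache)


def _save(df: pd.DataFrame, outdir: Path, name: str, index: bool = False) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / name, sep="\t", index=index)


_LIST_COLUMNS = ["co_ortholog_ids", "co_ortholog_distances",
                 "accepted_ids", "accepted_scores"]


def load_assignments(path) -> pd.DataFrame:
    """Re-load a persisted assignment table with stable column types."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     float_precision="round_trip",
                     converters={c: str for c in _LIST_COLUMNS})
    return df


# -- stages ------------------------------------------------------------------

def stage_survey(inputs: PipelineInputs, outdir: Path) -> pd.DataFrame:
    log.info("survey: %d queries x %d proteomes", len(inputs.queries), len(inputs.proteomes))
    result = run_ortholog_survey(inputs.query_records(), inputs.proteomes,
                                 inputs.meta, inputs.config.search_config(),
                                 progress=lambda q: log.debug("query %s", q))
    frame = result.frame()
    _save(frame, outdir, "assignments.tsv")
    _save(result.per_taxon_counts.rename("n_queries").to_frame(), outdir,
          "per_taxon_counts.tsv", index=True)
    return frame


def stage_filter(inputs: PipelineInputs, assignments: pd.DataFrame, outdir: Path):
    filtered, exclusions = shared_domain_filter(
        assignments, inputs.architectures, min_score=inputs.config.domain_min_score)
    log.info("domain filter: %d -> %d assignment rows", len(assignments), len(filtered))
    _save(filtered, outdir, "assignments_filtered.tsv")
    _save(exclusions.rename("n_excluded").to_frame(), outdir, "exclusions.tsv", index=True)
    return filtered


def stage_curate(inputs: PipelineInputs, filtered: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    """Curate every accepted candidate found in an archaeal or bacterial taxon."""
    cfg = inputs.config
    dom_of = dict(zip(inputs.meta["taxon_id"], inputs.meta["domain_of_life"]))
    focal_proteome = inputs.proteomes[inputs.focal_taxon]
    by_id = {r.protein_id: r for recs in inputs.proteomes.values() for r in recs}
    records = []
    for row in filtered.itertuples(index=False):
        if dom_of.get(row.taxon_id) == "eukaryote":
            continue
        ids = row.accepted_ids.split(",") if row.accepted_ids else []
        for pid in ids:
            records.append(curate_candidate(
                by_id[pid], row.rbf_id, focal_proteome, inputs.architectures,
                thresholds=cfg.curation_thresholds(),
                arch_weights=cfg.arch_weights(), cache=inputs.cache))
    frame = curation_frame(records)
    log.info("curation: %d prokaryotic candidates", len(frame))
    _save(frame, outdir, "curation.tsv")
    return frame


def stage_profile(inputs: PipelineInputs, assignments: pd.DataFrame, outdir: Path):
    cfg = inputs.config
    rbf_ids = sorted(inputs.queries["protein_id"])
    matrix = build_presence_matrix(assignments, rbf_ids,
                                   sorted(inputs.proteomes), inputs.focal_taxon)
    profile = supertaxon_profile(matrix, inputs.meta)
    counts = supertaxon_counts(profile)
    medians = coortholog_stats(matrix, inputs.meta,
                               include_absent=cfg.median_include_absent)
    _save(matrix, outdir, "presence.tsv", index=True)
    _save(profile, outdir, "supertaxon_profile.tsv")
    _save(counts, outdir, "supertaxon_counts.tsv", index=True)
    _save(medians, outdir, "coortholog_medians.tsv")
    return matrix, profile


def curated_presence(matrix: pd.DataFrame, meta: pd.DataFrame,
                     curation: pd.DataFrame, trusted_levels=(1, 2)) -> pd.DataFrame:
    """Zero out prokaryotic cells whose candidates were not curated as trusted."""
    dom_of = dict(zip(meta["taxon_id"], meta["domain_of_life"]))
    trusted = set()
    if len(curation):
        ok = curation[curation["level"].isin(trusted_levels)]
        trusted = set(zip(ok["rbf_id"], ok["taxon_id"]))
    out = matrix.copy()
    for taxon in out.columns:
        if dom_of.get(taxon) == "eukaryote":
            continue
        for rbf in out.index:
            if out.at[rbf, taxon] and (rbf, taxon) not in trusted:
                out.at[rbf, taxon] = 0
    return out


def stage_strata(inputs: PipelineInputs, matrix: pd.DataFrame,
                 curation: pd.DataFrame, outdir: Path):
    cfg = inputs.config
    adjusted = curated_presence(matrix, inputs.meta, curation)
    strata = assign_strata(inputs.tree, adjusted)
    xeno = flag_xenologs(matrix, inputs.meta, curation)
    table = strata.to_frame()
    table["xenolog"] = ["#" if r in xeno else "" for r in table.index]
    inv_sp = ancestral_inventories(inputs.tree, adjusted)
    inv_rows = [{"node": n, "n_rbfs": len(s), "rbf_ids": ",".join(sorted(s))}
                for n, s in sorted(inv_sp.items())]
    inv_st = ancestral_inventories(inputs.tree, adjusted, inputs.meta,
                                   level="supertaxon", stringency="any")
    inv_st_rows = [{"node": n, "n_rbfs": len(s), "rbf_ids": ",".join(sorted(s))}
                   for n, s in sorted(inv_st.items())]
    _save(table, outdir, "strata.tsv", index=True)
    _save(pd.DataFrame(inv_rows), outdir, "inventories_species.tsv")
    _save(pd.DataFrame(inv_st_rows), outdir, "inventories_supertaxon.tsv")
    return table, adjusted


def stage_paralogs(inputs: PipelineInputs, strata_table: pd.DataFrame, outdir: Path):
    cfg = inputs.config
    records = inputs.query_records()
    others = {t: recs for t, recs in inputs.proteomes.items()
              if t != inputs.focal_taxon}
    pairs = detect_pairs(records, others, inputs.tree, inputs.cache,
                         min_seed_score=cfg.paralog_min_seed_score)
    pairs += domain_composition_pairs(records, inputs.architectures, pairs,
                                      distance_ceiling=cfg.paralog_distance_ceiling,
                                      min_score=cfg.domain_min_score,
                                      cache=inputs.cache)
    strata = strata_table["stratum"].to_dict()
    lineages, counts, layers = collapse_lineages(strata, pairs, inputs.tree)
    lin_frame = pd.DataFrame([{"lineage_id": l.lineage_id,
                               "members": ",".join(l.members),
                               "origin_node": l.origin_node} for l in lineages])
    _save(layers, outdir, "paralog_pairs.tsv")
    _save(lin_frame, outdir, "lineages.tsv")
    _save(counts, outdir, "stratum_counts.tsv", index=True)
    return lineages, counts, layers


def stage_report(inputs: PipelineInputs, outdir: Path) -> None:
    """Assemble summary tables from stage outputs already on disk."""
    label_of = dict(zip(inputs.queries["protein_id"],
                        inputs.queries.get("rbf_id", inputs.queries["protein_id"])))
    counts = pd.read_csv(outdir / "supertaxon_counts.tsv", sep="\t", index_col=0)
    _save(counts, outdir, "report_supertaxon_counts.tsv", index=True)
    inv = pd.read_csv(outdir / "inventories_supertaxon.tsv", sep="\t")
    _save(inv[["node", "n_rbfs"]], outdir, "report_ancestral_counts.tsv")
    strata = pd.read_csv(outdir / "strata.tsv", sep="\t", index_col=0,
                         keep_default_na=False)
    strata["rbf_label"] = [label_of.get(i, i) for i in strata.index]
    _save(strata, outdir, "report_strata.tsv", index=True)
    cur_path = outdir / "curation.tsv"
    if cur_path.exists():
        cur = pd.read_csv(cur_path, sep="\t")
        if len(cur):
            pivot = cur.pivot_table(index="rbf_id", columns="taxon_id",
                                    values="level", aggfunc="min")
            _save(pivot.fillna(0).astype(int), outdir,
                  "report_prokaryote_candidates.tsv", index=True)
        else:
            _save(pd.DataFrame(), outdir, "report_prokaryote_candidates.tsv")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, basedir: str | Path = ".") -> Path:
    """Execute every stage in order and write a run manifest."""
    basedir = Path(basedir)
    outdir = basedir / config.outdir
    inputs = load_inputs(config, basedir)
    stage = "survey"
    try:
        assignments = stage_survey(inputs, outdir)
        stage = "filter"
        filtered = stage_filter(inputs, assignments, outdir)
        stage = "curate"
        curation = stage_curate(inputs, filtered, outdir)
        stage = "profile"
        source = assignments if config.prefilter_profiles else filtered
        matrix, _ = stage_profile(inputs, source, outdir)
        stage = "strata"
        strata_table, _ = stage_strata(inputs, matrix, curation, outdir)
        stage = "paralogs"
        stage_paralogs(inputs, strata_table, outdir)
        stage = "report"
        stage_report(inputs, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest = {
        "config": {k: getattr(config, k) for k in vars(config)},
        "outputs": {p.name: _checksum(p) for p in sorted(outdir.glob("*.tsv"))},
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
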