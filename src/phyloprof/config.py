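"""Pipeline configuration: flat key/value file, CLI overrides, strict keys.

The configuration file is a flat YAML mapping (one ``key: value`` per
line).  Unknown keys are a load-time error so typos never silently fall
back to defaults.  Precedence: CLI flags > file > defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .architecture import CurationThresholds
from .oneseq import SearchConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # paths
    proteome_dir: str = "fasta"
    tree_file: str = "tree.nwk"
    meta_file: str = "meta.tsv"
    query_file: str = "queries.tsv"
    domain_file: str = "domains.tsv"
    outdir: str = "results"
    focal_taxon: str = ""            # empty: taken from the query table

    # search parameters
    n_iterations: int = 5
    score_floor: float = 50.0
    max_hits_per_taxon: int = 5
    pseudocount: float = 1.0
    max_gap_fraction: float = 0.5
    gap_open: float = 11.0
    gap_extend: float = 1.0
    matrix: str = "BLOSUM62"

    # architecture / curation
    domain_min_score: float = 10.0   # significance floor for domain hits
    arch_w_set: float = 0.5
    arch_w_order: float = 0.3
    arch_w_len: float = 0.2
    comparable_frac: float = 0.10
    r_high: int = 3
    r_mid: int = 10
    f_max: int = 3
    rescue_seq_min_score: float = 80.0
    rescue_arch_min_sim: float = 0.7

    # paralogy
    paralog_distance_ceiling: float = 0.7
    paralog_min_seed_score: float = 100.0

    # profiling modes
    prefilter_profiles: bool = False     # profile pre-domain-filter assignments
    median_include_absent: bool = False

    # simulation defaults (the study conditions of the synthetic fixtures)
    n_species: int = 40
    n_supertaxa: int = 6
    genus_size: int = 2
    n_archaeal: int = 1
    n_bacterial: int = 1
    n_lineages: int = 50
    loss_rate: float = 0.1
    dup_rate: float = 0.02
    seq_length: int = 200
    domain_blocks: int = 2
    domain_span: int = 40
    linker_rate: float = 0.05
    domain_rate: float = 0.01
    n_decoys: int = 5
    seed: int = 1

    def search_config(self) -> SearchConfig:
        return SearchConfig(self.n_iterations, self.score_floor,
                            self.max_hits_per_taxon, self.pseudocount,
                            self.max_gap_fraction, self.gap_open,
                            self.gap_extend, self.matrix)

    def curation_thresholds(self) -> CurationThresholds:
        return CurationThresholds(self.comparable_frac, self.r_high,
                                  self.r_mid, self.f_max)

    def arch_weights(self) -> tuple:
        return (self.arch_w_set, self.arch_w_order, self.arch_w_len)

    def simulate_kwargs(self) -> dict:
        return dict(n_species=self.n_species, n_supertaxa=self.n_supertaxa,
                    genus_size=self.genus_size, n_archaeal=self.n_archaeal,
                    n_bacterial=self.n_bacterial, n_lineages=self.n_lineages,
                    loss_rate=self.loss_rate, dup_rate=self.dup_rate,
                    seq_length=self.seq_length, domain_blocks=self.domain_blocks,
                    domain_span=self.domain_span, linker_rate=self.linker_rate,
                    domain_rate=self.domain_rate, n_decoys=self.n_decoys,
                    seed=self.seed)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a config from defaults, an optional file and CLI overrides."""
    values: dict = {}
    known = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("configuration file must be a flat key/value mapping")
        unknown = sorted(set(loaded) - set(known))
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        values.update(loaded)
    for k, v in (overrides or {}).items():
        if v is None:
            continue
        if k not in known:
            raise ValueError(f"unknown configuration key: {k}")
        values[k] = v
    return PipelineConfig(**values)
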