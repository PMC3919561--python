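"""Shared fixtures: tiny trees and a small synthetic dataset with truth."""

from __future__ import annotations

import io

import pytest

from phyloprof.architecture import read_domain_table
from phyloprof.simulate import make_dataset
from phyloprof.treeops import parse_newick


@pytest.fixture
def toy_tree():
    return parse_newick("((A,B),C);", focal_leaf="A")


@pytest.fixture(scope="session")
def small_dataset():
    """12 species / 4 supertaxa / 6 planted lineages, no losses or duplications."""
    return make_dataset(n_species=12, n_supertaxa=4, n_archaeal=1, n_bacterial=1,
                        n_lineages=6, loss_rate=0.0, dup_rate=0.0,
                        seq_length=150, seed=3)


@pytest.fixture(scope="session")
def small_architectures(small_dataset):
    lengths = {r.protein_id: len(r)
               for recs in small_dataset.proteomes.values() for r in recs}
    tsv = small_dataset.domains.to_csv(sep="\t", index=False)
    return read_domain_table(io.StringIO(tsv), lengths=lengths)


@pytest.fixture(scope="session")
def small_survey(small_dataset):
    from phyloprof.oneseq import run_ortholog_survey
    ds = small_dataset
    return run_ortholog_survey(ds.query_records(), ds.proteomes, ds.meta)
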