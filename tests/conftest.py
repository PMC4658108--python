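"""Shared fixtures: one default truth and one deep library, built once."""

from __future__ import annotations

import pytest

from mirseek import cleaning, synthetic
from mirseek.config import PipelineConfig


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def truth() -> synthetic.SimTruth:
    """Default study conditions: 10 planted hairpins, 2x2 design, 8-fold miRNA."""
    return synthetic.build_truth(seed=7)


@pytest.fixture(scope="session")
def deep_library(truth, config):
    """One library at depth 1e5 with truth labels (the discovery fixture)."""
    reads, labels = synthetic.simulate_library(truth, "young1", 100_000, seed=1,
                                               pipeline_config=config)
    return reads, labels


@pytest.fixture(scope="session")
def deep_candidates(truth, config, deep_library):
    """Candidate unique tags of the deep library (cleaned and annotated)."""
    from mirseek import annotation

    reads, _ = deep_library
    clean, stats = cleaning.clean_library(reads, config)
    tags = cleaning.collapse_unique(clean)
    db = annotation.AnnotationDB.from_fasta_records(synthetic.nonmirna_reference(truth))
    annotated = annotation.annotate_tags(tags, db, config.annot_max_mismatch)
    cand = annotated[annotated["category"] == annotation.CANDIDATE][["insert", "count"]]
    return cand, stats
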