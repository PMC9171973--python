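"""Shared fixtures: small synthetic study conditions and the full pipeline.

The session-scoped ``pipeline`` fixture runs the complete study once —
synthetic assay records through curation, nested-CV training, registry
selection and Ph-fp assembly for the 189-compound five-class benchmark
set — and is shared by the end-to-end tests so the expensive training
step happens a single time.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from phfp import builder, clustering, curation, similarity, synthetic, training
from phfp.chem import BitVector


@pytest.fixture(scope="session")
def small_config() -> synthetic.SyntheticConfig:
    """Down-scaled generator for fast unit tests (3 assays, 30 compounds)."""
    return synthetic.SyntheticConfig(
        n_targets=3, compounds_per_assay=30, class_sizes=(8, 6, 5), seed=42
    )


@pytest.fixture(scope="session")
def small_datasets(small_config):
    records = synthetic.synth_assay_records(small_config)
    pool = synthetic.synth_decoy_pool(small_config)
    cfg = synthetic.curation_config(small_config, min_actives=10)
    return curation.assemble_assays(records, pool, cutoff=5, seed=3, config=cfg)


@pytest.fixture(scope="session")
def pipeline():
    """Full study conditions: 12 assays, 5 classes sized (73,29,53,21,13)."""
    cfg = synthetic.SyntheticConfig(seed=11)
    records = synthetic.synth_assay_records(cfg)
    pool = synthetic.synth_decoy_pool(cfg)
    datasets = curation.assemble_assays(
        records, pool, cutoff=5, seed=11, config=synthetic.curation_config(cfg)
    )
    cv_results = [
        training.nested_cv(ds, "synthetic", seed=11 + i)
        for i, ds in enumerate(datasets)
    ]
    registry = training.select_models(
        cv_results, datasets, encoding="synthetic", cutoff=5
    )
    compounds, labels = synthetic.synth_nps_set(cfg)
    phfps = builder.build_phfp(compounds, registry, seed=11)
    fps = [BitVector(bits=f.bits, encoding="phfp") for f in phfps]
    sim = similarity.similarity_matrix(
        fps, "rogot_goldberg", ids=[f.molecule_id for f in phfps]
    )
    return SimpleNamespace(
        config=cfg,
        records=records,
        pool=pool,
        datasets=datasets,
        cv_results=cv_results,
        registry=registry,
        compounds=compounds,
        labels=labels,
        phfps=phfps,
        sim=sim,
    )
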