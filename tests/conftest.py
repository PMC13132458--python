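"""Shared fixtures: the reference synthetic benchmark and its embeddings.

The reference configuration (200 drugs x 150 diseases, latent rank 8,
density 0.05, encoder noise 0.3, seed 0) is generated once per session; the
heavier cross-validated runs derived from it are session-scoped too so the
protocol tests share them instead of recomputing.
"""

import numpy as np
import pytest

from ddacl import evaluation as ev
from ddacl import io_cli
from ddacl.synthetic import (
    OracleDiseaseEncoder,
    OracleDrugEncoder,
    SynthConfig,
    generate_benchmark,
)


@pytest.fixture(scope="session")
def ref_dataset():
    return generate_benchmark(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def ref_embeddings(ref_dataset):
    drug_enc = OracleDrugEncoder(ref_dataset, seed=0)
    dis_enc = OracleDiseaseEncoder(ref_dataset, seed=0)
    return io_cli.encode_all(ref_dataset.drugs, ref_dataset.diseases, drug_enc, dis_enc)


@pytest.fixture(scope="session")
def ref_pairs(ref_dataset):
    return ev.balanced_negatives(
        ref_dataset.positives,
        [d.drug_id for d in ref_dataset.drugs],
        [d.disease_id for d in ref_dataset.diseases],
        seed=0,
    )


@pytest.fixture(scope="session")
def ref_cv_report(ref_pairs, ref_embeddings):
    """Full 5-fold cross-validated run of the default pipeline, seed 0."""
    token_mats, fused = ref_embeddings
    split = ev.make_cv_folds(ref_pairs, k=5, seed=0)
    return ev.run_cv_experiment(ref_pairs, token_mats, fused,
                                ev.PipelineConfig(seed=0), split)


@pytest.fixture(scope="session")
def small_dataset():
    """A miniature benchmark for cheap I/O and CLI round trips."""
    return generate_benchmark(SynthConfig(n_drugs=40, n_diseases=30,
                                          target_density=0.1, seed=7))
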