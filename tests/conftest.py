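"""Shared fixtures: a tiny synthetic bundle for I/O tests and one
session-scoped trained model stack for the recovery/perturbation tests."""

import numpy as np
import pytest

from insuloop.experiments import (StudyConfig, build_datasets, evaluate_stack,
                                  generate_bundle, train_stack)
from insuloop.synthetic import SyntheticGrammar, simulate_genome_and_loops, simulate_variants

SEED = 7


@pytest.fixture(scope="session")
def study() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def small_grammar() -> SyntheticGrammar:
    return SyntheticGrammar(seed=SEED)


@pytest.fixture(scope="session")
def small_bundle(small_grammar):
    """A fast bundle (60 loops over 3 chromosomes) for format and contract
    tests; no model training involved."""
    bundle = simulate_genome_and_loops(small_grammar, n_chrom=3,
                                       chrom_length=450_000, n_loops=60)
    return simulate_variants(small_grammar, bundle, n_samples=8,
                             variants_per_sample=4)


@pytest.fixture(scope="session")
def trained(study):
    """The full desk-scale recovery study: simulate, build, train, evaluate.

    Trained once per session; all model-dependent tests share it.
    """
    bundle = generate_bundle(study, SEED)
    datasets = build_datasets(bundle, study, SEED + 1)
    models = train_stack(datasets, study, SEED + 2)
    metrics = evaluate_stack(models, bundle, datasets, study, SEED + 3)
    return {"study": study, "bundle": bundle, "datasets": datasets,
            "models": models, "metrics": metrics}


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
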