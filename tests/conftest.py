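"""Shared fixtures.

Heavy artifacts (the 20k-patient cohort, trained embeddings, the scenario-
grid simulation) are session-scoped so every test that needs them shares
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import claimsvec as cv

MEASURED = ["severity", "jcs_disturbed", "adl_low_admission", "sbp", "ckd"]


@pytest.fixture(scope="session")
def tiny_cohort() -> cv.SyntheticCohort:
    """Small cohort for I/O, corpus and plumbing tests."""
    spec = cv.GeneratorSpec(
        n_patients=400, vocab_size=40, n_clusters=4, seed=9,
        codes_day1_lambda=8.0,
    )
    return cv.generate_cohort(spec)


@pytest.fixture(scope="session")
def cohort20k() -> cv.SyntheticCohort:
    """The reference synthetic cohort: 20 000 patients, confounding gamma=1."""
    return cv.generate_cohort(cv.GeneratorSpec(n_patients=20_000, gamma=1.0, seed=42))


@pytest.fixture(scope="session")
def corpus20k(cohort20k):
    vocab = cv.build_vocabulary(cohort20k.claims, min_count=5)
    return cv.build_documents(cohort20k.claims, vocab)


@pytest.fixture(scope="session")
def emb50(corpus20k) -> cv.EmbeddingTable:
    """50-dimensional embeddings: the workhorse table for simulation tests."""
    return cv.train_embeddings(
        corpus20k, cv.TrainingConfig(k=50, epochs=5, min_count=5, seed=5)
    )


@pytest.fixture(scope="session")
def features50(cohort20k, emb50):
    vecs = cv.vectorize_cohort(cohort20k.claims, emb50)
    return cv.assemble_features(cohort20k.patients, vecs, cohort20k.truth)


@pytest.fixture(scope="session")
def specs50(emb50):
    return cv.default_model_specs(MEASURED, cv.embedding_columns(emb50.k))


@pytest.fixture(scope="session")
def grid_run(features50, specs50) -> cv.simulator.SimulationResults:
    """Five-scenario bias-injection grid, 20 replicates each, reduced scale."""
    return cv.run_simulation(
        features50,
        specs50,
        scenarios=cv.scenario_grid(5),
        n_reps=20,
        n_control=2000,
        n_treated=2000,
        n_boot=200,
        seed=33,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
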