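"""Shared fixtures: small and full-size synthetic cohorts with planted truth.

Session-scoped because genome construction is the slow part; tests never
mutate the returned objects.
"""
from __future__ import annotations

import numpy as np
import pytest

from ltrscope import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """40-target cohort on a 1.2 Mb genome: fast, used by unit tests."""
    params = syn.CohortParams(
        seed=1234,
        genome_length=1_200_000,
        n_target_copies=40,
        n_decoy_copies=20,
    )
    genome, copies, genes, truth = syn.build_genome(params)
    return params, genome, copies, genes, truth


@pytest.fixture(scope="session")
def small_tracks(small_cohort):
    params, _, _, _, truth = small_cohort
    return syn.simulate_tracks(truth, params)


@pytest.fixture(scope="session")
def small_counts(small_cohort):
    params, _, _, _, truth = small_cohort
    return syn.simulate_counts(truth, params)


@pytest.fixture(scope="session")
def study_cohort():
    """Default study conditions (120 targets, effect 4, dispersion 0.1,
    20% co-marked): the cohort the recovery checks run on."""
    params = syn.CohortParams(seed=20240501)
    genome, copies, genes, truth = syn.build_genome(params)
    counts = syn.simulate_counts(truth, params)
    tracks = syn.simulate_tracks(truth, params)
    return params, genome, copies, genes, truth, counts, tracks


@pytest.fixture(scope="session")
def null_cohort():
    """1000-element cohort with effect_size=1 and 6+6 replicates for
    type-I calibration of the per-copy signed-rank test."""
    params = syn.CohortParams(
        seed=555,
        genome_length=2_500_000,
        n_target_copies=1000,
        n_decoy_copies=0,
        consensus_length=300,
        effect_size=1.0,
        n_replicates=6,
        fraction_with_internal=0.0,
        frac_copies_with_gene=0.0,
        readthrough_prob=0.0,
        n_background_genes=0,
        n_confounder_genes=0,
        n_independent_decoys=0,
        guide_offset=50,
    )
    _, copies, _, truth = syn.build_genome(params)
    counts = syn.simulate_counts(truth, params)
    return params, copies, truth, counts
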