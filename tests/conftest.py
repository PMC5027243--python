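"""Shared fixtures: hand-built genomes and a small, fast synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from radsig.genome import InMemoryGenome
from radsig import synthetic_cohort as sc


@pytest.fixture
def tiny_genome() -> InMemoryGenome:
    """A 9-bp and a 6-bp chromosome with known microhomology structure."""
    return InMemoryGenome({"chrA": "AAGTAGTCC", "chrB": "GCACAT"})


def small_params(
    n_radiation: int = 4, n_naive: int = 4, chrom_length: int = 200_000
) -> sc.SimParams:
    """Scaled-down two-group parameters for fast unit tests."""
    params = sc.default_params()
    params.genome.n_chroms = 2
    params.genome.chrom_length = chrom_length
    params.tracks.timing_period = 50_000
    params.tracks.chromatin_block = 20_000
    for group in params.groups:
        group.sub_burden_median = 400.0
        group.rearrangements.min_size = 5_000
        group.rearrangements.max_size = 50_000
        group.rearrangements.balanced_mean = 2.0
        group.rearrangements.unbalanced_mean = 1.0
        group.rearrangements.artefact_mean = 2.0
        group.rearrangements.interchrom_mean = 1.0
    params.groups[0].n_samples = n_radiation
    params.groups[1].n_samples = n_naive
    return params


@pytest.fixture(scope="session")
def small_cohort() -> sc.CohortSim:
    """One small simulated cohort shared (read-only) across tests."""
    return sc.simulate_cohort(small_params(), seed=20_001)
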