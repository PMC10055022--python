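"""Shared fixtures: tiny hand-built datasets and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from hybridplan import CohortConfig, GenotypeDataset, Locus, synth_cohort, synth_myb80_locus


def make_dataset(calls, populations=None, sample_prefix="S") -> GenotypeDataset:
    """Build a dataset from a nested list of genotype codes.

    *populations* maps row index -> population label (default: all 'PopA').
    """
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = [f"{sample_prefix}{i + 1}" for i in range(n)]
    if populations is None:
        pops = {s: "PopA" for s in samples}
    elif isinstance(populations, dict):
        pops = {samples[i]: populations[i] for i in range(n)}
    else:
        pops = {samples[i]: populations[i] for i in range(n)}
    loci = [Locus(f"L{j + 1}") for j in range(m)]
    return GenotypeDataset(samples, pops, loci, calls)


@pytest.fixture(scope="session")
def small_cohort():
    """Four diverged sib-mated populations, small enough for fast tests."""
    config = CohortConfig(
        n_loci=400, pop_sizes=(8, 8, 10, 9), fst=0.5, sib_generations=2,
        missing_rate=0.0, seed=11,
    )
    ds, truth = synth_cohort(config)
    return ds, truth


@pytest.fixture(scope="session")
def myb80():
    return synth_myb80_locus(seed=5)
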