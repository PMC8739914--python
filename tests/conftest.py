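"""Shared fixtures: a small synthetic study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from mirnet import discovery, srna, synthio


@pytest.fixture(scope="session")
def small_truth():
    """A compact genome: 8 miRNA + 8 siRNA loci in 300 kb."""
    genome, truth = synthio.generate_genome_with_hairpins(
        n_mirna=8, n_sirna=8, genome_length=300_000, seed=7)
    return genome, truth


@pytest.fixture(scope="session")
def small_library(small_truth):
    genome, truth = small_truth
    stacks = synthio.generate_srna_library(
        truth, genome, depth=60_000, precision=0.9, seed=11, library_id="lib")
    return stacks


@pytest.fixture(scope="session")
def small_loci(small_truth, small_library):
    genome, truth = small_truth
    pred = srna.select_prediction_reads(list(small_library))
    loci, rejections = discovery.discover_loci(pred, genome)
    return loci, rejections, pred


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
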