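"""Shared fixtures.

The expensive session fixtures (simulated batches, the headline study)
are computed lazily on first use and shared across test modules.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from sweepnet.demography import (
    SimRegionParams,
    SweepParams,
    build_single_pop_demography,
    simulate_neutral,
    simulate_sweep,
)


@pytest.fixture(scope="session")
def single_pop_dem():
    return build_single_pop_demography()


@pytest.fixture(scope="session")
def paired_batches(single_pop_dem):
    """Matched neutral / sweep (s_het=0.01) batches, 500 replicates each."""
    region = SimRegionParams(seed=0)
    sweep = SweepParams(s_het=0.01)
    rng = np.random.default_rng(1234)
    seeds = rng.integers(1, 2**31 - 1, size=500)
    neutral, swept = [], []
    for s in seeds:
        r = dataclasses.replace(region, seed=int(s))
        neutral.append(simulate_neutral(single_pop_dem, r))
        swept.append(simulate_sweep(single_pop_dem, r, sweep))
    return neutral, swept


@pytest.fixture(scope="session")
def headline_study(tmp_path_factory):
    """The full desk-scale single-population study (shared by the
    acceptance tests; dominates suite runtime)."""
    from sweepnet.study import headline_numbers, run_single_pop_study

    cache = tmp_path_factory.mktemp("study_cache")
    report = run_single_pop_study(seed=1, n_per_class=2000, cache_dir=cache)
    return {"report": report, "nums": headline_numbers(report), "cache": cache}


def random_matrix(rng: np.random.Generator, n_hap: int = 12, n_sites: int = 20):
    """Small random segregating haplotype matrix for unit tests."""
    from sweepnet.demography import HaplotypeMatrix

    while True:
        alleles = (rng.random((n_hap, n_sites)) < rng.uniform(0.1, 0.6)).astype(np.uint8)
        counts = alleles.sum(axis=0)
        keep = (counts > 0) & (counts < n_hap)
        if keep.sum() >= 2:
            alleles = alleles[:, keep]
            break
    positions = np.sort(rng.choice(np.arange(1, 10_000), size=alleles.shape[1], replace=False)).astype(float)
    return HaplotypeMatrix(alleles=alleles, positions=positions)
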