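import dataclasses
import warnings

import numpy as np
import pytest

import rohscan


@pytest.fixture(scope="session")
def desk_cohort():
    """Default five-population desk-scale cohort (with genotyping noise)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tract-merge warnings are expected
        matrix, variants, truth = rohscan.simulate_cohort(
            rohscan.default_layout(), rohscan.default_profiles(), seed=11
        )
    return matrix, variants, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Error-free cohort: no missing calls, no within-tract heterozygotes."""
    profiles = [
        dataclasses.replace(p, missing_rate=0.0, within_tract_het_rate=0.0)
        for p in rohscan.default_profiles()
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, variants, truth = rohscan.simulate_cohort(
            rohscan.default_layout(), profiles, seed=7
        )
    return matrix, variants, truth


@pytest.fixture(scope="session")
def clean_rohset(clean_cohort):
    matrix, variants, _ = clean_cohort
    return rohscan.scan_cohort(matrix, variants)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
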