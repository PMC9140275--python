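import numpy as np
import pandas as pd
import pytest

from claimspath import (
    PathSpec,
    SimConfig,
    default_blocks,
    default_structure,
    derive_lines,
    generate_bundle,
    simulate_analysis_table,
)


@pytest.fixture(scope="session")
def small_bundle():
    """120-patient synthetic bundle used across modules."""
    return generate_bundle(SimConfig(n_patients=120, seed=7))


@pytest.fixture(scope="session")
def small_lines(small_bundle):
    return derive_lines(small_bundle.drug_claims, encounters=small_bundle.encounters)


@pytest.fixture(scope="session")
def default_spec():
    return PathSpec.from_blocks(default_blocks())


@pytest.fixture(scope="session")
def structure():
    return default_structure()


@pytest.fixture(scope="session")
def table4k(structure):
    """One analysis table drawn at the study's model sample size."""
    return simulate_analysis_table(structure, 4000, 123)


@pytest.fixture(scope="session")
def fitted4k(table4k, default_spec):
    from claimspath import PathModel

    return PathModel(table4k, default_spec).fit()
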