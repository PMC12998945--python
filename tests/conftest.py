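import numpy as np
import pytest

from kinepi.mechanism_core import default_profile, rates_from_profile
from kinepi.mutation_simulator import build_variant_table, sample_mutations


@pytest.fixture(scope="session")
def simple_profile():
    return default_profile("simple")


@pytest.fixture(scope="session")
def complex_profile():
    return default_profile("complex")


@pytest.fixture(scope="session")
def simple_wt_rates(simple_profile):
    return rates_from_profile(simple_profile)


@pytest.fixture(scope="session")
def complex_wt_rates(complex_profile):
    return rates_from_profile(complex_profile)


@pytest.fixture(scope="session")
def small_simple_table(simple_profile):
    """n=40 simple-mechanism library -> 780 pairs; fast but non-trivial."""
    effects = sample_mutations(40, (-2, 2), "simple", seed=11)
    return build_variant_table(simple_profile, effects)


@pytest.fixture(scope="session")
def small_complex_table(complex_profile):
    effects = sample_mutations(40, (-2, 2), "complex", seed=12)
    return build_variant_table(complex_profile, effects)
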