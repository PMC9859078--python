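import numpy as np
import pytest
from hypothesis import settings

from strvarqc import (
    Dataset,
    InterpretationRecord,
    VarianceType,
    default_prior_benchmarks,
    default_priors,
    reference_bands,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bands():
    """Reference empirical bands for the three variance parameters."""
    return reference_bands()


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture(scope="session")
def prior_benchmarks():
    return default_prior_benchmarks()


@pytest.fixture
def make_record():
    """Factory for valid records with overridable fields."""

    def _make(**kw):
        defaults = dict(
            sample_id="s1",
            dataset=Dataset.UNCHALLENGED,
            noc_true=2,
            noc_assumed=2,
            contributor_templates=(1000.0, 100.0),
            allele_var=3.27,
            rev_stutter_var=3.6,
            fwd_stutter_var=2.4,
        )
        defaults.update(kw)
        return InterpretationRecord(**defaults)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
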