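import numpy as np
import pytest

from occultevo.cna import CNAProfile, LocusSet


@pytest.fixture
def small_loci():
    return LocusSet(("1q", "9p", "7q"))


def make_profile(sample_id, values, patient="p1", kind="DCC"):
    return CNAProfile(sample_id, patient, kind, np.asarray(values))


@pytest.fixture
def profile_factory():
    return make_profile


def random_sparse_profiles(rng, n_samples, n_loci, density=0.4):
    """Random gain/loss profiles for parsimony stress tests."""
    mat = np.where(rng.random((n_samples, n_loci)) < density,
                   rng.choice([-1, 1], size=(n_samples, n_loci)), 0)
    return [make_profile(f"S{j}", mat[j]) for j in range(n_samples)]
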