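import pytest

from appendix_cea import (
    baseline_distributions,
    baseline_parameter_set,
    build_appendicitis_tree,
    named_rng,
    psa_run,
)


@pytest.fixture(scope="session")
def params():
    return baseline_parameter_set()


@pytest.fixture(scope="session")
def tree(params):
    return build_appendicitis_tree(params)


@pytest.fixture(scope="session")
def specs(params):
    return baseline_distributions(params)


@pytest.fixture(scope="session")
def psa_samples(tree, params, specs):
    """A moderate shared PSA run reused across CEAC/NMB tests."""
    return psa_run(tree, params, specs, 500, named_rng(7, "psa"))
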