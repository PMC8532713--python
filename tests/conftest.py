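import pytest

import beeflca as b


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study bundle (full treatment effect)."""
    return b.gen_study_bundle()


@pytest.fixture(scope="session")
def null_bundle():
    """No-effect bundle: identical CNV and EFC trials."""
    return b.gen_study_bundle(b.GeneratorConfig().null())


@pytest.fixture(scope="session")
def results(bundle):
    """Deterministic fit of every scenario/boundary combination."""
    return b.ComparativeLCA(bundle).fit()


@pytest.fixture(scope="session")
def method(bundle):
    return bundle.method
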