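import pytest

from bekit import (
    AnalysisConfig,
    get_editor,
    get_profile,
    make_reference_with_site,
)


@pytest.fixture(scope="session")
def spcas9():
    return get_profile("SpCas9")


@pytest.fixture(scope="session")
def be3():
    return get_editor("BE3")


@pytest.fixture(scope="session")
def amplicon(be3):
    """A 120-nt reference with one SpCas9 site and its analysis config."""
    reference, target_site = make_reference_with_site(seed=11)
    config = AnalysisConfig(
        reference=reference, target_site=target_site, editor=be3, flank_left=5, flank_right=5
    )
    return config
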