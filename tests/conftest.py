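import pytest

from fracnmr.isotopomer import LabelingScheme
from fracnmr.synth import GeneratorConfig


@pytest.fixture
def scheme_clean():
    """20% labeling with no natural abundance, perfect purity: the textbook case."""
    return LabelingScheme(f_labeled=0.2, nat_abund=0.0, scramble=0.5,
                          isotopic_purity=1.0)


@pytest.fixture
def scheme_default():
    return LabelingScheme(f_labeled=0.2)


@pytest.fixture
def config():
    return GeneratorConfig(seed=1234)
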