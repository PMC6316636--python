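import pytest

from mrkit import load_vitd_mdd_instruments, wald_ratios


@pytest.fixture(scope="session")
def instruments():
    """The packaged six-SNP 25OHD/major-depression instrument set."""
    return load_vitd_mdd_instruments()


@pytest.fixture(scope="session")
def ratios(instruments):
    return wald_ratios(instruments)
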