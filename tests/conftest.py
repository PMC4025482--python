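import pytest

from zipperscan import datasets


@pytest.fixture(scope="session")
def scr_pair():
    """(wild-type, Ser10→Leu) SCR N-terminus peptides from the packaged FASTA."""
    return datasets.scr_queries()


@pytest.fixture(scope="session")
def scr_wt(scr_pair):
    return scr_pair[0]


@pytest.fixture(scope="session")
def scr14(scr_pair):
    return scr_pair[1]


@pytest.fixture(scope="session")
def pheno2013():
    return datasets.scr_phenotypes(2013)


@pytest.fixture(scope="session")
def pheno2009():
    return datasets.scr_phenotypes(2009)
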