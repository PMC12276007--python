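"""Shared fixtures: oligonucleotide sequences used across the test suite."""

import pytest

# Chemically defined oligos from the study design (5'->3')
GU12 = "GUGUGUGUGUGUGUGUGUGUGUGU"
GU29 = "GU" * 29
HO1_PUG = "GUGUGUGUGUGUGUGUGUGUGUGUAUGUGUGUGUGUGUGUGUGUGUGUGU"
GU3_AA_GU9 = "GUGUGUAAGUGUGUGUGUGUGUGUGU"


@pytest.fixture
def gu12():
    return GU12


@pytest.fixture
def gu29():
    return GU29


@pytest.fixture
def ho1_pug():
    return HO1_PUG


@pytest.fixture
def gu3_aa_gu9():
    return GU3_AA_GU9
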