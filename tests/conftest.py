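"""Shared fixtures: the study decamer in its three PT states."""

import pytest

from ptdna.duplex import build_bform_template, build_duplex_spec
from ptdna.synth import SynthConfig

SEQ1 = "CGGCCGCCGA"
SEQ2 = "TCGGCGGCCG"


@pytest.fixture(scope="session")
def free_spec():
    return build_duplex_spec(SEQ1, SEQ2, name="PT-free")


@pytest.fixture(scope="session")
def rp_spec():
    return build_duplex_spec(SEQ1, SEQ2, [(3, "Rp"), (17, "Rp")], name="[Rp,Rp]-PT")


@pytest.fixture(scope="session")
def sp_spec():
    return build_duplex_spec(SEQ1, SEQ2, [(3, "Sp"), (17, "Sp")], name="[Sp,Sp]-PT")


@pytest.fixture(scope="session")
def free_template(free_spec):
    return build_bform_template(free_spec)


@pytest.fixture(scope="session")
def rp_template(rp_spec):
    return build_bform_template(rp_spec)


@pytest.fixture(scope="session")
def sp_template(sp_spec):
    return build_bform_template(sp_spec)


@pytest.fixture()
def cfg():
    return SynthConfig(seed=7)
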