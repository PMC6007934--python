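import numpy as np
import pytest

from pkfold import ForceFieldParams, IonCondition, Sequence
from pkfold.synthetic import (
    HAIRPIN_10NT,
    PSEUDOKNOT_17NT,
    ideal_hairpin_chain,
    ideal_helix_chain,
)


@pytest.fixture(scope="session")
def params():
    return ForceFieldParams.default()


@pytest.fixture(scope="session")
def ion_1m():
    """1 M monovalent salt at 25 C (the structure-prediction condition)."""
    return IonCondition.from_celsius(25.0, 1000.0)


@pytest.fixture()
def helix8(params):
    """8-nt single strand on the ideal A-form template."""
    return ideal_helix_chain(Sequence("GGGGAGAG"), params)


@pytest.fixture()
def hairpin_chain(params):
    """Ideal 3-bp GC hairpin with a 4-nt loop (10 nt)."""
    return ideal_hairpin_chain("GGG", "AAAA", params)


@pytest.fixture(scope="session")
def hairpin_seq():
    return HAIRPIN_10NT


@pytest.fixture(scope="session")
def pk_seq():
    return PSEUDOKNOT_17NT
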