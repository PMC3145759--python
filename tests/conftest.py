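import numpy as np
import pytest

from nrrgo.engine import pack_model
from nrrgo.gomodel import (assign_contact_energies, build_native_contacts,
                           build_topology)
from nrrgo.toys import ToySpec, make_toy_structure, make_two_domain_shielded


@pytest.fixture(scope="session")
def hairpin():
    """16-residue hairpin structure + exact designed contact plan."""
    s, plan = make_toy_structure(ToySpec())
    return s, plan


@pytest.fixture(scope="session")
def hairpin_top(hairpin):
    s, _plan = hairpin
    contacts = assign_contact_energies(build_native_contacts(s), s.sequence())
    top = build_topology(s, contacts)
    return top


@pytest.fixture(scope="session")
def hairpin_packed(hairpin_top):
    return pack_model(hairpin_top)


@pytest.fixture(scope="session")
def two_domain():
    """Shielded two-domain fixture with designed interface energetics."""
    s, info = make_two_domain_shielded()
    contacts = build_native_contacts(s)
    plan = {(min(i, j), max(i, j)): e for i, j, e in info["contact_plan"]}
    for c in contacts:
        c.epsilon = plan[(min(c.bead_i, c.bead_j), max(c.bead_i, c.bead_j))]
    top = build_topology(s, contacts)
    return s, top, info


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
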