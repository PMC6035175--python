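"""Shared fixtures: small deterministic structures and point sets."""

import numpy as np
import pytest

from pfgeom.structio import Atom, Chain, Residue, Structure
from pfgeom.synthetic import FilamentSpec, build_filament, make_subunit


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def small_subunit():
    return make_subunit(atoms_per_subunit=60, seed=11)


@pytest.fixture
def curved_filament():
    spec = FilamentSpec(
        n_subunits=4,
        atoms_per_subunit=100,
        bend_per_interface=[15.3, 15.8, 12.1],
        twist_per_interface=3.0,
        rise=42.0,
        seed=5,
    )
    return build_filament(spec)


def make_point_structure(coords, element="C", chain_id="A"):
    """Structure with one CA pseudo-atom per coordinate row."""
    st = Structure(id="points")
    chain = Chain(chain_id=chain_id)
    for i, pos in enumerate(np.atleast_2d(coords)):
        res = Residue(name="ALA", number=i + 1, insertion_code="")
        res.atoms.append(
            Atom(serial=i + 1, name="CA", element=element, altloc="",
                 residue_name="ALA", chain_id=chain_id, residue_number=i + 1,
                 insertion_code="", position=np.asarray(pos, dtype=float))
        )
        chain.residues.append(res)
    st.chains.append(chain)
    return st


@pytest.fixture
def point_structure_factory():
    return make_point_structure
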