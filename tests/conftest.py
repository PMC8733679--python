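"""Shared fixtures: hand-built structures and seeded toy systems.

All fixture data is generated programmatically; nothing is read from disk
except files the tests themselves write.
"""

from __future__ import annotations

import numpy as np
import pytest

from arrbind.core import Structure
from arrbind import synth


def make_structure(coords, names=None, resids=None, chains=None,
                   resnames=None, elements=None, masses=None, charges=None,
                   box=None):
    """Small helper to build a Structure from plain lists."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = np.asarray(names if names is not None else ["CA"] * n,
                       dtype=object)
    elements = np.asarray(
        elements if elements is not None
        else [str(x)[0] for x in names], dtype=object)
    default_mass = {"C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
                    "H": 1.008, "S": 32.06}
    masses = np.asarray(
        masses if masses is not None
        else [default_mass.get(e, 12.0) for e in elements], dtype=float)
    return Structure(
        chain_ids=np.asarray(chains if chains is not None else ["A"] * n,
                             dtype=object),
        resids=np.asarray(resids if resids is not None else range(1, n + 1),
                          dtype=int),
        resnames=np.asarray(resnames if resnames is not None
                            else ["ALA"] * n, dtype=object),
        names=names, elements=elements, masses=masses, coords=coords,
        box=None if box is None else np.asarray(box, dtype=float),
        charges=None if charges is None else np.asarray(charges, dtype=float),
    )


def small_system_spec() -> synth.ToySystemSpec:
    """A reduced membrane for fast trajectory tests."""
    return synth.ToySystemSpec(nx=6, ny=6, pc_per_leaflet=14,
                               pg_per_leaflet=10, chol_per_leaflet=4)


@pytest.fixture(scope="session")
def toy_complex():
    return synth.build_toy_complex(synth.ToySystemSpec(), seed=11)


@pytest.fixture(scope="session")
def small_toy():
    return synth.build_toy_complex(small_system_spec(), seed=11)
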