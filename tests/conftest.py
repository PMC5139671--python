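"""Shared fixtures: synthetic structures and their scans (session-scoped,
since scanning is the expensive step)."""

import numpy as np
import pytest

import ums


@pytest.fixture(scope="session")
def helix3():
    return ums.make_fixture("helix", 3, "AGA", seed=1)


@pytest.fixture(scope="session")
def helix10():
    return ums.make_fixture("helix", 10, seed=4)


@pytest.fixture(scope="session")
def helix20():
    """The 20-residue helix used for identity-ΔΔG checks (seed 1)."""
    return ums.make_fixture("helix", 20, seed=1)


@pytest.fixture(scope="session")
def ball40():
    return ums.make_fixture("compact_ball", 40, seed=7)


@pytest.fixture(scope="session")
def helix10_records(helix10):
    return ums.run_scan(helix10)


@pytest.fixture(scope="session")
def helix10_matrix(helix10_records):
    return ums.build_matrix(helix10_records)


@pytest.fixture(scope="session")
def ball40_depths(ball40):
    return ums.residue_depth(ball40)


def _translate_site(site, offset):
    for a in site.atoms:
        a.coord = a.coord + offset


@pytest.fixture(scope="session")
def dilute_model():
    """Weak-coupling structure: residues pulled 30 Å apart along x, so no
    atom pair of different residues interacts under any cutoff."""
    m = ums.make_fixture("helix", 8, "LKMEQRFW", seed=2)
    m = m.copy()
    for i, site in enumerate(m.sites):
        _translate_site(site, np.array([30.0 * i, 0.0, 0.0]))
    return m
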