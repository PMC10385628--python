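"""Shared fixtures: small hand-built residues and generator shortcuts.

All molecular fixtures are constructed programmatically; coordinates are
idealized (standard bond lengths/angles) rather than taken from any
deposited structure.
"""

import numpy as np
import pytest

from contactzones.structure_io import AtomRecord


def _mk(i, element, name, pos, resname="GLY", resnum=1, chain="A", **kw):
    return AtomRecord(
        id=i, element=element, name=name, residue_name=resname,
        residue_number=resnum, chain=chain, position=pos, **kw,
    )


@pytest.fixture
def glycine_atoms():
    """Protonated glycine residue at idealized geometry."""
    return [
        _mk(1, "N", "N", (0.00, 0.00, 0.00)),
        _mk(2, "H", "H", (-0.50, -0.88, 0.00)),
        _mk(3, "C", "CA", (1.46, 0.00, 0.00)),
        _mk(4, "H", "HA2", (1.80, -0.55, 0.89)),
        _mk(5, "H", "HA3", (1.80, -0.55, -0.89)),
        _mk(6, "C", "C", (2.01, 1.42, 0.00)),
        _mk(7, "O", "O", (1.25, 2.39, 0.00)),
    ]


@pytest.fixture
def water_atom():
    return [
        _mk(8, "O", "O", (5.0, 5.0, 5.0), resname="HOH", resnum=101, chain="S")
    ]


@pytest.fixture
def guanidinium_atoms():
    """Arginine guanidinium group (CD-NE(-HE)-CZ(-NH1 H2)(-NH2 H2))."""
    return [
        _mk(11, "C", "CD", (0.065, -2.42, 0.0), resname="ARG", resnum=5),
        _mk(12, "N", "NE", (-0.665, -1.15, 0.0), resname="ARG", resnum=5),
        _mk(13, "H", "HE", (-1.53, -1.65, 0.0), resname="ARG", resnum=5),
        _mk(14, "C", "CZ", (0.0, 0.0, 0.0), resname="ARG", resnum=5),
        _mk(15, "N", "NH1", (1.33, 0.0, 0.0), resname="ARG", resnum=5),
        _mk(16, "H", "HH11", (2.20, 0.50, 0.0), resname="ARG", resnum=5),
        _mk(17, "H", "HH12", (1.85, -0.85, 0.0), resname="ARG", resnum=5),
        _mk(18, "N", "NH2", (-0.665, 1.15, 0.0), resname="ARG", resnum=5),
        _mk(19, "H", "HH21", (-1.53, 1.65, 0.0), resname="ARG", resnum=5),
        _mk(20, "H", "HH22", (-0.665, 2.15, 0.0), resname="ARG", resnum=5),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
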