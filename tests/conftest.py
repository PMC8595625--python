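import numpy as np
import pytest

from helixnet import (
    HelixSpec,
    SegmentDefinition,
    cb1_segment_definition,
    default_params,
    make_bundle,
    make_ideal_helix,
)
from helixnet.structure import AtomRecord, Structure

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def cb1_definition():
    return cb1_segment_definition()


@pytest.fixture(scope="session")
def helix20():
    """Untilted 20-residue ideal helix with its one-helix segment definition."""
    structure = make_ideal_helix(HelixSpec(n_residues=20))
    definition = SegmentDefinition(segments={"TM1": (1, 20)})
    return structure, definition


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic 7TM bundle (structure, definition, planted tilts)."""
    return make_bundle()


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def cloud50():
    """50 well-separated atoms in 10 five-atom residues (no LJ near-contacts)."""
    rng = np.random.default_rng(7)
    positions = []
    while len(positions) < 50:
        p = rng.uniform(-12, 12, size=3)
        if all(np.linalg.norm(p - q) > 2.6 for q in positions):
            positions.append(p)
    names = ["N", "CA", "C", "O", "CB"]
    atoms = [
        AtomRecord(names[i % 5], i // 5 + 1, "ALA", "A", positions[i],
                   names[i % 5][0])
        for i in range(50)
    ]
    return Structure(atoms, "cloud50")


def make_residue(resnum, resname, atom_names, chain="A", spacing=1.6):
    """Residue with atoms on a line — enough for topology-level operations."""
    return [
        AtomRecord(n, resnum, resname, chain,
                   np.array([spacing * k, 0.1 * resnum, 0.0]), n[0])
        for k, n in enumerate(atom_names)
    ]
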