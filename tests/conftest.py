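import numpy as np
import pytest

from tnkit import Atom, Topology, TrajectoryEnsemble
from tnkit.synthetic_data import GeometryEngine, _backbone_topology


@pytest.fixture
def engine():
    return GeometryEngine()


def backbone_ensemble(phi, psi, box=None, n_frames=1):
    """Ensemble holding identical frames of a built backbone chain."""
    coords = GeometryEngine().build_backbone(phi, psi)
    frames = np.repeat(coords[None], n_frames, axis=0)
    return TrajectoryEnsemble(_backbone_topology(len(phi)), frames, box=box)


@pytest.fixture
def helix12():
    """Ideal 12-residue α-helix (φ, ψ) = (−57°, −47°)."""
    return backbone_ensemble([-57.0] * 12, [-47.0] * 12)


@pytest.fixture
def mixed_topology():
    """Small peptide + water + ion topology for selection tests."""
    atoms = [
        Atom("N", "N", "GLU", 1, "A"),
        Atom("CA", "C", "GLU", 1, "A"),
        Atom("CD", "C", "GLU", 1, "A"),
        Atom("N", "N", "ASP", 2, "A"),
        Atom("CA", "C", "ASP", 2, "A"),
        Atom("OW", "O", "HOH", 1, "W"),
        Atom("OW", "O", "HOH", 2, "W"),
        Atom("NA", "Na", "NA", 1, "I"),
    ]
    return Topology(atoms)
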