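"""Contact-probability maps, ion radial distributions and formal charges.

Two groups are "in contact" in a frame when the minimum distance over
all their heavy-atom pairs is below the cutoff (default 10 Å); the
per-pair contact count normalized by the number of frames gives a
contact probability in [0, 1].  Formal net charges follow the standard
physiological-pH bookkeeping: Asp/Glu −1, Lys/Arg +1, His neutral by
default (switchable to +1), free termini +1/−1, and for
chondroitin-4-sulfate chains −1 per GalNAc(4S) and −1 per GlcUA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solvent_structure import RDFProfile
from .trajectory_io import TrajectoryEnsemble, pair_distances

__all__ = [
    "ContactMap",
    "ChargeModel",
    "contact_map",
    "ion_rdf",
    "net_charge",
    "AB42_SEQUENCE",
]

# Aβ1−42 one-letter sequence (42 residues)
AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class ContactMap:
    row_labels: list
    col_labels: list
    probability: np.ndarray  # (rows, cols) in [0, 1]
    cutoff: float
    n_frames: int

    def __post_init__(self):
        self.probability = np.asarray(self.probability, dtype=float)
        if np.any(self.probability < 0) or np.any(self.probability > 1):
            raise ValueError("contact probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probability, index=self.row_labels, columns=self.col_labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _default_charge_table() -> dict[str, int]:
    return {
        "ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1, "HIS": 0,
        "ALA": 0, "ASN": 0, "CYS": 0, "GLN": 0, "GLY": 0, "ILE": 0,
        "LEU": 0, "MET": 0, "PHE": 0, "PRO": 0, "SER": 0, "THR": 0,
        "TRP": 0, "TYR": 0, "VAL": 0,
    }


def _default_sugar_table() -> dict[str, int]:
    # chondroitin-4-sulfate units: sulfated N-acetylgalactosamine and
    # glucuronic acid, each carrying one negative charge
    return {"GalNAc(4S)": -1, "GlcUA": -1}


@dataclass
class ChargeModel:
    """Integer formal charges per residue / monosaccharide unit.

    ``his_charged`` switches histidine from the neutral default to +1
    (low-pH / His+ modelling); ``capped`` suppresses the +1/−1 terminal
    charges of an uncapped peptide.
    """

    residue_charges: dict[str, int] = field(default_factory=_default_charge_table)
    sugar_charges: dict[str, int] = field(default_factory=_default_sugar_table)
    his_charged: bool = False
    capped: bool = False
    n_terminal_charge: int = +1
    c_terminal_charge: int = -1

    def unit_charge(self, unit: str) -> int:
        key3 = _ONE_TO_THREE.get(unit, unit) if len(unit) == 1 else unit
        table = dict(self.residue_charges)
        if self.his_charged:
            table["HIS"] = +1
        if key3 in table:
            return table[key3]
        if unit in self.sugar_charges:
            return self.sugar_charges[unit]
        raise KeyError(f"unknown residue or monosaccharide code: {unit!r}")


def _heavy(ens: TrajectoryEnsemble, indices) -> np.ndarray:
    atoms = ens.topology.atoms
    return np.array(
        [i for i in indices if atoms[i].element.capitalize() != "H"], dtype=int
    )


def contact_map(
    ens: TrajectoryEnsemble,
    groups_a: dict | list,
    groups_b: dict | list,
    cutoff: float = 10.0,
    frames=None,
) -> ContactMap:
    """Contact probability between every pair of atom-index groups.

    ``groups_a``/``groups_b`` map labels to atom-index lists (plain lists
    get integer labels).  A pair counts as contacting in a frame when the
    minimum heavy-atom pair distance is strictly below ``cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not isinstance(groups_a, dict):
        groups_a = {i: g for i, g in enumerate(groups_a)}
    if not isinstance(groups_b, dict):
        groups_b = {i: g for i, g in enumerate(groups_b)}
    for name, grp in {**groups_a, **groups_b}.items():
        if len(grp) == 0:
            raise ValueError(f"group {name!r} is empty")
    frames = range(ens.n_frames) if frames is None else list(frames)
    n_frames = len(frames)
    heavy_a = {k: _heavy(ens, v) for k, v in groups_a.items()}
    heavy_b = {k: _heavy(ens, v) for k, v in groups_b.items()}
    for name, grp in {**heavy_a, **heavy_b}.items():
        if len(grp) == 0:
            raise ValueError(f"group {name!r} has no heavy atoms")
    counts = np.zeros((len(groups_a), len(groups_b)))
    for f in frames:
        coords = ens.frames[f]
        for i, ga in enumerate(heavy_a.values()):
            for j, gb in enumerate(heavy_b.values()):
                d = pair_distances(coords[ga], coords[gb], ens.box)
                if d.min() < cutoff:
                    counts[i, j] += 1
    return ContactMap(
        list(groups_a), list(groups_b), counts / n_frames, cutoff=cutoff, n_frames=n_frames
    )


def ion_rdf(
    ens: TrajectoryEnsemble,
    ion_indices,
    reference_indices,
    bins: int = 100,
    r_max: float | None = None,
    frames=None,
) -> RDFProfile:
    """g(r) of ions around a reference group, averaged over frames.

    The radial coordinate of an ion is its minimum-image distance to the
    *nearest* reference atom; counts are normalized by the ion bulk
    density and spherical shell volumes.  This is exact for a
    single-atom reference and a good approximation for compact groups
    such as a carboxylate.
    """
    ion_indices = np.asarray(ion_indices, dtype=int)
    reference_indices = np.asarray(reference_indices, dtype=int)
    if reference_indices.size == 0:
        raise ValueError("reference group is empty")
    if ion_indices.size == 0:
        raise ValueError("ion selection is empty")
    if ens.box is None:
        raise ValueError("a periodic box is required to define the ion bulk density")
    box = ens.box
    half = float(box.min()) / 2.0
    if r_max is None:
        r_max = half
    if r_max > half + 1e-9:
        raise ValueError(f"r_max {r_max:g} Å exceeds half the shortest box edge")
    frames = range(ens.n_frames) if frames is None else list(frames)
    edges = np.linspace(0.0, r_max, bins + 1)
    hist = np.zeros(bins)
    for f in frames:
        coords = ens.frames[f]
        d = pair_distances(coords[ion_indices], coords[reference_indices], box).min(axis=1)
        h, _ = np.histogram(d, bins=edges)
        hist += h
    volume = float(np.prod(box))
    rho_ion = len(ion_indices) / volume
    shell_volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = hist / (len(frames) * rho_ion * shell_volumes)
    return RDFProfile(edges, g, rho=rho_ion, n_particles=len(ion_indices), volume=volume)


def net_charge(sequence_or_composition, model: ChargeModel | None = None) -> int:
    """Formal net charge (in e) of a peptide sequence or a unit composition.

    ``sequence_or_composition`` is a one-letter peptide string, a list of
    three-letter residue codes, or a list of monosaccharide codes.
    Terminal charges (+1/−1) are added for uncapped peptides; sugar-only
    compositions get no terminal charges.
    """
    model = model or ChargeModel()
    units = list(sequence_or_composition)
    if not units:
        raise ValueError("empty sequence or composition")
    unknown = [
        u
        for u in units
        if (_ONE_TO_THREE.get(u, u) if len(u) == 1 else u) not in model.residue_charges
        and u not in model.sugar_charges
    ]
    if unknown:
        raise KeyError(f"unknown residue or monosaccharide codes: {sorted(set(unknown))}")
    total = sum(model.unit_charge(u) for u in units)
    is_peptide = all(
        (_ONE_TO_THREE.get(u, u) if len(u) == 1 else u) in model.residue_charges for u in units
    )
    if is_peptide and not model.capped:
        total += model.n_terminal_charge + model.c_terminal_charge
    return int(total)
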