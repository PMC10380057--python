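"""Per-frame conformational descriptors and state projection.

A frame is reduced to the tuple (Nα, Nβ, dNC):

* ``Nα`` — number of residues assigned an α-helical label,
* ``Nβ`` — number of residues assigned a β-strand label,
* ``dNC`` — the N-to-C end-to-end distance in Å (Cα–Cα by default).

Identical binned tuples map to the same integer state id (dense ids in
first-appearance order), giving the discrete state series S(t) on which
the transition network is built.

Secondary structure is assigned by a purely geometric backbone-dihedral
classifier: a residue is a helix candidate if (φ, ψ) falls in the α
window and helical labels require a run of ≥ 4 consecutive candidates;
strand candidates come from the β window with runs of ≥ 3, optionally
(default) requiring a partner strand run with at least one inter-run
Cα–Cα pair below 5.5 Å.  Residues whose φ or ψ is undefined (chain
termini) are coil.  The classifier is deterministic and depends only on
coordinates, so it is exactly testable on geometrically built chains;
its absolute strand counts can differ from energy-based assigners such
as DSSP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory_io import (
    Topology,
    TrajectoryEnsemble,
    minimum_image_displacements,
    pair_distances,
)

__all__ = [
    "HELIX_PHI_WINDOW",
    "HELIX_PSI_WINDOW",
    "STRAND_PHI_WINDOW",
    "DescriptorSpec",
    "SecondaryStructureAssignment",
    "DescriptorStateSeries",
    "dihedral_angle",
    "backbone_indices",
    "assign_secondary_structure",
    "compute_descriptors",
    "project_trajectory",
]

# (φ, ψ) windows in degrees
HELIX_PHI_WINDOW = (-100.0, -30.0)
HELIX_PSI_WINDOW = (-80.0, -5.0)
STRAND_PHI_WINDOW = (-180.0, -90.0)
STRAND_PSI_WINDOWS = ((90.0, 180.0), (-180.0, -170.0))
MIN_HELIX_RUN = 4
MIN_STRAND_RUN = 3
STRAND_PAIR_CUTOFF = 5.5  # Å, inter-run Cα–Cα


@dataclass
class DescriptorSpec:
    """Configuration of the descriptor tuple and its binning.

    ``dnc_bin_width`` — bin width in Å for the end-to-end distance
    (floor binning); Nα and Nβ are integers and used unbinned.
    ``dnc_mode`` — "ca" for Cα(first)–Cα(last), "n_c" for backbone
    N(first)–C(last).
    ``molecule_id`` — restrict to one molecule; default: molecule of the
    first atom.
    """

    dnc_bin_width: float = 1.0
    dnc_mode: str = "ca"
    paired_strands: bool = True
    molecule_id: str | None = None
    names: tuple[str, ...] = ("Nalpha", "Nbeta", "dNC")

    def __post_init__(self):
        if self.dnc_bin_width <= 0:
            raise ValueError("dnc_bin_width must be positive")
        if self.dnc_mode not in ("ca", "n_c"):
            raise ValueError("dnc_mode must be 'ca' or 'n_c'")


@dataclass
class SecondaryStructureAssignment:
    """One H/E/C label per residue of the analysed molecule."""

    residue_ids: list[tuple[str, int]]
    labels: list[str]

    def count(self, label: str) -> int:
        return self.labels.count(label)


@dataclass
class DescriptorStateSeries:
    raw: np.ndarray  # (n_frames, n_descriptors) unbinned values
    binned: list[tuple]
    state_map: dict[tuple, int]  # binned tuple -> dense state id
    states: np.ndarray  # (n_frames,) int
    spec: DescriptorSpec = field(default_factory=DescriptorSpec)

    @property
    def n_states(self) -> int:
        return len(self.state_map)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.raw, columns=list(self.spec.names))
        df.insert(0, "frame", np.arange(len(df)))
        df["state"] = self.states
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(-y, x)))


def backbone_indices(
    topology: Topology, molecule_id: str | None = None
) -> list[tuple[int, int, int]]:
    """Per-residue (N, CA, C) atom indices, ordered by residue index.

    Raises a descriptive error naming the residue if a backbone atom is
    missing.
    """
    if molecule_id is None:
        molecule_id = topology.atoms[0].molecule_id
    residues: dict[int, dict[str, int]] = {}
    for i, a in enumerate(topology.atoms):
        if a.molecule_id != molecule_id:
            continue
        residues.setdefault(a.residue_index, {})
        if a.name in ("N", "CA", "C") and a.name not in residues[a.residue_index]:
            residues[a.residue_index][a.name] = i
    if not residues:
        raise ValueError(f"no residues found for molecule {molecule_id!r}")
    out = []
    for res_idx in sorted(residues):
        atoms = residues[res_idx]
        for name in ("N", "CA", "C"):
            if name not in atoms:
                raise ValueError(
                    f"residue {res_idx} of molecule {molecule_id!r} lacks backbone atom {name}"
                )
        out.append((atoms["N"], atoms["CA"], atoms["C"]))
    return out


def _in_window(value: float, window: tuple[float, float]) -> bool:
    return window[0] <= value <= window[1]


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Half-open index ranges of True runs of length ≥ min_len."""
    runs = []
    start = None
    for i, flag in enumerate(list(mask) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    return runs


def assign_secondary_structure(
    ens: TrajectoryEnsemble,
    frame: int,
    *,
    molecule_id: str | None = None,
    paired_strands: bool = True,
) -> SecondaryStructureAssignment:
    """Assign H/E/C labels to every residue of one molecule in one frame."""
    bb = backbone_indices(ens.topology, molecule_id)
    coords = ens.frames[frame]
    n_res = len(bb)
    phi = np.full(n_res, np.nan)
    psi = np.full(n_res, np.nan)
    for r in range(n_res):
        n_i, ca_i, c_i = bb[r]
        if r > 0:
            phi[r] = dihedral_angle(coords[bb[r - 1][2]], coords[n_i], coords[ca_i], coords[c_i])
        if r < n_res - 1:
            psi[r] = dihedral_angle(coords[n_i], coords[ca_i], coords[c_i], coords[bb[r + 1][0]])

    helix_cand = np.array(
        [
            not np.isnan(phi[r])
            and not np.isnan(psi[r])
            and _in_window(phi[r], HELIX_PHI_WINDOW)
            and _in_window(psi[r], HELIX_PSI_WINDOW)
            for r in range(n_res)
        ]
    )
    strand_cand = np.array(
        [
            not np.isnan(phi[r])
            and not np.isnan(psi[r])
            and _in_window(phi[r], STRAND_PHI_WINDOW)
            and any(_in_window(psi[r], w) for w in STRAND_PSI_WINDOWS)
            for r in range(n_res)
        ]
    )

    labels = ["C"] * n_res
    for start, end in _runs(helix_cand, MIN_HELIX_RUN):
        for r in range(start, end):
            labels[r] = "H"

    strand_runs = _runs(strand_cand, MIN_STRAND_RUN)
    if paired_strands and len(strand_runs) >= 2:
        ca = np.array([coords[bb[r][1]] for r in range(n_res)])
        kept = []
        for i, (s1, e1) in enumerate(strand_runs):
            paired = False
            for j, (s2, e2) in enumerate(strand_runs):
                if i == j:
                    continue
                d = pair_distances(ca[s1:e1], ca[s2:e2], ens.box)
                if np.any(d < STRAND_PAIR_CUTOFF):
                    paired = True
                    break
            if paired:
                kept.append((s1, e1))
        strand_runs = kept
    elif paired_strands:
        strand_runs = []  # a lone strand has no partner
    for start, end in strand_runs:
        for r in range(start, end):
            if labels[r] == "C":  # helix runs take precedence (disjoint windows anyway)
                labels[r] = "E"

    molecule = molecule_id or ens.topology.atoms[0].molecule_id
    res_ids = [(molecule, ens.topology.atoms[bb[r][1]].residue_index) for r in range(n_res)]
    return SecondaryStructureAssignment(res_ids, labels)


def _end_to_end(ens: TrajectoryEnsemble, frame: int, bb, mode: str) -> float:
    coords = ens.frames[frame]
    if mode == "ca":
        a, b = coords[bb[0][1]], coords[bb[-1][1]]
    else:  # backbone N of first residue to backbone C of last
        a, b = coords[bb[0][0]], coords[bb[-1][2]]
    delta = minimum_image_displacements(b - a, ens.box)
    return float(np.linalg.norm(delta))


def compute_descriptors(
    ens: TrajectoryEnsemble, frame: int, spec: DescriptorSpec | None = None
) -> tuple[int, int, float]:
    """(Nα, Nβ, dNC) for one frame."""
    spec = spec or DescriptorSpec()
    ss = assign_secondary_structure(
        ens, frame, molecule_id=spec.molecule_id, paired_strands=spec.paired_strands
    )
    bb = backbone_indices(ens.topology, spec.molecule_id)
    return ss.count("H"), ss.count("E"), _end_to_end(ens, frame, bb, spec.dnc_mode)


def project_trajectory(
    ens: TrajectoryEnsemble, spec: DescriptorSpec | None = None
) -> DescriptorStateSeries:
    """Project every frame onto its descriptor tuple and dense state id.

    The raw (unbinned) descriptor values are retained for community
    averaging; binned tuples use exact integers for Nα/Nβ and floor
    binning at ``spec.dnc_bin_width`` for dNC.
    """
    spec = spec or DescriptorSpec()
    raw = np.empty((ens.n_frames, 3))
    binned: list[tuple] = []
    state_map: dict[tuple, int] = {}
    states = np.empty(ens.n_frames, dtype=int)
    for f in range(ens.n_frames):
        na, nb, dnc = compute_descriptors(ens, f, spec)
        raw[f] = (na, nb, dnc)
        key = (na, nb, int(np.floor(dnc / spec.dnc_bin_width)))
        binned.append(key)
        if key not in state_map:
            state_map[key] = len(state_map)
        states[f] = state_map[key]
    return DescriptorStateSeries(raw, binned, state_map, states, spec)
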