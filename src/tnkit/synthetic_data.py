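"""Synthetic inputs with known ground truth for every analysis stage.

The generators emulate the *statistical structure* of peptide MD data —
a 42-residue chain switching among coil/helix/hairpin macrostates under
a prescribed Markov matrix, water-oxygen configurations spanning the
ideal-gas-to-tetrahedral-lattice order spectrum, renewal-process H-bond
traces with stretched-exponential-like persistence, and toy ion systems
— without running any molecular dynamics.  Peptide frames are built from
internal coordinates (ideal bond geometry plus per-label backbone
dihedrals with Gaussian jitter), which is sufficient to drive the
descriptor, network, contact and solvent analyses with exactly known
ground truth.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hbond_kinetics import HBondTraceSet
from .trajectory_io import Atom, Topology, TrajectoryEnsemble

__all__ = [
    "GeometryEngine",
    "Macrostate",
    "MacrostateSpec",
    "generate_markov_series",
    "stationary_distribution",
    "realize_trajectory",
    "abeta_like_spec",
    "generate_water_configuration",
    "generate_hbond_traces",
    "generate_ion_system",
]

# canonical (φ, ψ) in degrees per conformational label
PHI_PSI = {
    "H": (-57.0, -47.0),  # α-helix
    "E": (-139.0, 135.0),  # β-strand
    "C": (-75.0, 145.0),  # polyproline-II-like coil, outside both classifier windows
}


@dataclass
class GeometryEngine:
    """Internal-coordinate backbone builder (NeRF chain extension).

    Ideal geometry: N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; angles
    N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°; ω = 180°.
    """

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    omega: float = 180.0

    @staticmethod
    def _place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
        """Position of atom D given A-B-C, |CD|, angle(BCD) and dihedral(ABCD)."""
        angle = np.radians(angle_deg)
        dihedral = np.radians(dihedral_deg)
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        n = np.cross(ab, bc)  # right-handed frame: measured A-B-C-D dihedral equals the input
        n /= np.linalg.norm(n)
        m = np.cross(n, bc)
        d_local = bond * np.array(
            [-np.cos(angle), np.sin(angle) * np.cos(dihedral), np.sin(angle) * np.sin(dihedral)]
        )
        return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n

    def build_backbone(self, phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
        """Coordinates of the N, CA, C backbone atoms of an n-residue
        chain with the given per-residue dihedrals (φ of the first and ψ
        of the last residue are not used)."""
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        n_res = len(phi)
        if len(psi) != n_res or n_res < 2:
            raise ValueError("need matching φ/ψ arrays for at least two residues")
        coords = np.zeros((3 * n_res, 3))
        # seed triad for residue 1
        coords[0] = (0.0, 0.0, 0.0)  # N1
        coords[1] = (self.bond_n_ca, 0.0, 0.0)  # CA1
        ang = np.radians(self.angle_n_ca_c)
        coords[2] = coords[1] + self.bond_ca_c * np.array([-np.cos(ang), np.sin(ang), 0.0])  # C1
        for r in range(1, n_res):
            n_prev, ca_prev, c_prev = coords[3 * r - 3], coords[3 * r - 2], coords[3 * r - 1]
            n_i = self._place(n_prev, ca_prev, c_prev, self.bond_c_n, self.angle_ca_c_n, psi[r - 1])
            ca_i = self._place(ca_prev, c_prev, n_i, self.bond_n_ca, self.angle_c_n_ca, self.omega)
            c_i = self._place(c_prev, n_i, ca_i, self.bond_ca_c, self.angle_n_ca_c, phi[r])
            coords[3 * r : 3 * r + 3] = (n_i, ca_i, c_i)
        return coords


@dataclass
class Macrostate:
    """One macrostate: a name and per-residue backbone dihedrals."""

    name: str
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi must have equal length")

    @property
    def n_residues(self) -> int:
        return len(self.phi)

    @classmethod
    def from_pattern(cls, name: str, pattern: str, special: dict | None = None) -> "Macrostate":
        """Build from a per-residue label string.

        Labels 'H', 'E', 'C' use the canonical (φ, ψ) table; other labels
        must appear in ``special`` mapping label → (φ, ψ).
        """
        table = dict(PHI_PSI)
        if special:
            table.update(special)
        try:
            angles = [table[ch] for ch in pattern]
        except KeyError as exc:
            raise ValueError(f"unknown residue label {exc.args[0]!r} in pattern") from exc
        phi = np.array([a[0] for a in angles])
        psi = np.array([a[1] for a in angles])
        return cls(name, phi, psi)


@dataclass
class MacrostateSpec:
    """Study conditions for a Markov-switching synthetic peptide run."""

    macrostates: list[Macrostate]
    transition_matrix: np.ndarray
    n_frames: int
    seed: int = 0
    jitter_sigma: float = 6.0  # degrees, Gaussian on every dihedral
    dt: float = 1.0  # ps
    proximity_constraint: tuple[int, int, float] | None = None
    # (residue_i, residue_j, max Cα distance Å) enforced on hairpin-like states

    def __post_init__(self):
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        k = len(self.macrostates)
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition matrix must be square over the macrostates")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        n_res = {m.n_residues for m in self.macrostates}
        if len(n_res) != 1:
            raise ValueError("all macrostates must cover the same residues")


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left
    eigenvector of eigenvalue 1, normalized)."""
    P = np.asarray(P, dtype=float)
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def generate_markov_series(P: np.ndarray, n: int, seed: int) -> np.ndarray:
    """A length-``n`` realization of the Markov chain with transition
    matrix ``P``, first state drawn from the stationary distribution."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("P must be row-stochastic")
    rng = np.random.default_rng(seed)
    k = P.shape[0]
    cum = np.cumsum(P, axis=1)
    out = np.empty(n, dtype=int)
    out[0] = rng.choice(k, p=stationary_distribution(P))
    u = rng.random(n - 1)
    for t in range(1, n):
        out[t] = np.searchsorted(cum[out[t - 1]], u[t - 1], side="right")
    return out


_BACKBONE_NAMES = ("N", "CA", "C")


def _backbone_topology(n_res: int) -> Topology:
    atoms = [
        Atom(name=name, element=name[0], residue_name="ALA", residue_index=r + 1)
        for r in range(n_res)
        for name in _BACKBONE_NAMES
    ]
    bonds = []
    for i in range(3 * n_res - 1):
        bonds.append((i, i + 1))
    return Topology(atoms, bonds)


def _has_collision(coords: np.ndarray, min_dist: float = 1.5, exclude_within: int = 3) -> bool:
    """Any nonbonded atom pair closer than ``min_dist`` Å (pairs within
    ``exclude_within`` chain positions are bonded/angle pairs)."""
    n = len(coords)
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(min_dist):
        if abs(i - j) > exclude_within:
            return True
    return False


def realize_trajectory(spec: MacrostateSpec) -> tuple[TrajectoryEnsemble, np.ndarray]:
    """Build a full coordinate trajectory from a macrostate spec.

    Returns the ensemble and the generating macrostate id sequence (the
    ground truth against which descriptor/network recovery is checked).
    Frames whose jittered geometry self-collides (< 1.5 Å nonbonded) or
    violates the proximity constraint are rebuilt with fresh jitter; an
    error is raised after 100 attempts.
    """
    engine = GeometryEngine()
    rng = np.random.default_rng(spec.seed)
    series = generate_markov_series(
        spec.transition_matrix, spec.n_frames, seed=int(rng.integers(2**31))
    )
    n_res = spec.macrostates[0].n_residues
    frames = np.empty((spec.n_frames, 3 * n_res, 3))
    for t in range(spec.n_frames):
        macro = spec.macrostates[series[t]]
        for attempt in range(100):
            phi = macro.phi + rng.normal(0.0, spec.jitter_sigma, n_res)
            psi = macro.psi + rng.normal(0.0, spec.jitter_sigma, n_res)
            coords = engine.build_backbone(phi, psi)
            if _has_collision(coords):
                continue
            if spec.proximity_constraint is not None and macro.name == "hairpin":
                ri, rj, dmax = spec.proximity_constraint
                ca_i, ca_j = coords[3 * (ri - 1) + 1], coords[3 * (rj - 1) + 1]
                if np.linalg.norm(ca_i - ca_j) > dmax:
                    continue
            frames[t] = coords
            break
        else:
            raise RuntimeError(
                f"failed to build a collision-free frame for macrostate "
                f"{macro.name!r} after 100 attempts"
            )
    ens = TrajectoryEnsemble(_backbone_topology(n_res), frames, dt=spec.dt)
    return ens, series


# -- the Aβ-like three-macrostate study conditions --------------------------
#
# 42 residues; an extended random-coil state, a central helix state and a
# β-hairpin state whose turn brings two strands into antiparallel contact
# and holds the Glu22/Asp23–Lys28 analogue residues close, mimicking the
# salt-bridge-stabilized hairpin signature.  Turn dihedrals were designed
# geometrically with the backbone builder (type-I'-like tight turn).
TURN_DIHEDRALS = {
    "1": (65.0, 30.0),  # turn position i+1 (left-handed)
    "2": (70.0, 20.0),  # turn position i+2
}

COIL_PATTERN = "C" * 42
HELIX_PATTERN = "C" * 8 + "H" * 26 + "C" * 8
HAIRPIN_PATTERN = "C" * 16 + "E" * 8 + "12" + "E" * 8 + "C" * 8


def abeta_like_spec(
    n_frames: int = 2000,
    seed: int = 0,
    jitter_sigma: float = 6.0,
    transition_matrix: np.ndarray | None = None,
    dt: float = 1.0,
) -> MacrostateSpec:
    """Default study conditions: coil/helix/hairpin with stationary
    populations (0.6, 0.3, 0.1) via a detailed-balance Markov matrix."""
    if transition_matrix is None:
        transition_matrix = np.array(
            [
                [0.97, 0.02, 0.01],
                [0.04, 0.95, 0.01],
                [0.06, 0.03, 0.91],
            ]
        )
    macrostates = [
        Macrostate.from_pattern("coil", COIL_PATTERN),
        Macrostate.from_pattern("helix", HELIX_PATTERN),
        Macrostate.from_pattern("hairpin", HAIRPIN_PATTERN, special=TURN_DIHEDRALS),
    ]
    return MacrostateSpec(
        macrostates,
        transition_matrix,
        n_frames=n_frames,
        seed=seed,
        jitter_sigma=jitter_sigma,
        dt=dt,
        proximity_constraint=(23, 28, 5.0),
    )


# -- water configurations ---------------------------------------------------

def generate_water_configuration(
    kind: str,
    n: int,
    density: float = 0.0334,  # Å⁻³, liquid-water oxygen number density
    jitter_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oxygen point configurations spanning the order spectrum.

    kinds: ``ideal_gas`` (uniform), ``diamond_lattice`` (perfectly
    4-coordinated tetrahedral network), ``perturbed_lattice`` (lattice
    plus Gaussian displacement of ``jitter_sigma`` Å).  Returns
    (coordinates, box).  For lattices, ``n`` is rounded to the nearest
    8·m³ compatible with the conventional cell and the choice is logged.
    """
    if n <= 0 or density <= 0:
        raise ValueError("n and density must be positive")
    rng = np.random.default_rng(seed)
    if kind == "ideal_gas":
        edge = (n / density) ** (1.0 / 3.0)
        box = np.full(3, edge)
        return rng.uniform(0.0, edge, size=(n, 3)), box
    if kind in ("diamond_lattice", "perturbed_lattice"):
        m = max(1, round((n / 8.0) ** (1.0 / 3.0)))
        n_actual = 8 * m**3
        if n_actual != n:
            import logging

            logging.getLogger("tnkit").warning(
                "diamond lattice requires 8·m³ sites; using n=%d instead of %d", n_actual, n
            )
        a = (8.0 / density) ** (1.0 / 3.0)  # conventional cell edge
        fcc = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        basis = np.vstack([fcc, fcc + 0.25])
        cells = np.array(
            [[i, j, k] for i in range(m) for j in range(m) for k in range(m)], dtype=float
        )
        coords = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
        box = np.full(3, m * a)
        if kind == "perturbed_lattice" and jitter_sigma > 0:
            coords = coords + rng.normal(0.0, jitter_sigma, coords.shape)
        return np.mod(coords, box), box
    raise ValueError(f"unknown water configuration kind: {kind!r}")


# -- H-bond renewal traces --------------------------------------------------

def generate_hbond_traces(
    n_bonds: int,
    n_frames: int,
    dt: float = 0.5,
    on_shape: float = 0.7,
    on_scale: float = 10.0,
    off_scale: float = 200.0,
    seed: int = 0,
) -> HBondTraceSet:
    """Alternating on/off renewal traces: on-durations Weibull(shape β,
    scale τ) — whose survival is exactly exp(−(t/τ)^β) — off-durations
    exponential(off_scale); all durations in ps."""
    if min(n_bonds, n_frames) <= 0 or min(dt, on_shape, on_scale, off_scale) <= 0:
        raise ValueError("all parameters must be positive")
    if on_shape > 1:
        raise ValueError("on_shape (β) must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    horizon = n_frames * dt
    h = np.zeros((n_bonds, n_frames), dtype=np.int8)
    t_grid = np.arange(n_frames) * dt
    p_on = 1.0  # every trace starts with a fresh on-interval at a bond-formation event
    for b in range(n_bonds):
        t = 0.0
        state_on = rng.random() < p_on
        while t < horizon:
            if state_on:
                dur = on_scale * rng.weibull(on_shape)
                lo, hi = np.searchsorted(t_grid, [t, t + dur])
                h[b, lo:hi] = 1
            else:
                dur = rng.exponential(off_scale)
            t += dur
            state_on = not state_on
    bonds = [(3 * b, 3 * b + 1, 3 * b + 2) for b in range(n_bonds)]
    return HBondTraceSet(bonds, h, dt=dt)


# -- toy ion systems --------------------------------------------------------

def generate_ion_system(
    reference_atoms: np.ndarray,
    n_ions: int,
    placement: str = "uniform",
    box: np.ndarray | None = None,
    r0: float = 2.2,
    width: float = 0.1,
    seed: int = 0,
    min_separation: float = 1.0,
) -> np.ndarray:
    """Ion coordinates around reference atoms.

    ``uniform`` fills the box uniformly (resampling ions landing within
    ``min_separation`` Å of a reference atom); ``shell`` places each ion
    at radius N(r0, width) from a randomly chosen reference atom, giving
    a g(r) peak at r0.
    """
    reference_atoms = np.atleast_2d(np.asarray(reference_atoms, dtype=float))
    if box is None:
        raise ValueError("a box is required")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    if placement == "uniform":
        out = np.empty((n_ions, 3))
        count = 0
        while count < n_ions:
            cand = rng.uniform(0.0, 1.0, size=(n_ions, 3)) * box
            delta = cand[:, None, :] - reference_atoms[None, :, :]
            delta -= box * np.round(delta / box)
            ok = np.sqrt((delta**2).sum(-1)).min(axis=1) >= min_separation
            take = min(int(ok.sum()), n_ions - count)
            out[count : count + take] = cand[ok][:take]
            count += take
        return out
    if placement == "shell":
        if r0 >= box.min() / 2:
            raise ValueError("shell radius must be below half the box edge")
        ref_pick = rng.integers(0, len(reference_atoms), size=n_ions)
        directions = rng.normal(size=(n_ions, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        radii = rng.normal(r0, width, size=n_ions)
        radii = np.abs(radii)
        return np.mod(reference_atoms[ref_pick] + directions * radii[:, None], box)
    raise ValueError(f"unknown placement: {placement!r}")
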