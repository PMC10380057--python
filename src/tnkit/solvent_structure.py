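"""Water-structure analysis: radial distribution functions and the
translational (T) and orientational/tetrahedral (Q) order parameters.

T integrates the deviation of the oxygen–oxygen RDF from 1 over the
density-rescaled distance ζ = r·ρ^{1/3} up to ζc (default 2.8, chosen
where |g − 1| has decayed):

    T = (1/ζc) ∫₀^ζc |g(ζ) − 1| dζ

so an ideal gas (g ≡ 1) gives T = 0 while crystals with long-range
order give large T.  Q measures how tetrahedrally the 4 nearest oxygen
neighbors of a central oxygen are arranged:

    q_i = 1 − (3/8) Σ_{j<k} (cos ψ_jk + 1/3)²,   Q = ⟨q_i⟩

which is 1 for a perfect tetrahedron and averages to 0 for uniformly
random neighbor directions (individual q values can be negative for
pathological geometries; condensed-phase values fall in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .trajectory_io import TrajectoryEnsemble, pair_distances

__all__ = [
    "RDFProfile",
    "OrderParameters",
    "compute_rdf",
    "translational_order",
    "tetrahedral_q",
    "orientational_order",
    "select_vicinity",
]

DEFAULT_ZETA_C = 2.8


@dataclass
class RDFProfile:
    """A binned radial distribution function with the metadata needed for
    ζ-rescaling (ρ = N/V)."""

    bin_edges: np.ndarray  # Å, len = n_bins + 1
    g: np.ndarray
    rho: float  # number density, Å⁻³
    n_particles: int = 0
    volume: float = 0.0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.g) != len(self.bin_edges) - 1:
            raise ValueError("need one g value per bin")
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")
        if self.rho <= 0:
            raise ValueError("density must be positive")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_g_of_zeta(cls, zeta_edges, g) -> "RDFProfile":
        """Build a profile whose radial axis is already the rescaled ζ
        (unit density, so ζ = r)."""
        return cls(zeta_edges, g, rho=1.0)


@dataclass
class OrderParameters:
    Q: float
    q_values: np.ndarray
    T: float | None = None
    zeta_c: float = DEFAULT_ZETA_C


def compute_rdf(
    positions: np.ndarray,
    box: np.ndarray,
    bins: int = 200,
    r_max: float | None = None,
) -> RDFProfile:
    """Oxygen–oxygen (or any single-species) RDF under periodic
    minimum-image distances, with the standard shell-volume/ideal-gas
    normalization."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must be (n, 3)")
    n = len(positions)
    if n < 2:
        raise ValueError("need at least two particles for an RDF")
    box = np.asarray(box, dtype=float)
    half_min_edge = box.min() / 2.0
    if r_max is None:
        r_max = half_min_edge
    if r_max > half_min_edge + 1e-9:
        raise ValueError(
            f"r_max {r_max:g} Å exceeds half the shortest box edge ({half_min_edge:g} Å)"
        )
    wrapped = np.mod(positions, box)
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    if pairs.size:
        delta = wrapped[pairs[:, 0]] - wrapped[pairs[:, 1]]
        delta -= box * np.round(delta / box)
        dists = np.sqrt((delta**2).sum(axis=1))
    else:
        dists = np.empty(0)
    edges = np.linspace(0.0, r_max, bins + 1)
    hist, _ = np.histogram(dists, bins=edges)
    volume = float(np.prod(box))
    rho = n / volume
    shell_volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    # hist counts unordered pairs; ideal count per particle is ρ·V_shell
    ideal = rho * shell_volumes * n / 2.0
    g = hist / ideal
    return RDFProfile(edges, g, rho=rho, n_particles=n, volume=volume)


def translational_order(rdf: RDFProfile, zeta_c: float = DEFAULT_ZETA_C) -> float:
    """T = (1/ζc) ∫₀^ζc |g(ζ) − 1| dζ by the trapezoidal rule on the
    profile's ζ-rescaled bin centers.

    The integrand is extended flat from the first bin center down to
    ζ = 0 and linearly interpolated at ζc.  Raises if the profile does
    not cover ζc.
    """
    if zeta_c <= 0:
        raise ValueError("zeta_c must be positive")
    scale = rdf.rho ** (1.0 / 3.0)
    zeta = rdf.bin_centers * scale
    zeta_edge_max = rdf.bin_edges[-1] * scale
    if zeta_edge_max < zeta_c:
        raise ValueError(
            f"RDF covers ζ only up to {zeta_edge_max:.3f}, below ζc = {zeta_c:g}; "
            "increase r_max or the particle count"
        )
    dev = np.abs(rdf.g - 1.0)
    grid = np.concatenate(([0.0], zeta))
    vals = np.concatenate(([dev[0]], dev))
    inside = grid < zeta_c
    g_c = float(np.interp(zeta_c, grid, vals))
    grid = np.concatenate((grid[inside], [zeta_c]))
    vals = np.concatenate((vals[inside], [g_c]))
    return float(np.trapezoid(vals, grid) / zeta_c)


def tetrahedral_q(directions: np.ndarray) -> float:
    """q for one center from its four neighbor direction vectors (3-vectors,
    any length; only orientations matter)."""
    d = np.asarray(directions, dtype=float)
    if d.shape != (4, 3):
        raise ValueError("need exactly four neighbor vectors")
    u = d / np.linalg.norm(d, axis=1, keepdims=True)
    total = 0.0
    for j in range(3):
        for k in range(j + 1, 4):
            cos_psi = float(np.dot(u[j], u[k]))
            total += (cos_psi + 1.0 / 3.0) ** 2
    return 1.0 - 3.0 / 8.0 * total


def orientational_order(
    oxygens: np.ndarray,
    box: np.ndarray | None = None,
    centers: np.ndarray | list[int] | None = None,
) -> OrderParameters:
    """Tetrahedral order q for each central oxygen and the mean Q.

    Each center's neighbors are its 4 nearest oxygens (minimum image when
    ``box`` is given), searched among *all* oxygens, not only the centers.
    """
    oxygens = np.asarray(oxygens, dtype=float)
    n = len(oxygens)
    if n < 5:
        raise ValueError("need at least five oxygens (a center plus four neighbors)")
    if centers is None:
        centers = np.arange(n)
    centers = np.asarray(centers, dtype=int)
    if box is not None:
        box = np.asarray(box, dtype=float)
        pts = np.mod(oxygens, box)
        tree = cKDTree(pts, boxsize=box)
    else:
        pts = oxygens
        tree = cKDTree(pts)
    _, idx = tree.query(pts[centers], k=5)
    q = np.empty(len(centers))
    for m, c in enumerate(centers):
        neigh = [i for i in idx[m] if i != c][:4]
        if len(neigh) < 4:
            raise ValueError(f"center {c} has fewer than four distinct neighbors")
        delta = pts[neigh] - pts[c]
        if box is not None:
            delta -= box * np.round(delta / box)
        q[m] = tetrahedral_q(delta)
    return OrderParameters(Q=float(q.mean()), q_values=q)


def select_vicinity(
    ens: TrajectoryEnsemble,
    frame: int,
    solute_indices,
    oxygen_indices,
    cutoff: float = 10.0,
) -> list[int]:
    """Oxygen atom indices whose minimum (image) distance to any solute
    atom is ≤ cutoff Å, re-evaluated per frame."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    solute_indices = np.asarray(solute_indices, dtype=int)
    oxygen_indices = np.asarray(oxygen_indices, dtype=int)
    if solute_indices.size == 0:
        raise ValueError("solute selection is empty")
    if oxygen_indices.size == 0:
        return []
    coords = ens.frames[frame]
    d = pair_distances(coords[oxygen_indices], coords[solute_indices], ens.box)
    keep = d.min(axis=1) <= cutoff
    return sorted(int(i) for i in oxygen_indices[keep])
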