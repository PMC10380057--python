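"""Hydrogen-bond detection and lifetime kinetics.

A candidate bond is present in a frame when the donor–acceptor
heavy-atom distance is within the cutoff (default 3.5 Å) and the
D–H–A angle at the hydrogen is at least the minimum (default 150°).
The binary existence series h(t) of every bond ever observed is pooled
into the intermittent autocorrelation

    c(t) = Σ_bonds Σ_t0 h(t0)·h(t0 + t) / Σ_bonds Σ_t0 h(t0)²

averaged over all time origins t0, so bonds that break and reform still
correlate and c(0) = 1.  A stretched exponential

    c(t) = exp(−(t/τ)^β)

is fitted by least squares, and the mean lifetime follows analytically
from the survival integral:

    ⟨τ⟩ = (τ/β)·Γ(1/β).

The stretching exponent β ≤ 1 quantifies the deviation from simple
exponential relaxation caused by a distribution of bond environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve
from scipy.special import gamma as gamma_fn

from .trajectory_io import TrajectoryEnsemble, minimum_image_displacements

__all__ = [
    "HBondCriteria",
    "HBondTraceSet",
    "StretchedExpFit",
    "FitError",
    "detect_hbonds",
    "build_traces",
    "autocorrelation",
    "fit_stretched_exponential",
    "mean_lifetime",
]


class FitError(RuntimeError):
    """Stretched-exponential fit failed to converge; carries the best
    iterate and residuals seen."""

    def __init__(self, message, best_params=None, residuals=None):
        super().__init__(message)
        self.best_params = best_params
        self.residuals = residuals


@dataclass(frozen=True)
class HBondCriteria:
    distance_cutoff: float = 3.5  # donor–acceptor heavy-atom distance, Å
    angle_min: float = 150.0  # D–H–A angle, degrees

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.angle_min <= 180:
            raise ValueError("angle minimum must lie in (0, 180]")


@dataclass
class HBondTraceSet:
    """Binary presence matrix h[bond, frame] for identified candidate bonds."""

    bonds: list[tuple[int, int, int]]  # (donor, hydrogen, acceptor) atom indices
    h: np.ndarray  # (n_bonds, n_frames) in {0, 1}
    dt: float  # ps

    def __post_init__(self):
        self.h = np.asarray(self.h)
        if self.h.ndim != 2:
            raise ValueError("h must be (n_bonds, n_frames)")
        if not np.isin(self.h, (0, 1)).all():
            raise ValueError("h entries must be binary")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.h.shape[1]


@dataclass
class StretchedExpFit:
    tau: float  # ps
    beta: float
    mean_tau: float  # ps, (τ/β)·Γ(1/β)
    residual_norm: float

    def __post_init__(self):
        if self.tau <= 0 or not 0 < self.beta <= 1:
            raise ValueError("require τ > 0 and β ∈ (0, 1]")


def _resolve_hydrogens(ens: TrajectoryEnsemble, frame: int, donors) -> dict[int, list[int]]:
    """Hydrogens covalently attached to each donor heavy atom, from
    topology bonds when present, else by an element-H-within-1.2-Å
    geometric heuristic."""
    top = ens.topology
    hydro = {d: [] for d in donors}
    h_atoms = [i for i, a in enumerate(top.atoms) if a.element.capitalize() == "H"]
    if top.bonds:
        donor_set = set(donors)
        for i, j in top.bonds:
            if i in donor_set and j in h_atoms:
                hydro[i].append(j)
            elif j in donor_set and i in h_atoms:
                hydro[j].append(i)
    if not any(hydro.values()):
        coords = ens.frames[frame]
        for d in donors:
            for h in h_atoms:
                delta = minimum_image_displacements(coords[h] - coords[d], ens.box)
                if np.linalg.norm(delta) < 1.2:
                    hydro[d].append(h)
    if not any(hydro.values()):
        raise ValueError(
            "no hydrogens could be assigned to any donor; add topology bonds "
            "or check element records"
        )
    return hydro


def detect_hbonds(
    ens: TrajectoryEnsemble,
    frame: int,
    donors,
    acceptors,
    criteria: HBondCriteria = HBondCriteria(),
) -> set[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples satisfying the geometric
    criterion in one frame."""
    coords = ens.frames[frame]
    hydro = _resolve_hydrogens(ens, frame, donors)
    found = set()
    for d in donors:
        for a in acceptors:
            if a == d:
                continue
            delta_da = minimum_image_displacements(coords[a] - coords[d], ens.box)
            if np.linalg.norm(delta_da) > criteria.distance_cutoff:
                continue
            for h in hydro[d]:
                hd = minimum_image_displacements(coords[d] - coords[h], ens.box)
                ha = minimum_image_displacements(coords[a] - coords[h], ens.box)
                cos_angle = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                angle = np.degrees(np.arccos(np.clip(cos_angle, -1.0, 1.0)))
                if angle >= criteria.angle_min:
                    found.add((d, h, a))
    return found


def build_traces(
    ens: TrajectoryEnsemble,
    donors,
    acceptors,
    criteria: HBondCriteria = HBondCriteria(),
    frames=None,
) -> HBondTraceSet:
    """Binary h(t) series for every candidate bond observed at least once."""
    frames = range(ens.n_frames) if frames is None else list(frames)
    per_frame = [detect_hbonds(ens, f, donors, acceptors, criteria) for f in frames]
    bonds = sorted(set().union(*per_frame)) if per_frame else []
    if not bonds:
        raise ValueError("no hydrogen bonds detected in any frame")
    index = {b: i for i, b in enumerate(bonds)}
    h = np.zeros((len(bonds), len(per_frame)), dtype=np.int8)
    for f, found in enumerate(per_frame):
        for b in found:
            h[index[b], f] = 1
    return HBondTraceSet(bonds, h, dt=ens.dt)


def autocorrelation(
    traces: HBondTraceSet, max_lag: int | None = None, origins: str = "all"
) -> np.ndarray:
    """Multi-origin intermittent autocorrelation c(t), t = 0..max_lag.

    With ``origins="all"`` (the field convention) every frame is a time
    origin: for each lag t the sums run over all origins t0 with t0 + t
    inside the series, pooled over bonds, and the denominator uses the
    same origins, so c(0) = 1 exactly whenever any bond exists.  Note
    that sampling origins uniformly over on-time weights long bond
    episodes more (the inspection paradox), so the fitted (τ, β) are
    effective parameters of the observed relaxation, not of the
    underlying episode-length distribution.

    With ``origins="formation"`` only frames where a bond forms (0→1
    edges, or frame 0 if already bonded) are origins, so c(t) estimates
    the survival probability of a bond t after formation — for a renewal
    process with on-survival exp(−(t/τ)^β) this recovers (τ, β)
    without the inspection bias.
    """
    h = traces.h.astype(float)
    n_frames = h.shape[1]
    if max_lag is None:
        max_lag = n_frames - 1
    if not 0 <= max_lag < n_frames:
        raise ValueError("max_lag must be smaller than the trace length")
    if not h.any():
        raise ValueError("all traces are zero: no bonds to correlate")
    if origins == "formation":
        num = np.zeros(max_lag + 1)
        den = np.zeros(max_lag + 1)
        for row in h:
            starts = np.nonzero(np.diff(np.concatenate(([0.0], row))) > 0)[0]
            for t0 in starts:
                span = min(max_lag + 1, n_frames - t0)
                num[:span] += row[t0 : t0 + span]
                den[:span] += 1.0
        den = np.where(den > 0, den, np.nan)
        return np.nan_to_num(num / den, nan=0.0)
    if origins != "all":
        raise ValueError("origins must be 'all' or 'formation'")
    # numerator via correlation: Σ_b Σ_t0 h[t0]·h[t0+t]
    num = np.zeros(max_lag + 1)
    for row in h:
        corr = fftconvolve(row, row[::-1])[n_frames - 1 : n_frames + max_lag]
        num += corr
    # denominator: Σ_b Σ_{t0 < n_frames - t} h[t0]²  (h binary → h² = h)
    tail = np.cumsum(h.sum(axis=0)[::-1])[::-1]  # tail[t0] = Σ_{s ≥ t0} h[s]
    total = tail[0]
    den = np.array([total - (tail[n_frames - t] if t > 0 else 0.0) for t in range(max_lag + 1)])
    den = np.where(den > 0, den, np.nan)
    c = np.round(num, 10) / den
    return np.nan_to_num(c, nan=0.0)


def _stretched_exp(t, tau, beta):
    return np.exp(-((t / tau) ** beta))


def fit_stretched_exponential(c: np.ndarray, dt: float) -> StretchedExpFit:
    """Least-squares fit of exp(−(t/τ)^β) to a correlation curve.

    The fit window runs from t = 0 to the first time c drops below 0.01
    (or the series end); the initial guess is τ = first 1/e crossing,
    β = 0.8, with bounds τ > 0 and β ∈ (0, 1].
    """
    c = np.asarray(c, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if abs(c[0] - 1.0) > 0.05:
        raise ValueError("correlation curve must start near c(0) = 1")
    below = np.nonzero(c < 0.01)[0]
    end = int(below[0]) if below.size else len(c)
    t = np.arange(end) * dt
    y = c[:end]
    if len(y) < 10:
        raise ValueError("need at least 10 usable correlation points for the fit")
    crossing = np.nonzero(y < np.exp(-1.0))[0]
    tau0 = t[crossing[0]] if crossing.size and crossing[0] > 0 else t[-1] / 2
    tau0 = max(tau0, dt)
    try:
        popt, _ = curve_fit(
            _stretched_exp,
            t,
            y,
            p0=(tau0, 0.8),
            bounds=((1e-12, 1e-6), (np.inf, 1.0)),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"stretched-exponential fit did not converge: {exc}") from exc
    tau, beta = float(popt[0]), float(popt[1])
    resid = y - _stretched_exp(t, tau, beta)
    return StretchedExpFit(
        tau=tau,
        beta=beta,
        mean_tau=mean_lifetime(tau, beta),
        residual_norm=float(np.linalg.norm(resid)),
    )


def mean_lifetime(tau: float, beta: float) -> float:
    """⟨τ⟩ = (τ/β)·Γ(1/β), the exact integral of the stretched-exponential
    survival curve."""
    if tau <= 0:
        raise ValueError("τ must be positive")
    if not 0 < beta <= 1:
        raise ValueError("β must lie in (0, 1]")
    return float(tau / beta * gamma_fn(1.0 / beta))
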