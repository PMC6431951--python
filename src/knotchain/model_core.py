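"""Energy function of the stretched bead-spring chain, in reduced units.

The chain is a Kremer-Grest-style bead-spring polymer: purely repulsive
WCA excluded volume between *all* distinct bead pairs (bonded pairs
included), FENE bonds, a discrete worm-like-chain bending term, and two
smooth repulsive walls at x = 0 and x = L that confine every bead except
the two tethered termini, which sit exactly on the wall planes.

All quantities are expressed in reduced units: energies in epsilon
(= kBT), lengths in sigma, masses in the bead mass m.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .errors import DegenerateGeometryError, OverstretchedBondError

__all__ = [
    "ModelParams",
    "Conformation",
    "EnergyBreakdown",
    "wca_pair_energy",
    "fene_bond_energy",
    "bending_energy",
    "wall_energy",
    "total_energy",
    "forces",
    "WCA_CUTOFF",
]

#: WCA cutoff in units of sigma (minimum of the LJ potential).
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)

# Purely repulsive 9-3 wall: cut and shifted at its minimum so that both
# the energy and its derivative vanish continuously at the cutoff.
_WALL_CUT = (2.0 / 5.0) ** (1.0 / 6.0)
_WALL_SHIFT = (2.0 / 3.0) * np.sqrt(2.5)


@dataclass
class ModelParams:
    """Physical constants of the chain model and the run protocol scale.

    Defaults reproduce the production system: N = 300 beads tethered
    between walls separated by L = 205 sigma, Kremer-Grest bond
    parameters (kappa_fene = 30 eps/sigma^2, R0 = 1.5 sigma), WCA scale
    epsilon = kBT = 1.
    """

    N: int = 300
    epsilon: float = 1.0
    sigma: float = 1.0
    mass: float = 1.0
    kappa_fene: float = 30.0
    R0: float = 1.5
    kappa_b: float = 20.0
    L_wall: float = 205.0
    kBT: float = 1.0
    dt: float = 0.01
    tau_frict: float = 1.0e3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ValueError("N must be >= 3")
        if not (self.R0 > self.sigma > 0):
            raise ValueError("require R0 > sigma > 0")
        if self.kappa_b < 0:
            raise ValueError("kappa_b must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.L_wall <= 0:
            raise ValueError("L_wall must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass
class Conformation:
    """One chain state: ordered bead positions, optional velocities."""

    positions: np.ndarray
    velocities: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions shape")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def bonds(self) -> np.ndarray:
        """Bond vectors u_i = r_{i+1} - r_i, shape (N-1, 3)."""
        return np.diff(self.positions, axis=0)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.bonds(), axis=1)

    def copy(self) -> "Conformation":
        return Conformation(
            self.positions.copy(),
            None if self.velocities is None else self.velocities.copy(),
        )

    def validate(self, params: ModelParams) -> None:
        """Check the structural invariants against *params*.

        Raises on bond overstretch or beads outside the wall slab.
        Terminal beads are allowed to sit exactly on the wall planes.
        """
        if self.n_beads != params.N:
            raise ValueError(f"expected {params.N} beads, got {self.n_beads}")
        b = self.bond_lengths()
        if np.any(b >= params.R0):
            i = int(np.argmax(b))
            raise OverstretchedBondError(
                f"bond {i} has length {b[i]:.4f} >= R0 = {params.R0}"
            )
        if np.any(b <= 0):
            raise DegenerateGeometryError("zero-length bond")
        x = self.positions[1:-1, 0]
        if x.size and (np.any(x <= 0.0) or np.any(x >= params.L_wall)):
            raise ValueError("interior bead outside the wall slab")


@dataclass
class EnergyBreakdown:
    wca: float
    fene: float
    bending: float
    walls: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.wca + self.fene + self.bending + self.walls


def wca_pair_energy(r, params: ModelParams):
    """WCA pair energy 4 eps [(sigma/r)^12 - (sigma/r)^6 + 1/4] for
    r <= 2^(1/6) sigma, zero beyond; continuous at the cutoff.

    Accepts scalars or arrays. Raises on any non-positive distance.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be > 0")
    sr6 = (params.sigma / r) ** 6
    u = 4.0 * params.epsilon * (sr6 * sr6 - sr6 + 0.25)
    out = np.where(r <= WCA_CUTOFF * params.sigma, u, 0.0)
    return float(out) if out.ndim == 0 else out


def fene_bond_energy(b, params: ModelParams):
    """FENE bond energy -(kappa R0^2 / 2) ln(1 - (b/R0)^2).

    Diverges as b -> R0; a bond at or beyond R0 is a topology-safety
    violation and raises :class:`OverstretchedBondError`.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("bond length must be >= 0")
    if np.any(b >= params.R0):
        raise OverstretchedBondError(
            f"bond length {float(np.max(b)):.4f} >= R0 = {params.R0}"
        )
    x = (b / params.R0) ** 2
    out = -0.5 * params.kappa_fene * params.R0**2 * np.log1p(-x)
    return float(out) if out.ndim == 0 else out


def bending_energy(conf: Conformation, params: ModelParams) -> float:
    """Discrete bending energy sum_i kappa_b (1 - cos phi_i) over the
    N - 2 interior joints."""
    u = conf.bonds()
    norms = np.linalg.norm(u, axis=1)
    if np.any(norms <= 0):
        raise DegenerateGeometryError("zero-length bond in bending term")
    cosphi = np.sum(u[:-1] * u[1:], axis=1) / (norms[:-1] * norms[1:])
    cosphi = np.clip(cosphi, -1.0, 1.0)
    return float(params.kappa_b * np.sum(1.0 - cosphi))


def wall_energy(x, params: ModelParams):
    """Repulsive 9-3 wall energy for a bead at distance x from the wall
    at x = 0 plus the mirror wall at x = L; purely repulsive (cut and
    shifted at the potential minimum).

    *x* is the bead x coordinate; raises if a bead touches either plane.
    """
    x = np.asarray(x, dtype=float)
    d = np.minimum(x, params.L_wall - x)
    if np.any(d <= 0):
        raise DegenerateGeometryError("bead at or beyond a wall plane")

    def _u93(dist):
        s = params.sigma / dist
        s3 = s**3
        u = params.epsilon * ((2.0 / 15.0) * s3**3 - s3 + _WALL_SHIFT)
        return np.where(dist < _WALL_CUT * params.sigma, u, 0.0)

    out = _u93(x) + _u93(params.L_wall - x)
    return float(out) if out.ndim == 0 else out


def _pair_matrix(pos: np.ndarray):
    """All-pair displacement vectors and distances (upper triangle)."""
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    iu = np.triu_indices(pos.shape[0], k=1)
    return diff, dist, iu


def total_energy(conf: Conformation, params: ModelParams) -> EnergyBreakdown:
    """Total potential energy, broken down by term.

    The WCA sum runs over all distinct pairs (bonded neighbours
    included); FENE over the N - 1 bonds; bending over the N - 2
    joints; walls act on every bead except the two tethered termini.
    """
    pos = conf.positions
    _, dist, iu = _pair_matrix(pos)
    d = dist[iu]
    if np.any(d <= 0):
        raise DegenerateGeometryError("coincident beads")
    within = d <= WCA_CUTOFF * params.sigma
    e_wca = float(np.sum(wca_pair_energy(d[within], params))) if within.any() else 0.0

    b = conf.bond_lengths()
    e_fene = float(np.sum(fene_bond_energy(b, params)))
    e_bend = bending_energy(conf, params)
    e_wall = float(np.sum(wall_energy(pos[1:-1, 0], params))) if conf.n_beads > 2 else 0.0
    return EnergyBreakdown(wca=e_wca, fene=e_fene, bending=e_bend, walls=e_wall)


def forces(conf: Conformation, params: ModelParams) -> np.ndarray:
    """Analytic forces -grad(U_tot), shape (N, 3).

    The tethered terminal beads (0 and N-1) get a force value like any
    other bead; the integrator is responsible for never moving them.
    """
    pos = conf.positions
    n = pos.shape[0]
    f = np.zeros_like(pos)

    # WCA, all pairs within cutoff
    diff = pos[:, None, :] - pos[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    iu = np.triu_indices(n, k=1)
    dsq = d2[iu]
    if np.any(dsq <= 0):
        raise DegenerateGeometryError("coincident beads")
    cut2 = (WCA_CUTOFF * params.sigma) ** 2
    mask = dsq <= cut2
    if mask.any():
        ii, jj = iu[0][mask], iu[1][mask]
        dd2 = dsq[mask]
        sr6 = (params.sigma**2 / dd2) ** 3
        # -dV/dr / r = 24 eps (2 sr12 - sr6) / r^2
        fmag = 24.0 * params.epsilon * (2.0 * sr6 * sr6 - sr6) / dd2
        fvec = fmag[:, None] * diff[ii, jj]  # force on i, away from j
        for c in range(3):
            f[:, c] += np.bincount(ii, weights=fvec[:, c], minlength=n)
            f[:, c] -= np.bincount(jj, weights=fvec[:, c], minlength=n)

    # FENE bonds
    u = np.diff(pos, axis=0)
    b = np.linalg.norm(u, axis=1)
    if np.any(b >= params.R0):
        raise OverstretchedBondError("bond at or beyond R0")
    if np.any(b <= 0):
        raise DegenerateGeometryError("zero-length bond")
    # dU/db = kappa b / (1 - (b/R0)^2); force on bead i is +dU/db * u_hat
    dudb = params.kappa_fene * b / (1.0 - (b / params.R0) ** 2)
    fb = (dudb / b)[:, None] * u
    f[:-1] += fb
    f[1:] -= fb

    # bending
    if n >= 3 and params.kappa_b != 0.0:
        ua, va = u[:-1], u[1:]
        na = np.linalg.norm(ua, axis=1)
        nb = np.linalg.norm(va, axis=1)
        c = np.sum(ua * va, axis=1) / (na * nb)
        c = np.clip(c, -1.0, 1.0)
        dcdu = va / (na * nb)[:, None] - (c / na**2)[:, None] * ua
        dcdv = ua / (na * nb)[:, None] - (c / nb**2)[:, None] * va
        k = params.kappa_b
        f[: n - 2] -= k * dcdu
        f[1 : n - 1] += k * (dcdu - dcdv)
        f[2:] += k * dcdv

    # walls on interior beads
    if n > 2:
        x = pos[1:-1, 0]
        d0 = x
        d1 = params.L_wall - x
        if np.any(d0 <= 0) or np.any(d1 <= 0):
            raise DegenerateGeometryError("bead at or beyond a wall plane")

        def _f93(dist):
            s3 = (params.sigma / dist) ** 3
            # -dU/dd = eps (9*(2/15) s9 - 3 s3)/d = eps ((6/5) s9 - 3 s3)/d
            mag = params.epsilon * (1.2 * s3**3 - 3.0 * s3) / dist
            return np.where(dist < _WALL_CUT * params.sigma, mag, 0.0)

        f[1:-1, 0] += _f93(d0)  # pushes toward +x
        f[1:-1, 0] -= _f93(d1)  # mirror wall pushes toward -x
    return f
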