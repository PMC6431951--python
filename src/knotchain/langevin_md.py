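"""Underdamped Langevin dynamics with tethered termini.

The thermostat is applied with a BAOAB-style splitting around a
velocity-Verlet core: half kick, half drift, exact Ornstein-Uhlenbeck
velocity update (friction + Gaussian kick), half drift, half kick. With
the friction switched off the scheme reduces exactly to velocity
Verlet, which is what the energy-conservation property tests exercise.

The two terminal beads never move; bonds are monitored every step and a
bond reaching R0 aborts the run, since past that point the chain can
cross itself and the topology is no longer conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional

import numpy as np

from .errors import InstabilityError, TopologySafetyError
from .model_core import Conformation, ModelParams, forces

__all__ = [
    "RunProtocol",
    "Trajectory",
    "integrate",
    "kinetic_temperature",
    "maxwell_boltzmann_velocities",
]


@dataclass
class RunProtocol:
    """Run length, sampling stride (in steps) and equilibration length.

    The default stride of 10^4 steps corresponds to one stored frame
    every 100 tau_MD at dt = 0.01.
    """

    n_steps: int = 100_000
    sample_every: int = 10_000
    equilibration_steps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.n_steps < 0 or self.equilibration_steps < 0:
            raise ValueError("step counts must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunProtocol":
        return cls(**d)


@dataclass
class Trajectory:
    frames: List[Conformation]
    params: Optional[ModelParams] = None
    protocol: Optional[RunProtocol] = None

    def __post_init__(self) -> None:
        ns = {f.n_beads for f in self.frames}
        if len(ns) > 1:
            raise ValueError("frames differ in bead count")

    def __len__(self) -> int:
        return len(self.frames)

    def positions_array(self) -> np.ndarray:
        return np.stack([f.positions for f in self.frames])


def maxwell_boltzmann_velocities(
    n_beads: int, params: ModelParams, rng: np.random.Generator
) -> np.ndarray:
    """Velocities drawn from the Maxwell-Boltzmann distribution, with
    the tethered terminal beads at rest."""
    v = rng.normal(scale=np.sqrt(params.kBT / params.mass), size=(n_beads, 3))
    v[0] = 0.0
    v[-1] = 0.0
    return v


def integrate(
    conf: Conformation,
    params: ModelParams,
    protocol: RunProtocol,
    thermostat: bool = True,
) -> Trajectory:
    """Run Langevin dynamics and return the sampled trajectory.

    Friction gamma = m / tau_frict. ``thermostat=False`` disables both
    friction and noise (pure velocity Verlet, microcanonical). Frames
    are stored every ``protocol.sample_every`` steps after the
    equilibration phase; the initial state is not stored. With a fixed
    seed the output is bit-reproducible.
    """
    rng = np.random.default_rng(protocol.seed)
    pos = conf.positions.copy()
    n = pos.shape[0]
    vel = (
        conf.velocities.copy()
        if conf.velocities is not None
        else np.zeros_like(pos)
    )
    vel[0] = 0.0
    vel[-1] = 0.0
    mobile = np.zeros(n, dtype=bool)
    mobile[1:-1] = True

    dt = params.dt
    m = params.mass
    if thermostat:
        a = np.exp(-dt / params.tau_frict)
        noise_scale = np.sqrt((1.0 - a * a) * params.kBT / m)
    else:
        a = 1.0
        noise_scale = 0.0

    f = forces(Conformation(pos), params)
    frames: List[Conformation] = []
    total = protocol.equilibration_steps + protocol.n_steps

    for step in range(1, total + 1):
        vel[mobile] += 0.5 * dt * f[mobile] / m
        pos[mobile] += 0.5 * dt * vel[mobile]
        if thermostat:
            vel[mobile] = a * vel[mobile] + noise_scale * rng.normal(
                size=(int(mobile.sum()), 3)
            )
        pos[mobile] += 0.5 * dt * vel[mobile]

        if not np.all(np.isfinite(pos)):
            raise InstabilityError(
                f"non-finite positions at step {step}; try a smaller dt"
            )
        b = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        if np.any(b >= params.R0):
            i = int(np.argmax(b))
            raise TopologySafetyError(
                f"bond {i} reached {b[i]:.4f} >= R0 = {params.R0} "
                f"at step {step}; topology no longer guaranteed"
            )

        f = forces(Conformation(pos), params)
        vel[mobile] += 0.5 * dt * f[mobile] / m

        if (
            step > protocol.equilibration_steps
            and (step - protocol.equilibration_steps) % protocol.sample_every == 0
        ):
            frames.append(Conformation(pos.copy(), vel.copy()))

    return Trajectory(frames=frames, params=params, protocol=protocol)


def kinetic_temperature(traj: Trajectory) -> float:
    """Instantaneous kinetic temperature 2<KE> / (3 N_mobile), averaged
    over frames, in units of kBT. Requires stored velocities."""
    if not traj.frames:
        raise ValueError("empty trajectory")
    if traj.params is None:
        raise ValueError("trajectory carries no model parameters")
    n_mobile = traj.frames[0].n_beads - 2
    if n_mobile <= 0:
        raise ValueError("no mobile beads")
    m = traj.params.mass
    temps = []
    for fr in traj.frames:
        if fr.velocities is None:
            raise ValueError("trajectory frames carry no velocities")
        ke = 0.5 * m * float(np.sum(fr.velocities[1:-1] ** 2))
        temps.append(2.0 * ke / (3.0 * n_mobile))
    return float(np.mean(temps))
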