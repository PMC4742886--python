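"""Langevin dynamics in reduced units.

The integrator is a BAOAB-splitting Langevin leapfrog: two half-kicks (B)
and two half-drifts (A) around an exact Ornstein-Uhlenbeck update (O) of
the velocities. With friction = 0 and temperature = 0 the O step is the
identity and the scheme reduces to velocity Verlet, so the zero-friction
limit conserves energy. All masses are 1 in reduced units; the production
protocol of the translocation study uses dt = 0.002 at temperature 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .forcefield import Topology, forces, potential_energy
from .structure_io import Trajectory


class DynamicsError(RuntimeError):
    pass


@dataclass
class SimulationParams:
    """Integration protocol in reduced units.

    dt=0.002 and temperature=0.5 are the study's production values; the
    friction coefficient is a documented stand-in (gamma = 1 reduced units)
    since only "Langevin dynamics" is prescribed.
    """

    n_steps: int
    dt: float = 0.002
    temperature: float = 0.5
    friction: float = 1.0
    seed: int = 0
    save_interval: int = 100
    blowup_bound: float = 1e4     # |coordinate| beyond this aborts the run
    termination: Callable[[np.ndarray], bool] | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.temperature < 0 or self.friction < 0:
            raise ValueError("dt must be > 0; temperature and friction >= 0")
        if self.n_steps < 1 or self.save_interval < 1:
            raise ValueError("n_steps and save_interval must be >= 1")


def run_simulation(topology: Topology, start: np.ndarray,
                   params: SimulationParams) -> tuple[Trajectory, pd.DataFrame]:
    """Integrate and return (trajectory, per-save log).

    The log has one row per saved frame: step, per-term potential energies,
    total energy and the instantaneous kinetic temperature. The run is
    bitwise reproducible for a fixed seed. A termination predicate, if
    given, is evaluated on saved frames only and stops the run at first
    satisfaction.
    """
    x = np.array(start, dtype=float)
    if x.shape != (topology.n_atoms, 3):
        raise DynamicsError(f"start shape {x.shape} != ({topology.n_atoms}, 3)")
    rng = np.random.default_rng(params.seed)
    ndof = x.size
    if params.temperature > 0:
        v = rng.normal(0.0, np.sqrt(params.temperature), size=x.shape)
    else:
        v = np.zeros_like(x)
    c1 = np.exp(-params.friction * params.dt)
    c2 = np.sqrt(max(params.temperature, 0.0) * (1.0 - c1 * c1))
    half = 0.5 * params.dt
    f = forces(topology, x)

    frames, times, log_rows = [], [], []
    for step in range(1, params.n_steps + 1):
        v += half * f
        x += half * v
        if params.friction > 0:
            v = c1 * v + c2 * rng.standard_normal(x.shape)
        x += half * v
        f = forces(topology, x)
        v += half * f
        if step % params.save_interval == 0:
            if np.max(np.abs(x)) > params.blowup_bound:
                raise DynamicsError(f"coordinate blow-up at step {step}")
            frames.append(x.copy())
            times.append(step * params.dt)
            eb = potential_energy(topology, x)
            t_kin = float(np.sum(v * v) / ndof)
            log_rows.append({"step": step, "bond": eb.bond, "angle": eb.angle,
                             "dihedral": eb.dihedral, "contact": eb.contact,
                             "repulsion": eb.repulsion, "potential": eb.total,
                             "kinetic_temperature": t_kin,
                             "total": eb.total + 0.5 * float(np.sum(v * v))})
            if params.termination is not None and params.termination(x):
                break
    if not frames:
        raise DynamicsError("no frames saved; decrease save_interval")
    traj = Trajectory(frames=np.stack(frames), times=np.asarray(times))
    return traj, pd.DataFrame(log_rows)


def integrate_langevin(topology: Topology, start: np.ndarray,
                       params: SimulationParams) -> Trajectory:
    """Integrate Langevin dynamics; see :func:`run_simulation`."""
    traj, _ = run_simulation(topology, start, params)
    return traj


def basin_occupancy(trajectory: Trajectory, topology: Topology,
                    assignment: Callable[[np.ndarray], str]) -> dict[str, float]:
    """Fraction of frames per basin label under an assignment predicate.

    The predicate maps a coordinate frame to a basin label (or
    "transition"); fractions over all returned labels sum to 1.
    """
    labels = [assignment(frame) for frame in trajectory.frames]
    n = len(labels)
    out: dict[str, float] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0.0) + 1.0 / n
    return out


def native_contact_fraction(coords: np.ndarray, topology: Topology,
                            basin: str, tol: float = 1.2) -> float:
    """Fraction of a basin's contacts formed (r < tol * r0) in a frame."""
    cm = topology.contacts
    mask = cm.basin == basin
    if not mask.any():
        raise ValueError(f"no contacts labelled {basin!r}")
    r = np.linalg.norm(coords[cm.i[mask]] - coords[cm.j[mask]], axis=1)
    return float(np.mean(r < tol * cm.r0[mask]))
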