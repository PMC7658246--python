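"""Potential evaluation and Langevin sampling in reduced units.

The potential is the structure-based form: harmonic bonds, angles and
improper/planar dihedrals; cosine flexible dihedrals
``eps * ([1 - cos(phi - phi0)] + 1/2 [1 - cos 3(phi - phi0)])``; 6-12 native
contacts ``eps * [(sigma/r)^12 - 2 (sigma/r)^6]``; a generic r^-12 excluded
volume between all remaining pairs; plus optional harmonic position
restraints.  Dynamics uses a BAOAB Langevin discretization (velocity Verlet
in the zero-friction, microcanonical limit); identical seed and configuration
reproduce the trajectory bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import numpy as np

from . import _kernels
from .structures import AtomSelection, MolecularStructure, _as_selection
from .topology import MultiBasinTopology
from .units import TEMPERATURE

__all__ = [
    "SimulationConfig", "Trajectory", "DynamicsError",
    "dihedral_profile", "contact_potential", "excluded_volume",
    "total_energy", "forces", "run_langevin",
]

_TERM_LABELS = ["bonds", "angles", "impropers", "dihedrals", "contacts",
                "excluded_volume", "extra_excluded_volume", "restraints"]


class DynamicsError(ValueError):
    """Raised for invalid simulation input or numerical blow-up."""


@dataclasses.dataclass
class SimulationConfig:
    """Langevin run parameters (reduced units).

    friction = 0 switches the thermostat off (microcanonical integration);
    ``restraint_spring`` applies to atoms passed as ``restrained`` in
    :func:`run_langevin`.
    """

    n_steps: int
    seed: int
    temperature: float = TEMPERATURE     # epsilon / k_B
    timestep: float = 0.002
    friction: float = 1.0
    restraint_spring: float = 0.1        # epsilon / A^2
    output_stride: int = 100

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise DynamicsError("timestep must be positive")
        if self.temperature < 0:
            raise DynamicsError("temperature must be non-negative")
        if self.n_steps < 1:
            raise DynamicsError("n_steps must be >= 1")
        if self.output_stride < 1:
            raise DynamicsError("output_stride must be >= 1")

    def provenance(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class Trajectory:
    """Time-ordered coordinate frames (Angstrom) plus provenance."""

    frames: np.ndarray            # (n_frames, n_atoms, 3) float32
    times: np.ndarray             # (n_frames,) reduced time
    provenance: dict = dataclasses.field(default_factory=dict)
    energies: np.ndarray | None = None   # total (kinetic+potential) energy

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise DynamicsError("trajectory needs >= 1 frame of (n, 3)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def save(self, path: str) -> None:
        """Write to an .npz array container with a JSON provenance field."""
        extra = {}
        if self.energies is not None:
            extra["energies"] = self.energies
        np.savez_compressed(
            path, frames=self.frames, times=self.times,
            provenance=np.array(json.dumps(self.provenance)), **extra)

    @staticmethod
    def load(path: str) -> "Trajectory":
        with np.load(path, allow_pickle=False) as data:
            return Trajectory(
                frames=data["frames"], times=data["times"],
                provenance=json.loads(str(data["provenance"])),
                energies=data["energies"] if "energies" in data else None)


# ---------------------------------------------------------------------------
# Elementary potential terms
# ---------------------------------------------------------------------------

def dihedral_profile(phi: float | np.ndarray,
                     phi_o: float | np.ndarray) -> float | np.ndarray:
    """Cosine dihedral shape ``[1 - cos d] + 1/2 [1 - cos 3d]``, d=phi-phi_o."""
    d = np.asarray(phi, dtype=float) - np.asarray(phi_o, dtype=float)
    out = (1.0 - np.cos(d)) + 0.5 * (1.0 - np.cos(3.0 * d))
    return float(out) if out.ndim == 0 else out


def contact_potential(sigma: float, r: float | np.ndarray
                      ) -> float | np.ndarray:
    """6-12 contact shape ``(sigma/r)^12 - 2 (sigma/r)^6`` (minimum -1 at r=sigma)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise DynamicsError("contact_potential requires r > 0")
    sr6 = (sigma / r) ** 6
    out = sr6 * sr6 - 2.0 * sr6
    return float(out) if out.ndim == 0 else out


def excluded_volume(epsilon: float, sigma: float,
                    r: float | np.ndarray) -> float | np.ndarray:
    """Repulsive wall ``epsilon (sigma/r)^12``."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise DynamicsError("excluded_volume requires r > 0")
    out = epsilon * (sigma / r) ** 12
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Packed evaluation
# ---------------------------------------------------------------------------

def _pack(topology: MultiBasinTopology,
          restrained_idx: np.ndarray | None = None,
          restraint_positions: np.ndarray | None = None,
          restraint_spring: float = 0.0) -> tuple:
    t = topology
    if restrained_idx is None:
        res_idx = np.zeros(0, dtype=np.int64)
        res_pos = np.zeros((0, 3))
        res_k = np.zeros(0)
    else:
        res_idx = np.asarray(restrained_idx, dtype=np.int64)
        res_pos = np.asarray(restraint_positions, dtype=np.float64)
        res_k = np.full(len(res_idx), float(restraint_spring))
    return (
        t.bonds, t.bond_r0, t.bond_k,
        t.angles, t.angle_theta0, t.angle_k,
        t.impropers, t.improper_chi0, t.improper_k,
        t.dihedrals, t.dihedral_phi0, t.dihedral_strength,
        t.contacts, t.contact_sigma, t.contact_strength,
        t.extra_ev, t.extra_ev_sigma, t.extra_ev_eps,
        t.exclusion_matrix(), float(t.eps_nc), float(t.sigma_nc),
        res_idx, res_pos, res_k,
    )


def _check_frame(topology: MultiBasinTopology, frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != (topology.n_atoms, 3):
        raise DynamicsError(
            f"frame shape {frame.shape} does not match topology "
            f"({topology.n_atoms} atoms)")
    return frame


def total_energy(topology: MultiBasinTopology, frame: np.ndarray,
                 restrained_idx: np.ndarray | None = None,
                 restraint_positions: np.ndarray | None = None,
                 restraint_spring: float = 0.0,
                 electrostatics=None,
                 ) -> tuple[float, dict[str, float]]:
    """Potential energy of a frame, itemized by term (epsilon).

    ``electrostatics`` may be any object exposing
    ``energy(coords, topology) -> float`` (e.g. a screened-electrostatics
    perturbation spec); its value is reported under ``"electrostatics"``.
    """
    frame = _check_frame(topology, frame)
    f = np.zeros_like(frame)
    terms = _kernels.energy_forces(
        frame, *_pack(topology, restrained_idx, restraint_positions,
                      restraint_spring), f)
    by_term = dict(zip(_TERM_LABELS, map(float, terms)))
    if electrostatics is not None:
        by_term["electrostatics"] = float(
            electrostatics.energy(frame, topology))
    return float(sum(by_term.values())), by_term


def forces(topology: MultiBasinTopology, frame: np.ndarray,
           restrained_idx: np.ndarray | None = None,
           restraint_positions: np.ndarray | None = None,
           restraint_spring: float = 0.0) -> np.ndarray:
    """Forces (epsilon / A), equal to minus the gradient of the potential."""
    frame = _check_frame(topology, frame)
    f = np.zeros_like(frame)
    _kernels.energy_forces(
        frame, *_pack(topology, restrained_idx, restraint_positions,
                      restraint_spring), f)
    return f


# ---------------------------------------------------------------------------
# Langevin sampling
# ---------------------------------------------------------------------------

def run_langevin(topology: MultiBasinTopology,
                 start: MolecularStructure,
                 config: SimulationConfig,
                 restrained: AtomSelection | str | None = None,
                 ) -> Trajectory:
    """Sample the topology with Langevin dynamics from ``start``.

    Atoms matched by ``restrained`` are harmonically tethered to their start
    positions with ``config.restraint_spring``.  Frame 0 of the returned
    trajectory is the start configuration; subsequent frames are saved every
    ``config.output_stride`` steps.
    """
    if start.n_atoms != topology.n_atoms:
        raise DynamicsError("start structure does not match topology")
    pos0 = np.asarray(start.coord, dtype=np.float64)
    if restrained is not None:
        res_idx = _as_selection(restrained).resolve(start)
        res_pos = pos0[res_idx].copy()
        spring = config.restraint_spring
    else:
        res_idx, res_pos, spring = None, None, 0.0

    rng = np.random.default_rng(config.seed)
    kT = config.temperature
    vel0 = (rng.standard_normal(pos0.shape) * np.sqrt(kT)
            if kT > 0 else np.zeros_like(pos0))
    noise_seed = int(rng.integers(0, 2 ** 31 - 1))

    packed = _pack(topology, res_idx, res_pos, spring)
    frames, times, energies, _, _, err_step = _kernels.langevin_baoab(
        pos0, vel0, config.timestep, config.friction, kT,
        config.n_steps, config.output_stride, noise_seed, *packed)
    if err_step >= 0:
        raise DynamicsError(
            f"non-finite coordinates at step {err_step}; "
            "reduce the timestep or check the topology")
    return Trajectory(frames=frames, times=times, energies=energies,
                      provenance={"config": config.provenance(),
                                  "n_atoms": topology.n_atoms,
                                  "restrained": res_idx.tolist()
                                  if res_idx is not None else []})
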