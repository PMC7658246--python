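"""Synthetic test systems with known answers.

Two generators drive every desk-scale analysis:

* a *gate system*: a small ligand chain bound in either of two pockets on a
  rigid scaffold, separated by a narrow ring of beads (the constriction)
  that the ligand must thread to exchange pockets.  Endpoint structures with
  the ligand in pocket A (PRE) and pocket B (POST) feed the full
  multi-basin pipeline; the constriction beads are the programmed "gate"
  that contact statistics must recover.  A soft wide-bore tube (pair-
  specific excluded volume, too distant to ever register as a 4 A steric
  contact) keeps the ligand from diffusing away.

* 1D/2D overdamped Brownian dynamics on analytic double-well potentials
  U(x) = h ((x/a)^2 - 1)^2 (+ harmonic channel in 2D), whose barrier
  heights, equilibrium distributions and mean first-passage times are known
  in closed form or by quadrature.

All generators are deterministic in their seed.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np

from . import _kernels
from .contacts import EnsembleWindow
from .coords import CoordinateSpec
from .dynamics import SimulationConfig, Trajectory, run_langevin
from .structures import AtomSelection, MolecularStructure, write_pdb
from .topology import (DEFAULT_MERGE_WEIGHTS, MultiBasinTopology,
                       TopologyError, build_single_basin, merge_multibasin,
                       save_topology, set_contact_epsilon,
                       shadow_contact_map)

__all__ = ["GateSystemSpec", "GateSystem", "AnalyticPotentialSpec",
           "make_gate_system", "simulate_gate", "brownian_1d", "brownian_2d",
           "quartic_potential", "write_fixture_suite"]


# ---------------------------------------------------------------------------
# Gate system
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GateSystemSpec:
    """Geometry and energetics of the synthetic two-pocket gate system.

    Lengths in Angstrom, energies in epsilon.  The pocket at -z (A) holds
    the PRE pose, the pocket at +z (B) the POST pose; the constriction ring
    sits in the z = 0 plane.  Contact strengths mirror the dual-basin
    weighting scheme (basin-unique ligand-scaffold contacts at 0.15 / 0.275
    of the base strength, one anchored pair at 1.5x).
    """

    n_ring: int = 6              # constriction beads
    r_pore: float = 3.6          # constriction radius
    pocket_offset: float = 7.0   # pocket centers at z = +/- this
    n_pocket_a: int = 6
    n_pocket_b: int = 2
    r_pocket: float = 3.0
    n_lig: int = 2               # ligand chain length
    lig_bond: float = 2.5
    eps_c: float = 1.2           # base contact strength (epsilon)
    tube_radius: float = 6.0
    tube_sigma: float = 5.0      # pair-specific wall diameter
    tube_spacing: float = 4.0
    n_tube_side: int = 8         # beads per tube ring
    jitter: float = 0.1          # seeded scaffold roughness
    seed: int = 0
    charge_ligand: float = 0.0   # per-bead charges (e); 0 disables
    charge_scaffold: float = 0.0

    def __post_init__(self) -> None:
        from .topology import SIGMA_NC
        if self.r_pore <= SIGMA_NC:
            raise TopologyError(
                f"pore radius {self.r_pore} A is narrower than the ligand "
                f"excluded volume ({SIGMA_NC} A): ligand cannot thread")
        if self.n_lig < 1 or self.n_ring < 3:
            raise TopologyError("need >= 1 ligand bead and >= 3 ring beads")


@dataclasses.dataclass
class GateSystem:
    """Built gate system: endpoint structures, merged topology and the
    analysis conventions derived from the geometry (not from data)."""

    spec: GateSystemSpec
    pre: MolecularStructure
    post: MolecularStructure
    topology: MultiBasinTopology
    ligand_selection: str
    scaffold_selection: str
    gate_residues: list[tuple[str, int]]        # the constriction beads
    pocket_a_residues: list[tuple[str, int]]
    pocket_b_residues: list[tuple[str, int]]
    rho_spec: CoordinateSpec
    rho_i1: float                                # geometric window centers
    rho_tse: float
    rho_i2: float

    def windows(self, half_width_well: float = 1.5,
                half_width_tse: float = 1.0) -> list[EnsembleWindow]:
        return [
            EnsembleWindow("I1", self.rho_i1 - half_width_well,
                           self.rho_i1 + half_width_well),
            EnsembleWindow("TSE", self.rho_tse - half_width_tse,
                           self.rho_tse + half_width_tse),
            EnsembleWindow("I2", self.rho_i2 - half_width_well,
                           self.rho_i2 + half_width_well),
        ]


def _ring(n: int, radius: float, z: float, phase: float = 0.0) -> np.ndarray:
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.full(n, z)], axis=1)


def make_gate_system(spec: GateSystemSpec | None = None) -> GateSystem:
    """Build the two-pocket gate system from a spec (deterministic in seed).

    The scaffold (chain S) carries pocket A, the constriction ring, pocket B,
    the confining tube and two end caps; the ligand (chain L) is a short
    bonded bead chain.  Contacts come from shadow maps of the two endpoint
    poses merged into a dual-basin topology; the tube confines through
    pair-specific excluded volume only.
    """
    spec = GateSystemSpec() if spec is None else spec
    rng = np.random.default_rng(spec.seed)
    d = spec.pocket_offset

    blocks: list[tuple[str, np.ndarray]] = []   # (kind, coords)
    blocks.append(("pocket_a", _ring(spec.n_pocket_a, spec.r_pocket, -d)))
    blocks.append(("ring", _ring(spec.n_ring, spec.r_pore, 0.0,
                                 phase=np.pi / spec.n_ring)))
    blocks.append(("pocket_b", _ring(spec.n_pocket_b, spec.r_pocket, d)))

    z_end = d + 8.0
    n_rings = int(np.floor(2 * z_end / spec.tube_spacing)) + 1
    tube = []
    for k in range(n_rings):
        z = -z_end + k * spec.tube_spacing
        tube.append(_ring(spec.n_tube_side, spec.tube_radius, z,
                          phase=0.3 * k))
    blocks.append(("tube", np.vstack(tube)))
    blocks.append(("caps", np.array([[0.0, 0.0, -z_end],
                                     [0.0, 0.0, z_end]])))

    kinds: list[str] = []
    coords: list[np.ndarray] = []
    for kind, xyz in blocks:
        xyz = xyz + rng.normal(0.0, spec.jitter, xyz.shape)
        kinds.extend([kind] * len(xyz))
        coords.append(xyz)
    scaffold = np.vstack(coords)
    n_sca = len(scaffold)

    # ligand chain along z, centered on a pocket
    half = 0.5 * spec.lig_bond * (spec.n_lig - 1)
    lig_z = np.linspace(-half, half, spec.n_lig)
    lig_a = np.stack([np.zeros(spec.n_lig), np.zeros(spec.n_lig),
                      lig_z - d], axis=1)
    lig_b = lig_a + np.array([0.0, 0.0, 2.0 * d])

    def structure(lig_xyz: np.ndarray, tag: str) -> MolecularStructure:
        return MolecularStructure(
            atom_name=["BD"] * (n_sca + spec.n_lig),
            res_id=list(range(1, n_sca + 1)) +
                   list(range(1, spec.n_lig + 1)),
            res_name=["GB"] * n_sca + ["LB"] * spec.n_lig,
            chain_id=["S"] * n_sca + ["L"] * spec.n_lig,
            coord=np.vstack([scaffold, lig_xyz]),
            metadata=f"synthetic gate system ({tag}), seed={spec.seed}")

    pre = structure(lig_a, "PRE: ligand in pocket A")
    post = structure(lig_b, "POST: ligand in pocket B")

    pre_topo = build_single_basin(pre, shadow_contact_map(pre))
    post_topo = build_single_basin(post, shadow_contact_map(post))

    pocket_b_first = kinds.index("pocket_b") + 1     # 1-based residue number
    anchor = (AtomSelection(chain="L", residues=[spec.n_lig]),
              AtomSelection(chain="S", residues=[pocket_b_first]))
    merged = merge_multibasin(
        pre_topo, post_topo,
        ligand_group="chain L", scaffold_group="chain S",
        weights=DEFAULT_MERGE_WEIGHTS, anchor_pairs=[anchor])
    merged = set_contact_epsilon(merged, spec.eps_c)

    # the tube exists purely for confinement: borderline ligand-tube pairs
    # picked up by the contact maps would act as sticky wall spots, so they
    # are removed from the merged contact set
    tube_idx = [i for i, k in enumerate(kinds) if k in ("tube", "caps")]
    lig_idx = list(range(n_sca, n_sca + spec.n_lig))
    tube_set = set(tube_idx)
    lig_set = set(lig_idx)
    keep = np.array(
        [not ((i in tube_set and j in lig_set) or
              (j in tube_set and i in lig_set))
         for i, j in merged.contacts.tolist()], dtype=bool)
    merged = merged.replace(
        contacts=merged.contacts[keep],
        contact_sigma=merged.contact_sigma[keep],
        contact_sigma_native=merged.contact_sigma_native[keep],
        contact_weight=merged.contact_weight[keep],
        contact_strength=merged.contact_strength[keep],
        contact_tag=merged.contact_tag[keep])

    # confining tube: pair-specific soft walls against every ligand bead
    pairs = np.array([(min(i, j), max(i, j))
                      for i in tube_idx for j in lig_idx], dtype=np.int64)
    merged = merged.replace(
        extra_ev=np.vstack([merged.extra_ev, pairs]),
        extra_ev_sigma=np.concatenate(
            [merged.extra_ev_sigma, np.full(len(pairs), spec.tube_sigma)]),
        extra_ev_eps=np.concatenate(
            [merged.extra_ev_eps, np.full(len(pairs), 1.0)]),
    )

    if spec.charge_ligand or spec.charge_scaffold:
        charges = np.zeros(merged.n_atoms)
        charges[:n_sca] = spec.charge_scaffold
        charges[n_sca:] = spec.charge_ligand
        merged = merged.replace(charges=charges)

    # progression coordinate: weighted ligand-bead distances to the bottom
    # cap bead -- monotone along the pore axis
    cap_res = n_sca - 1                               # bottom cap, 1-based
    comps = [CoordinateSpec(
        kind="atompair_distance", label=f"r_lig{k+1}",
        selections=(f"chain L and resnum {k+1}",
                    f"chain S and resnum {cap_res}"))
        for k in range(spec.n_lig)]
    if spec.n_lig >= 2:
        w = [0.4] + [0.6 / (spec.n_lig - 1)] * (spec.n_lig - 1)
    else:
        w = [1.0]
    rho_spec = CoordinateSpec(kind="linear_combination", label="rho_gate",
                              components=comps, weights=w)

    # geometric window centers from the endpoint/ring poses
    from .coords import evaluate_coordinate
    rho_i1 = float(evaluate_coordinate(rho_spec, pre.coord[None], pre)[0])
    rho_i2 = float(evaluate_coordinate(rho_spec, post.coord[None], post)[0])
    mid = pre.coord.copy()
    mid[n_sca:, 2] += d      # ligand shifted to the ring plane
    rho_tse = float(evaluate_coordinate(rho_spec, mid[None], pre)[0])

    def residues(kind: str) -> list[tuple[str, int]]:
        return [("S", i + 1) for i, k in enumerate(kinds) if k == kind]

    return GateSystem(
        spec=spec, pre=pre, post=post, topology=merged,
        ligand_selection="chain L", scaffold_selection="chain S",
        gate_residues=residues("ring"),
        pocket_a_residues=residues("pocket_a"),
        pocket_b_residues=residues("pocket_b"),
        rho_spec=rho_spec, rho_i1=rho_i1, rho_tse=rho_tse, rho_i2=rho_i2)


def simulate_gate(system: GateSystem,
                  n_steps: int = 2_000_000,
                  seed: int = 1,
                  output_stride: int = 25,
                  temperature: float = 0.5,
                  scaffold_restraint: float = 10.0,
                  topology: MultiBasinTopology | None = None,
                  start: MolecularStructure | None = None) -> Trajectory:
    """Langevin run of the gate system with a rigidly restrained scaffold.

    The scaffold is tethered stiffly (default 10 epsilon/A^2) so the pore
    geometry is preserved while the ligand diffuses; pass a perturbed
    ``topology`` to simulate modified models directly.
    """
    cfg = SimulationConfig(n_steps=n_steps, seed=seed,
                           temperature=temperature,
                           output_stride=output_stride,
                           restraint_spring=scaffold_restraint)
    return run_langevin(topology or system.topology,
                        start or system.pre, cfg,
                        restrained=system.scaffold_selection)


def make_fep_check_system(seed: int = 0
                          ) -> tuple[GateSystem, MultiBasinTopology]:
    """Fast-mixing gate instance for perturbation-estimator cross-checks.

    Comparing an exponential-average free-energy change against a direct
    simulation of the perturbed model is a per-bin identity, but testing it
    demands dense sampling of the barrier-top bin in *both* simulations.
    The standard two-pocket system crosses its barrier only a handful of
    times per desk-scale run, so the comparison would be dominated by
    rare-event noise.  This instance removes that noise at the source: a
    single-bead ligand (no threading-alignment entropy), softer pocket
    contacts (eps_c = 0.6), and the far pocket blocked by wide soft walls
    in the base model itself, leaving one ergodic component in which the
    approach to the constriction is sampled continuously.

    Returns the gate system and the plugged base topology (apply the
    perturbation of interest on top of the latter).
    """
    system = make_gate_system(GateSystemSpec(n_lig=1, eps_c=0.6, seed=seed))
    ref = system.pre
    pocket_b = set(system.pocket_b_residues)
    pb_atoms = [i for i in range(ref.n_atoms)
                if (str(ref.chain_id[i]), int(ref.res_id[i])) in pocket_b]
    lig_atoms = AtomSelection.parse(system.ligand_selection).resolve(ref)
    pairs = np.array([(min(i, j), max(i, j))
                      for i in pb_atoms for j in lig_atoms.tolist()],
                     dtype=np.int64)
    topo = system.topology
    plugged = topo.replace(
        extra_ev=np.vstack([topo.extra_ev, pairs]),
        extra_ev_sigma=np.concatenate(
            [topo.extra_ev_sigma, np.full(len(pairs), 7.0)]),
        extra_ev_eps=np.concatenate(
            [topo.extra_ev_eps, np.full(len(pairs), 1.0)]),
    )
    return system, plugged


# ---------------------------------------------------------------------------
# Analytic-potential Brownian dynamics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AnalyticPotentialSpec:
    """Overdamped dynamics on an analytic double well (beta = 1).

    ``h`` is the barrier height in k_B T, wells sit at x = +/- a; the 2D
    form adds an orthogonal harmonic channel (k_y/2) y^2.
    """

    form: str = "quartic"        # "quartic" | "double_well_2d"
    h: float = 4.0               # k_B T
    a: float = 1.0               # A
    k_y: float = 2.0             # k_B T / A^2 (2D only)
    diffusion: float = 1.0       # A^2 / time
    dt: float = 0.001
    n_steps: int = 1_000_000
    x0: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h < 0 or self.a <= 0:
            raise ValueError("need h >= 0 and a > 0")
        # explicit Euler stability: dt below the inverse max curvature
        stiffness = 23.0 * max(self.h, 1e-12) * self.diffusion / self.a ** 2
        if self.dt * stiffness > 1.0:
            raise ValueError(
                f"dt={self.dt} too large for h={self.h}, a={self.a} "
                f"(limit ~{1.0 / stiffness:.2e})")


def quartic_potential(x: np.ndarray, h: float, a: float) -> np.ndarray:
    """U(x) = h ((x/a)^2 - 1)^2 in k_B T."""
    return h * ((np.asarray(x, dtype=float) / a) ** 2 - 1.0) ** 2


def brownian_1d(spec: AnalyticPotentialSpec
                ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Euler-Maruyama series on the quartic double well.

    Returns (x series, (grid, U on grid)); deterministic in seed.
    """
    x0 = -spec.a if spec.x0 is None else spec.x0
    x = _kernels.brownian_quartic_1d(
        float(x0), float(spec.h), float(spec.a), float(spec.diffusion),
        float(spec.dt), int(spec.n_steps), int(spec.seed) & 0x7FFFFFFF)
    grid = np.linspace(-2.5 * spec.a, 2.5 * spec.a, 501)
    return x, (grid, quartic_potential(grid, spec.h, spec.a))


def brownian_2d(spec: AnalyticPotentialSpec) -> np.ndarray:
    """(n+1, 2) series on the 2D double well with harmonic channel."""
    x0 = -spec.a if spec.x0 is None else spec.x0
    return _kernels.brownian_double_well_2d(
        float(x0), 0.0, float(spec.h), float(spec.a), float(spec.k_y),
        float(spec.diffusion), float(spec.dt), int(spec.n_steps),
        int(spec.seed) & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

def write_fixture_suite(outdir: str, seed: int = 0) -> list[str]:
    """Write a deterministic fixture set exercising every reader.

    Emits endpoint PDBs, the merged topology, a short trajectory, a
    coordinate time series (TSV), a charge table (TSV) and a run config
    (YAML); returns the manifest (also written as manifest.tsv).
    """
    import yaml

    os.makedirs(outdir, exist_ok=True)
    spec = GateSystemSpec(seed=seed, charge_ligand=-1.0,
                          charge_scaffold=-0.05)
    system = make_gate_system(spec)
    manifest: list[str] = []

    def emit(name: str) -> str:
        path = os.path.join(outdir, name)
        manifest.append(name)
        return path

    write_pdb(system.pre, emit("gate_pre.pdb"))
    write_pdb(system.post, emit("gate_post.pdb"))
    save_topology(system.topology, emit("gate_topology.txt"))

    traj = simulate_gate(system, n_steps=2000, seed=seed + 1,
                         output_stride=100)
    traj.save(emit("gate_short.npz"))

    from .coords import evaluate_coordinate
    rho = evaluate_coordinate(system.rho_spec, traj, system.pre)
    with open(emit("gate_rho.tsv"), "w") as fh:
        fh.write("# time\trho\n")
        for t, r in zip(traj.times, rho):
            fh.write(f"{t:.4f}\t{r:.6f}\n")

    charges = system.topology.charges
    with open(emit("charges.tsv"), "w") as fh:
        fh.write("# chain\tresidue\tatom\tcharge\n")
        s = system.pre
        for i in range(s.n_atoms):
            fh.write(f"{s.chain_id[i]}\t{s.res_id[i]}\t{s.atom_name[i]}\t"
                     f"{charges[i]:.4f}\n")

    config = {
        "seed": seed,
        "structures": {"pre": "gate_pre.pdb", "post": "gate_post.pdb"},
        "topology": "gate_topology.txt",
        "ligand": "chain L",
        "scaffold": "chain S",
        "simulation": {"n_steps": 2000, "temperature": 0.5,
                       "timestep": 0.002, "output_stride": 100},
    }
    with open(emit("config.yaml"), "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    with open(os.path.join(outdir, "manifest.tsv"), "w") as fh:
        fh.write("# file\n")
        for name in manifest:
            fh.write(name + "\n")
    manifest.append("manifest.tsv")
    return manifest
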