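"""Potential terms, forces, and Langevin sampling."""

import numpy as np
import pytest
from scipy import stats

from ribogate.dynamics import (DynamicsError, SimulationConfig, Trajectory,
                               contact_potential, dihedral_profile,
                               excluded_volume, forces, run_langevin,
                               total_energy)
from ribogate.topology import ContactMap, build_single_basin, \
    shadow_contact_map

from conftest import bead_chain


# ---------------------------------------------------------------------------
# elementary terms
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("phi,phi0,expected", [
    (1.3, 1.3, 0.0),
    (1.3 + 2 * np.pi, 1.3, 0.0),            # periodic
    (0.5 + np.pi, 0.5, 3.0),                # (1-cos pi) + (1-cos 3pi)/2
])
def test_dihedral_profile(phi, phi0, expected):
    assert dihedral_profile(phi, phi0) == pytest.approx(expected, abs=1e-12)


def test_contact_potential_values():
    assert contact_potential(3.0, 3.0) == pytest.approx(-1.0)
    assert contact_potential(3.0, 3000.0) == pytest.approx(0.0, abs=1e-7)
    # r = 2 sigma: 2^-12 - 2*2^-6
    assert contact_potential(2.0, 4.0) == pytest.approx(
        1 / 4096 - 2 / 64, abs=1e-9)
    with pytest.raises(DynamicsError):
        contact_potential(2.0, 0.0)


def test_excluded_volume_values():
    assert excluded_volume(1.0, 2.5, 2.5) == pytest.approx(1.0)
    assert excluded_volume(2.0, 2.5, 5.0) == pytest.approx(2.0 / 4096)
    # steric inflation 2.1 -> 3.0 A multiplies the wall by (3/2.1)^12 ~ 72
    ratio = excluded_volume(1.0, 3.0, 4.0) / excluded_volume(1.0, 2.1, 4.0)
    assert ratio == pytest.approx((3.0 / 2.1) ** 12, rel=1e-12)
    assert ratio == pytest.approx(72.0, rel=0.005)
    with pytest.raises(DynamicsError):
        excluded_volume(1.0, 2.5, -1.0)


# ---------------------------------------------------------------------------
# total energy vs an independent scalar-loop oracle
# ---------------------------------------------------------------------------

def _energy_oracle(topo, frame):
    """Term-by-term evaluation written independently of the kernels."""
    def dihedral(p):
        b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        return np.arctan2(m1 @ n2, n1 @ n2)

    e = 0.0
    for (i, j), r0, k in zip(topo.bonds.tolist(), topo.bond_r0, topo.bond_k):
        e += 0.5 * k * (np.linalg.norm(frame[i] - frame[j]) - r0) ** 2
    for (i, j, k_), t0, k in zip(topo.angles.tolist(), topo.angle_theta0,
                                 topo.angle_k):
        u, v = frame[i] - frame[j], frame[k_] - frame[j]
        th = np.arccos(np.clip(
            u @ v / np.linalg.norm(u) / np.linalg.norm(v), -1, 1))
        e += 0.5 * k * (th - t0) ** 2
    for q, phi0, eps in zip(topo.dihedrals.tolist(), topo.dihedral_phi0,
                            topo.dihedral_strength):
        d = dihedral(frame[list(q)]) - phi0
        e += eps * ((1 - np.cos(d)) + 0.5 * (1 - np.cos(3 * d)))
    for (i, j), sig, eps in zip(topo.contacts.tolist(), topo.contact_sigma,
                                topo.contact_strength):
        r = np.linalg.norm(frame[i] - frame[j])
        e += eps * ((sig / r) ** 12 - 2 * (sig / r) ** 6)
    excl = topo.exclusion_matrix()
    n = topo.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if not excl[i, j]:
                r = np.linalg.norm(frame[i] - frame[j])
                e += topo.eps_nc * (topo.sigma_nc / r) ** 12
    for (i, j), sig, eps in zip(topo.extra_ev.tolist(), topo.extra_ev_sigma,
                                topo.extra_ev_eps):
        r = np.linalg.norm(frame[i] - frame[j])
        e += eps * (sig / r) ** 12
    return e


def test_total_energy_matches_oracle():
    rng = np.random.default_rng(17)
    s = bead_chain(5, seed=17)
    topo = build_single_basin(s, shadow_contact_map(s))
    for _ in range(3):
        frame = s.coord + rng.normal(0, 0.5, s.coord.shape)
        e, by_term = total_energy(topo, frame)
        assert e == pytest.approx(_energy_oracle(topo, frame), rel=1e-10)
        assert e == pytest.approx(sum(by_term.values()))


def test_native_state_is_contact_minimum(chain6, chain6_topology):
    e, by_term = total_energy(chain6_topology, chain6.coord)
    assert by_term["bonds"] == pytest.approx(0.0, abs=1e-18)
    assert by_term["angles"] == pytest.approx(0.0, abs=1e-18)
    assert by_term["dihedrals"] == pytest.approx(0.0, abs=1e-14)
    assert by_term["contacts"] == pytest.approx(
        -chain6_topology.contact_strength.sum())


def test_energy_rejects_mismatched_frame(chain6_topology):
    with pytest.raises(DynamicsError, match="atoms"):
        total_energy(chain6_topology, np.zeros((3, 3)))


def test_forces_equal_numerical_gradient():
    """Central-difference check on random frames (1e-5 epsilon/A)."""
    rng = np.random.default_rng(23)
    s = bead_chain(10, seed=23)
    topo = build_single_basin(s, shadow_contact_map(s))
    h = 1e-6
    for _ in range(2):
        frame = s.coord + rng.normal(0, 0.3, s.coord.shape)
        f = forces(topo, frame)
        num = np.zeros_like(frame)
        for i in range(10):
            for c in range(3):
                fp, fm = frame.copy(), frame.copy()
                fp[i, c] += h
                fm[i, c] -= h
                num[i, c] = -(total_energy(topo, fp)[0]
                              - total_energy(topo, fm)[0]) / (2 * h)
        assert np.abs(f - num).max() < 1e-5


# ---------------------------------------------------------------------------
# Langevin sampling
# ---------------------------------------------------------------------------

def test_run_langevin_is_deterministic(chain6, chain6_topology):
    cfg = SimulationConfig(n_steps=2000, seed=5, output_stride=100)
    t1 = run_langevin(chain6_topology, chain6, cfg)
    t2 = run_langevin(chain6_topology, chain6, cfg)
    assert np.array_equal(t1.frames, t2.frames)
    t3 = run_langevin(chain6_topology, chain6,
                      SimulationConfig(n_steps=2000, seed=6,
                                       output_stride=100))
    assert not np.array_equal(t1.frames, t3.frames)


def test_microcanonical_energy_conservation(chain6, chain6_topology):
    """Zero friction: secular energy drift below 1e-4 epsilon per 1e4
    steps (the symplectic shadow-energy oscillation is bounded and is not
    drift)."""
    cfg = SimulationConfig(n_steps=100_000, seed=1, friction=0.0,
                           temperature=0.5, output_stride=100)
    traj = run_langevin(chain6_topology, chain6, cfg)
    steps = np.arange(len(traj.energies)) * cfg.output_stride
    slope = np.polyfit(steps, traj.energies, 1)[0] * 1e4
    assert abs(slope) < 1e-4
    assert traj.energies.max() - traj.energies.min() < 1e-3


def test_single_bond_equipartition():
    """var(bond length) = k_B T / eps_b within 5%."""
    s = bead_chain(2, seed=0, noise=0.0, spacing=1.5)
    topo = build_single_basin(
        s, ContactMap(pairs=np.zeros((0, 2), dtype=int),
                      sigma=np.zeros(0), basin_tag="PRE", cutoff=6.0))
    cfg = SimulationConfig(n_steps=2_000_000, seed=2, friction=2.0,
                           temperature=0.5, output_stride=20)
    traj = run_langevin(topo, s, cfg)
    d = np.linalg.norm(traj.frames[:, 0] - traj.frames[:, 1], axis=1)[200:]
    assert d.var() == pytest.approx(0.5 / 100.0, rel=0.05)


def test_bond_length_boltzmann_law():
    """Sampled bond lengths follow r^2 exp(-k (r-r0)^2 / 2 k_B T)."""
    s = bead_chain(2, seed=0, noise=0.0, spacing=1.5)
    topo = build_single_basin(
        s, ContactMap(pairs=np.zeros((0, 2), dtype=int),
                      sigma=np.zeros(0), basin_tag="PRE", cutoff=6.0))
    cfg = SimulationConfig(n_steps=1_500_000, seed=3, friction=2.0,
                           temperature=0.5, output_stride=150)
    traj = run_langevin(topo, s, cfg)
    d = np.linalg.norm(traj.frames[:, 0] - traj.frames[:, 1], axis=1)[100:]

    grid = np.linspace(1.0, 2.0, 4001)
    pdf = grid ** 2 * np.exp(-100.0 * (grid - 1.5) ** 2 / (2 * 0.5))
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    result = stats.kstest(d, lambda v: np.interp(v, grid, cdf))
    assert result.pvalue > 0.01


def test_restrained_atom_mean_square_displacement():
    """Harmonic tether: <|dr|^2> = 3 k_B T / k."""
    s = bead_chain(1, seed=0, noise=0.0)
    topo = build_single_basin(
        s, ContactMap(pairs=np.zeros((0, 2), dtype=int),
                      sigma=np.zeros(0), basin_tag="PRE", cutoff=6.0))
    cfg = SimulationConfig(n_steps=1_000_000, seed=4, friction=2.0,
                           temperature=0.5, restraint_spring=0.5,
                           output_stride=50)
    traj = run_langevin(topo, s, cfg, restrained="all")
    disp = traj.frames[200:, 0, :] - s.coord[0]
    msd = (disp ** 2).sum(axis=1).mean()
    assert msd == pytest.approx(3 * 0.5 / 0.5, rel=0.08)


def test_blowup_reports_step(chain6, chain6_topology):
    cfg = SimulationConfig(n_steps=5000, seed=1, timestep=1.0,
                           output_stride=10)
    with pytest.raises(DynamicsError, match="step"):
        run_langevin(chain6_topology, chain6, cfg)


def test_trajectory_round_trip(tmp_path, chain6, chain6_topology):
    cfg = SimulationConfig(n_steps=500, seed=9, output_stride=50)
    traj = run_langevin(chain6_topology, chain6, cfg)
    path = tmp_path / "t.npz"
    traj.save(path)
    back = Trajectory.load(path)
    assert np.array_equal(back.frames, traj.frames)
    assert back.provenance["config"]["seed"] == 9


def test_config_validation():
    with pytest.raises(DynamicsError):
        SimulationConfig(n_steps=0, seed=1)
    with pytest.raises(DynamicsError):
        SimulationConfig(n_steps=10, seed=1, timestep=-0.1)
    with pytest.raises(DynamicsError):
        SimulationConfig(n_steps=10, seed=1, temperature=-1.0)
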