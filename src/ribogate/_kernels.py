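"""Numba kernels for potential-energy evaluation and Langevin integration.

Everything here operates on packed primitive arrays; the user-facing API in
:mod:`ribogate.dynamics` handles packing and validation.  All masses are 1 in
reduced units.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# energy term indices
TERM_BOND = 0
TERM_ANGLE = 1
TERM_IMPROPER = 2
TERM_DIHEDRAL = 3
TERM_CONTACT = 4
TERM_EXCLUDED = 5
TERM_EXTRA_EV = 6
TERM_RESTRAINT = 7
N_TERMS = 8


@njit(cache=True)
def _wrap_pi(x: float) -> float:
    while x > np.pi:
        x -= 2.0 * np.pi
    while x <= -np.pi:
        x += 2.0 * np.pi
    return x


@njit(cache=True)
def energy_forces(pos,
                  bonds, bond_r0, bond_k,
                  angles, angle_theta0, angle_k,
                  impropers, improper_chi0, improper_k,
                  dihedrals, dihedral_phi0, dihedral_eps,
                  contacts, contact_sigma, contact_eps,
                  extra_ev, extra_ev_sigma, extra_ev_eps,
                  excl, eps_nc, sigma_nc,
                  res_idx, res_pos, res_k,
                  forces):
    """Fill ``forces`` (zeroed here) and return the per-term energy array."""
    n = pos.shape[0]
    terms = np.zeros(N_TERMS)
    forces[:, :] = 0.0

    # bonds: (k/2)(r - r0)^2
    for m in range(bonds.shape[0]):
        i, j = bonds[m, 0], bonds[m, 1]
        dx0 = pos[i, 0] - pos[j, 0]
        dx1 = pos[i, 1] - pos[j, 1]
        dx2 = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        dr = r - bond_r0[m]
        terms[TERM_BOND] += 0.5 * bond_k[m] * dr * dr
        f = -bond_k[m] * dr / r
        forces[i, 0] += f * dx0
        forces[i, 1] += f * dx1
        forces[i, 2] += f * dx2
        forces[j, 0] -= f * dx0
        forces[j, 1] -= f * dx1
        forces[j, 2] -= f * dx2

    # angles: (k/2)(theta - theta0)^2
    for m in range(angles.shape[0]):
        i, j, k = angles[m, 0], angles[m, 1], angles[m, 2]
        u = pos[i] - pos[j]
        v = pos[k] - pos[j]
        nu = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
        nv = np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
        c = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (nu * nv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        dth = theta - angle_theta0[m]
        terms[TERM_ANGLE] += 0.5 * angle_k[m] * dth * dth
        dedth = angle_k[m] * dth
        for cc in range(3):
            du = (c * u[cc] / nu - v[cc] / nv) / (nu * s)
            dv = (c * v[cc] / nv - u[cc] / nu) / (nv * s)
            forces[i, cc] -= dedth * du
            forces[k, cc] -= dedth * dv
            forces[j, cc] += dedth * (du + dv)

    # dihedrals (proper cosine and harmonic impropers share the geometry)
    for group in range(2):
        quads = dihedrals if group == 0 else impropers
        for m in range(quads.shape[0]):
            i, j, k, l = quads[m, 0], quads[m, 1], quads[m, 2], quads[m, 3]
            b1 = pos[j] - pos[i]
            b2 = pos[k] - pos[j]
            b3 = pos[l] - pos[k]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
            n1sq = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
            n2sq = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
            if n1sq < 1e-12 or n2sq < 1e-12:
                continue
            m1 = np.cross(n1, b2 / nb2)
            x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
            y = m1[0] * n2[0] + m1[1] * n2[1] + m1[2] * n2[2]
            phi = np.arctan2(y, x)
            if group == 0:
                d = phi - dihedral_phi0[m]
                terms[TERM_DIHEDRAL] += dihedral_eps[m] * (
                    (1.0 - np.cos(d)) + 0.5 * (1.0 - np.cos(3.0 * d)))
                dedphi = dihedral_eps[m] * (np.sin(d) + 1.5 * np.sin(3.0 * d))
            else:
                d = _wrap_pi(phi - improper_chi0[m])
                terms[TERM_IMPROPER] += 0.5 * improper_k[m] * d * d
                dedphi = improper_k[m] * d
            # gradient of phi wrt the four positions
            dp1 = (nb2 / n1sq) * n1
            dp4 = -(nb2 / n2sq) * n2
            t12 = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (nb2 * nb2)
            t32 = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (nb2 * nb2)
            for c in range(3):
                g1 = dp1[c]
                g4 = dp4[c]
                g2 = -(1.0 + t12) * g1 + t32 * g4
                g3 = -(1.0 + t32) * g4 + t12 * g1
                forces[i, c] -= dedphi * g1
                forces[j, c] -= dedphi * g2
                forces[k, c] -= dedphi * g3
                forces[l, c] -= dedphi * g4

    # contacts: eps * [ (s/r)^12 - 2 (s/r)^6 ]
    for m in range(contacts.shape[0]):
        i, j = contacts[m, 0], contacts[m, 1]
        dx0 = pos[i, 0] - pos[j, 0]
        dx1 = pos[i, 1] - pos[j, 1]
        dx2 = pos[i, 2] - pos[j, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        sr6 = (contact_sigma[m] * contact_sigma[m] / r2) ** 3
        terms[TERM_CONTACT] += contact_eps[m] * (sr6 * sr6 - 2.0 * sr6)
        # dE/dr = -12 eps/r (sr12 - sr6); pair force along dx
        f = 12.0 * contact_eps[m] * (sr6 * sr6 - sr6) / r2
        forces[i, 0] += f * dx0
        forces[i, 1] += f * dx1
        forces[i, 2] += f * dx2
        forces[j, 0] -= f * dx0
        forces[j, 1] -= f * dx1
        forces[j, 2] -= f * dx2

    # pair-specific extra excluded volume: eps (s/r)^12
    for m in range(extra_ev.shape[0]):
        i, j = extra_ev[m, 0], extra_ev[m, 1]
        dx0 = pos[i, 0] - pos[j, 0]
        dx1 = pos[i, 1] - pos[j, 1]
        dx2 = pos[i, 2] - pos[j, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        sr12 = ((extra_ev_sigma[m] * extra_ev_sigma[m] / r2) ** 3) ** 2
        e = extra_ev_eps[m] * sr12
        terms[TERM_EXTRA_EV] += e
        f = 12.0 * e / r2
        forces[i, 0] += f * dx0
        forces[i, 1] += f * dx1
        forces[i, 2] += f * dx2
        forces[j, 0] -= f * dx0
        forces[j, 1] -= f * dx1
        forces[j, 2] -= f * dx2

    # generic excluded volume over all non-excluded pairs
    s2 = sigma_nc * sigma_nc
    for i in range(n):
        pi0 = pos[i, 0]
        pi1 = pos[i, 1]
        pi2 = pos[i, 2]
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            dx0 = pi0 - pos[j, 0]
            dx1 = pi1 - pos[j, 1]
            dx2 = pi2 - pos[j, 2]
            r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
            sr12 = ((s2 / r2) ** 3) ** 2
            e = eps_nc * sr12
            terms[TERM_EXCLUDED] += e
            f = 12.0 * e / r2
            forces[i, 0] += f * dx0
            forces[i, 1] += f * dx1
            forces[i, 2] += f * dx2
            forces[j, 0] -= f * dx0
            forces[j, 1] -= f * dx1
            forces[j, 2] -= f * dx2

    # harmonic position restraints: (k/2)|x - x0|^2
    for m in range(res_idx.shape[0]):
        i = res_idx[m]
        for c in range(3):
            d = pos[i, c] - res_pos[m, c]
            terms[TERM_RESTRAINT] += 0.5 * res_k[m] * d * d
            forces[i, c] -= res_k[m] * d

    return terms


@njit(cache=True)
def langevin_baoab(pos0, vel0, dt, gamma, kT, n_steps, stride, noise_seed,
                   bonds, bond_r0, bond_k,
                   angles, angle_theta0, angle_k,
                   impropers, improper_chi0, improper_k,
                   dihedrals, dihedral_phi0, dihedral_eps,
                   contacts, contact_sigma, contact_eps,
                   extra_ev, extra_ev_sigma, extra_ev_eps,
                   excl, eps_nc, sigma_nc,
                   res_idx, res_pos, res_k):
    """BAOAB Langevin integrator (velocity Verlet when gamma == 0).

    Returns (frames float32, times, final_pos, final_vel, err_step); a
    non-negative ``err_step`` flags the first step with non-finite
    coordinates.
    """
    n = pos0.shape[0]
    pos = pos0.copy()
    vel = vel0.copy()
    forces = np.zeros((n, 3))
    n_save = n_steps // stride + 1
    frames = np.zeros((n_save, n, 3), dtype=np.float32)
    times = np.zeros(n_save)
    energies = np.zeros(n_save)
    np.random.seed(noise_seed)

    terms = energy_forces(
        pos, bonds, bond_r0, bond_k, angles, angle_theta0, angle_k,
        impropers, improper_chi0, improper_k,
        dihedrals, dihedral_phi0, dihedral_eps,
        contacts, contact_sigma, contact_eps,
        extra_ev, extra_ev_sigma, extra_ev_eps,
        excl, eps_nc, sigma_nc, res_idx, res_pos, res_k, forces)
    frames[0] = pos.astype(np.float32)
    energies[0] = terms.sum() + 0.5 * (vel * vel).sum()
    isave = 1

    c1 = np.exp(-gamma * dt) if gamma > 0.0 else 1.0
    c2 = np.sqrt(max(0.0, (1.0 - c1 * c1) * kT))
    half_dt = 0.5 * dt
    err_step = -1
    for step in range(1, n_steps + 1):
        # B: half kick
        for i in range(n):
            for c in range(3):
                vel[i, c] += half_dt * forces[i, c]
        # A: half drift
        for i in range(n):
            for c in range(3):
                pos[i, c] += half_dt * vel[i, c]
        # O: thermostat
        if gamma > 0.0:
            for i in range(n):
                for c in range(3):
                    vel[i, c] = c1 * vel[i, c] + c2 * np.random.normal()
        # A: half drift
        for i in range(n):
            for c in range(3):
                pos[i, c] += half_dt * vel[i, c]
        # force refresh + B: half kick
        terms = energy_forces(
            pos, bonds, bond_r0, bond_k, angles, angle_theta0,
            angle_k, impropers, improper_chi0, improper_k,
            dihedrals, dihedral_phi0, dihedral_eps,
            contacts, contact_sigma, contact_eps,
            extra_ev, extra_ev_sigma, extra_ev_eps,
            excl, eps_nc, sigma_nc, res_idx, res_pos, res_k, forces)
        for i in range(n):
            for c in range(3):
                vel[i, c] += half_dt * forces[i, c]

        if step % stride == 0:
            ok = True
            for i in range(n):
                for c in range(3):
                    if not np.isfinite(pos[i, c]):
                        ok = False
            if not ok:
                err_step = step
                break
            frames[isave] = pos.astype(np.float32)
            times[isave] = step * dt
            energies[isave] = terms.sum() + 0.5 * (vel * vel).sum()
            isave += 1

    return frames[:isave], times[:isave], energies[:isave], pos, vel, err_step


@njit(cache=True)
def brownian_quartic_1d(x0, h, a, diffusion, dt, n_steps, seed):
    """Overdamped Euler-Maruyama on U(x) = h ((x/a)^2 - 1)^2, beta = 1.

    ``h`` is the barrier height in k_B T.  Returns the full position series
    (n_steps + 1 values).
    """
    np.random.seed(seed)
    x = np.zeros(n_steps + 1)
    x[0] = x0
    amp = np.sqrt(2.0 * diffusion * dt)
    cur = x0
    for step in range(1, n_steps + 1):
        grad = 4.0 * h * cur * (cur * cur / (a * a) - 1.0) / (a * a)
        cur = cur - diffusion * grad * dt + amp * np.random.normal()
        x[step] = cur
    return x


@njit(cache=True)
def brownian_double_well_2d(x0, y0, h, a, k_y, diffusion, dt, n_steps, seed):
    """Overdamped dynamics on U = h((x/a)^2-1)^2 + (k_y/2) y^2, beta = 1."""
    np.random.seed(seed)
    xy = np.zeros((n_steps + 1, 2))
    xy[0, 0] = x0
    xy[0, 1] = y0
    amp = np.sqrt(2.0 * diffusion * dt)
    cx, cy = x0, y0
    for step in range(1, n_steps + 1):
        gx = 4.0 * h * cx * (cx * cx / (a * a) - 1.0) / (a * a)
        gy = k_y * cy
        cx = cx - diffusion * gx * dt + amp * np.random.normal()
        cy = cy - diffusion * gy * dt + amp * np.random.normal()
        xy[step, 0] = cx
        xy[step, 1] = cy
    return xy
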