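"""Numba inner loops for the coarse-grained Langevin annealer.

State layout (C copies, up to 3 particles each):
  pos (C,3) reference positions, theta (C,) rotation about Z,
  offsets (C,3,3) body-frame particle offsets, radii (C,3), pmask (C,3) 0/1,
  dof (C,4) movable flags for x,y,z,theta, mass (C,), inertia (C,),
  ztk (C,) harmonic Z-tether constants (0 = none), z0 (C,) tether targets,
  slabs (S,2) reserved z-intervals, slab_flag (C,) 0/1 exclusion applies.

Units: Å, ps, amu, kcal/mol.  CONV converts kcal/mol/Å/amu to Å/ps².
"""

import numpy as np
from numba import njit

CONV = 418.4  # (kcal/mol/Å) / amu -> Å/ps²


@njit(cache=True)
def _min_image(d, L):
    # wrap to (-L/2, L/2]
    w = d - L * np.floor(d / L + 0.5)
    if w <= -L / 2.0:
        w += L
    return w


@njit(cache=True)
def _world_positions(pos, theta, offsets, pmask, out):
    C = pos.shape[0]
    for i in range(C):
        ct = np.cos(theta[i])
        st = np.sin(theta[i])
        for p in range(3):
            if pmask[i, p]:
                ox, oy, oz = offsets[i, p, 0], offsets[i, p, 1], offsets[i, p, 2]
                out[i, p, 0] = pos[i, 0] + ct * ox - st * oy
                out[i, p, 1] = pos[i, 1] + st * ox + ct * oy
                out[i, p, 2] = pos[i, 2] + oz


@njit(cache=True)
def _pair_force(dist, sigma, kforce, cutoff, r_on):
    """Force magnitude (>0 repulsive) and energy of the switched overlap term."""
    if dist >= sigma or dist >= cutoff:
        return 0.0, 0.0
    v = 0.5 * kforce * (sigma - dist) ** 2
    f = kforce * (sigma - dist)
    if dist > r_on:
        c, ron = cutoff, r_on
        sw = (c - dist) ** 2 * (c + 2.0 * dist - 3.0 * ron) / (c - ron) ** 3
        dsw = 6.0 * (c - dist) * (ron - dist) / (c - ron) ** 3
        f = f * sw - v * dsw
        v = v * sw
    return f, v


@njit(cache=True)
def compute_forces(
    pos, theta, offsets, radii, pmask, dof, slabs, slab_flag,
    box, kforce, cutoff, ztk, z0, world, forces, torques,
):
    C = pos.shape[0]
    _world_positions(pos, theta, offsets, pmask, world)
    for i in range(C):
        forces[i, 0] = forces[i, 1] = forces[i, 2] = 0.0
        torques[i] = 0.0
    energy = 0.0
    r_on = cutoff - 2.0
    for i in range(C):
        for j in range(i + 1, C):
            for p in range(3):
                if not pmask[i, p]:
                    continue
                for q in range(3):
                    if not pmask[j, q]:
                        continue
                    dx = _min_image(world[i, p, 0] - world[j, q, 0], box[0])
                    dy = _min_image(world[i, p, 1] - world[j, q, 1], box[1])
                    dz = _min_image(world[i, p, 2] - world[j, q, 2], box[2])
                    dist = np.sqrt(dx * dx + dy * dy + dz * dz)
                    sigma = radii[i, p] + radii[j, q]
                    if dist < 1e-9:
                        # coincident centers: deterministic tiny kick along x
                        dx, dist = 1e-6, 1e-6
                    fmag, v = _pair_force(dist, sigma, kforce, cutoff, r_on)
                    if v == 0.0 and fmag == 0.0:
                        continue
                    energy += v
                    fx, fy, fz = fmag * dx / dist, fmag * dy / dist, fmag * dz / dist
                    forces[i, 0] += fx
                    forces[i, 1] += fy
                    forces[i, 2] += fz
                    forces[j, 0] -= fx
                    forces[j, 1] -= fy
                    forces[j, 2] -= fz
                    # torque about Z from lever arm (world - pos)
                    rix = world[i, p, 0] - pos[i, 0]
                    riy = world[i, p, 1] - pos[i, 1]
                    torques[i] += rix * fy - riy * fx
                    rjx = world[j, q, 0] - pos[j, 0]
                    rjy = world[j, q, 1] - pos[j, 1]
                    torques[j] += rjx * (-fy) - rjy * (-fx)
    # reserved-slab exclusion walls and Z tethers
    for i in range(C):
        if slab_flag[i]:
            for s in range(slabs.shape[0]):
                zmin, zmax = slabs[s, 0], slabs[s, 1]
                for p in range(3):
                    if not pmask[i, p]:
                        continue
                    r = radii[i, p]
                    z = world[i, p, 2]
                    if zmin - r < z < zmax + r:
                        mid = 0.5 * (zmin + zmax)
                        if z >= mid:
                            pen = (zmax + r) - z
                            forces[i, 2] += kforce * pen
                        else:
                            pen = z - (zmin - r)
                            forces[i, 2] -= kforce * pen
                        energy += 0.5 * kforce * pen * pen
        if ztk[i] > 0.0:
            dzt = pos[i, 2] - z0[i]
            forces[i, 2] -= ztk[i] * dzt
            energy += 0.5 * ztk[i] * dzt * dzt
    return energy


@njit(cache=True)
def overlap_energy(pos, theta, offsets, radii, pmask, box, kforce, cutoff):
    """Total switched overlap energy (no walls/tethers), for diagnostics."""
    C = pos.shape[0]
    world = np.zeros((C, 3, 3))
    _world_positions(pos, theta, offsets, pmask, world)
    energy = 0.0
    r_on = cutoff - 2.0
    for i in range(C):
        for j in range(i + 1, C):
            for p in range(3):
                if not pmask[i, p]:
                    continue
                for q in range(3):
                    if not pmask[j, q]:
                        continue
                    dx = _min_image(world[i, p, 0] - world[j, q, 0], box[0])
                    dy = _min_image(world[i, p, 1] - world[j, q, 1], box[1])
                    dz = _min_image(world[i, p, 2] - world[j, q, 2], box[2])
                    dist = np.sqrt(dx * dx + dy * dy + dz * dz)
                    _f, v = _pair_force(dist, radii[i, p] + radii[j, q], kforce, cutoff, r_on)
                    energy += v
    return energy


@njit(cache=True)
def run_langevin(
    pos, theta, vel, vtheta, offsets, radii, pmask, dof, mass, inertia,
    ztk, z0, slabs, slab_flag, box, nsteps, dt, temperature, gamma,
    kforce, cutoff, seed,
):
    """Langevin-leapfrog dynamics; mutates pos/theta/vel/vtheta in place.

    v <- a v + (1-a)/(gamma m) F + sqrt(kT/m (1-a^2)) xi ;  x <- x + v dt
    with a = exp(-gamma dt).  Immobile degrees of freedom are masked.
    """
    np.random.seed(seed)
    C = pos.shape[0]
    kT = 0.0019872041 * temperature * CONV  # amu Å²/ps²
    a = np.exp(-gamma * dt)
    b = np.sqrt(1.0 - a * a)
    world = np.zeros((C, 3, 3))
    forces = np.zeros((C, 3))
    torques = np.zeros(C)
    for _step in range(nsteps):
        compute_forces(
            pos, theta, offsets, radii, pmask, dof, slabs, slab_flag,
            box, kforce, cutoff, ztk, z0, world, forces, torques,
        )
        for i in range(C):
            m = mass[i]
            sig = np.sqrt(kT / m) * b
            for k in range(3):
                if dof[i, k]:
                    fa = forces[i, k] * CONV / (gamma * m)
                    vel[i, k] = a * vel[i, k] + (1.0 - a) * fa + sig * np.random.normal(0.0, 1.0)
                    pos[i, k] += vel[i, k] * dt
                else:
                    vel[i, k] = 0.0
            if dof[i, 3] and inertia[i] > 1e-9:
                Iner = inertia[i]
                siga = np.sqrt(kT / Iner) * b
                ta = torques[i] * CONV / (gamma * Iner)
                vtheta[i] = a * vtheta[i] + (1.0 - a) * ta + siga * np.random.normal(0.0, 1.0)
                theta[i] += vtheta[i] * dt
            else:
                vtheta[i] = 0.0
    return overlap_energy(pos, theta, offsets, radii, pmask, box, kforce, cutoff)
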