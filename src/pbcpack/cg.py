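"""Coarse-grained sphere model and shrinking-box Langevin annealing.

Every component copy is reduced to 1–3 spheres: a single sphere at the COM
with radius equal to the mass-weighted radius of gyration for solvated
components, and one sphere per non-empty membrane region (above / intra /
below the 24 Å slab) for membrane-embedded components, rigidly linked.  The
sphere system is annealed in 5 stages of Langevin dynamics (100 ps each,
2 fs timestep, 500 K) with a purely repulsive harmonic-overlap pair term
force-switched to zero at 10 Å plus the largest sphere radius, while the box
shrinks from 150% of the target to 100% in equal steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .components import Component
from .geometry import ensure_metrics, membrane_partition
from .sizing import Constraint, Slab, SystemSpec


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap a displacement into (-box/2, box/2] per axis."""
    delta = np.asarray(delta, float)
    box = np.asarray(box, float)
    if np.any(box <= 0):
        raise ValueError("box must be positive")
    w = delta - box * np.floor(delta / box + 0.5)
    return np.where(w <= -box / 2, w + box, w)


@dataclass
class CGParticle:
    center: np.ndarray
    radius: float
    region: str  # whole | above | intra | below
    copy_ref: tuple[int, int]  # (component index, copy index)
    mass: float = 0.0


@dataclass
class AnnealSchedule:
    """5-stage shrinking-box Langevin protocol (defaults are the method's)."""

    n_iterations: int = 5
    duration_per_iteration: float = 100.0  # ps
    timestep: float = 0.002  # ps
    temperature: float = 500.0  # K
    friction: float = 5.0  # ps^-1
    force_constant: float = 10.0  # kcal/mol/Å^2
    start_scale: float = 1.50
    end_scale: float = 1.00

    @property
    def box_scales(self) -> np.ndarray:
        return np.linspace(self.start_scale, self.end_scale, self.n_iterations)

    @property
    def steps_per_iteration(self) -> int:
        return int(round(self.duration_per_iteration / self.timestep))

    def cutoff(self, max_radius: float) -> float:
        return 10.0 + max_radius


@dataclass
class CGSystem:
    """Sphere system state in box-centered coordinates [-L/2, L/2) per axis."""

    target_box: np.ndarray
    pos: np.ndarray  # (C,3) reference positions
    theta: np.ndarray  # (C,) rotation about Z
    offsets: np.ndarray  # (C,3,3) body-frame particle offsets
    radii: np.ndarray  # (C,3)
    pmask: np.ndarray  # (C,3) uint8
    regions: list[list[str]]
    dof: np.ndarray  # (C,4) uint8 movable x,y,z,theta
    mass: np.ndarray  # (C,)
    pmass: np.ndarray  # (C,3) per-particle masses
    inertia: np.ndarray  # (C,)
    ztether_k: np.ndarray  # (C,)
    ztether_z0: np.ndarray  # (C,)
    slab_flag: np.ndarray  # (C,) uint8
    copy_refs: list[tuple[int, int]]
    slabs: np.ndarray  # (S,2)
    rng_seed: int
    box_scale: float = 1.0
    stage_energies: list[float] = field(default_factory=list)

    @property
    def n_copies(self) -> int:
        return len(self.pos)

    @property
    def box(self) -> np.ndarray:
        return self.target_box * self.box_scale

    def particle_centers(self, copy: int) -> np.ndarray:
        """World-frame centers of the copy's particles."""
        ct, st = np.cos(self.theta[copy]), np.sin(self.theta[copy])
        R = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])
        offs = self.offsets[copy][self.pmask[copy].astype(bool)]
        return self.pos[copy] + offs @ R.T

    def particles(self) -> list[CGParticle]:
        out = []
        for i in range(self.n_copies):
            centers = self.particle_centers(i)
            sel = self.pmask[i].astype(bool)
            for c, r, m, reg in zip(
                centers, self.radii[i][sel], self.pmass[i][sel],
                [self.regions[i][k] for k in np.flatnonzero(sel)],
            ):
                out.append(CGParticle(c, float(r), reg, self.copy_refs[i], float(m)))
        return out

    def overlap_energy(self, schedule: AnnealSchedule | None = None) -> float:
        schedule = schedule or AnnealSchedule()
        cutoff = schedule.cutoff(float(self.radii.max()))
        return float(
            _kernels.overlap_energy(
                self.pos, self.theta, self.offsets, self.radii, self.pmask,
                self.box, schedule.force_constant, cutoff,
            )
        )


def build_cg_model(component: Component) -> list[CGParticle]:
    """1 sphere (COM, radius Rg) for solvated components; up to 3 region
    spheres for membrane-embedded components, omitting empty regions."""
    if component.n_atoms == 0:
        raise ValueError("empty component")
    m = ensure_metrics(component)
    if component.comp_type == "membrane_embedded":
        part = m.partition or membrane_partition(component)
        out = []
        for region in ("above", "intra", "below"):
            if region in part:
                reg = part[region]
                out.append(CGParticle(reg.com.copy(), reg.rg, region, (-1, -1), 0.0))
        if not out:
            raise ValueError("membrane component with no atoms in any region")
        return out
    com = component.center_of_mass()
    return [CGParticle(com, m.rg, "whole", (-1, -1), component.mass)]


def _region_masses(component: Component, regions: list[str]) -> list[float]:
    z = component.positions[:, 2]
    masks = {
        "above": z > 12.0, "intra": np.abs(z) <= 12.0, "below": z < -12.0,
        "whole": np.ones(len(z), bool),
    }
    return [float(component.masses[masks[r]].sum()) for r in regions]


def initialize_cg(
    spec: SystemSpec,
    components: list[Component],
    constraints: list[Constraint],
    seed: int,
    schedule: AnnealSchedule | None = None,
) -> CGSystem:
    """Build and randomly initialize the CG sphere system at 150% box scale.

    Fixed copies sit at their constrained coordinates; planar-Z copies draw
    uniform X,Y at the given Z; unconstrained copies draw uniform positions in
    the scaled box outside the reserved slabs.  Deterministic for a seed.
    """
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    target_box = np.asarray(spec.dims, float)
    scaled = target_box * schedule.start_scale

    slabs = np.array([[s.z_min, s.z_max] for s in spec.reserved_slabs], float)
    if len(slabs) == 0:
        slabs = np.zeros((0, 2))

    rows = []  # one per copy
    for ci, (comp, n, con) in enumerate(zip(components, spec.counts, constraints)):
        if comp.comp_type in ("solvent", "ion", "xy_periodic"):
            continue
        parts = build_cg_model(comp)
        regions = [p.region for p in parts]
        pmass = _region_masses(comp, regions)
        centers = np.array([p.center for p in parts])
        ref = np.array(pmass) @ centers / sum(pmass)
        offsets = centers - ref
        radii = [p.radius for p in parts]
        for copy in range(1, n + 1):
            rows.append((ci, copy, comp, con, regions, offsets, radii, pmass, ref))

    C = len(rows)
    pos = np.zeros((C, 3))
    theta = np.zeros(C)
    offs = np.zeros((C, 3, 3))
    radii = np.zeros((C, 3))
    pmask = np.zeros((C, 3), np.uint8)
    dof = np.zeros((C, 4), np.uint8)
    mass = np.zeros(C)
    pmass_arr = np.zeros((C, 3))
    inertia = np.zeros(C)
    ztk = np.zeros(C)
    z0 = np.zeros(C)
    slab_flag = np.zeros(C, np.uint8)
    regions_all: list[list[str]] = []
    copy_refs: list[tuple[int, int]] = []

    def draw_xy():
        return rng.uniform(-scaled[:2] / 2, scaled[:2] / 2)

    def draw_z_outside_slabs(max_r):
        for _ in range(10_000):
            z = rng.uniform(-scaled[2] / 2, scaled[2] / 2)
            if not any(s[0] - max_r < z < s[1] + max_r for s in slabs):
                return z
        raise RuntimeError("cannot place a copy outside the reserved slabs")

    for i, (ci, copy, comp, con, regions, offsets, rr, pm, ref) in enumerate(rows):
        k = len(regions)
        offs[i, :k] = offsets
        radii[i, :k] = rr
        pmask[i, :k] = 1
        pmass_arr[i, :k] = pm
        mass[i] = sum(pm)
        inertia[i] = float(
            sum(m * (o[0] ** 2 + o[1] ** 2) for m, o in zip(pm, offsets))
        )
        regions_all.append(list(regions))
        copy_refs.append((ci, copy))
        membrane = comp.comp_type == "membrane_embedded"
        max_r = max(rr)
        if con.kind == "fixed_xyz":
            pos[i] = (con.x, con.y, con.z)
            if any(Slab(s[0], s[1]).contains(pos[i, 2]) for s in slabs):
                raise ValueError("fixed position lies inside a reserved slab")
        elif con.kind == "fixed_xy":
            pos[i, :2] = (con.x, con.y)
            pos[i, 2] = ref[2]
            dof[i, 3] = 1 if (membrane and k > 1) else 0
        elif con.kind == "planar_z" and not membrane:
            pos[i, :2] = draw_xy()
            pos[i, 2] = con.z
            dof[i, 0] = dof[i, 1] = 1
        elif con.kind == "planar_z" and membrane:
            pos[i, :2] = draw_xy()
            pos[i, 2] = con.z if con.z is not None else ref[2]
            dof[i, :3] = 1
            dof[i, 3] = 1 if k > 1 else 0
            ztk[i] = 1.0  # soft Z tether: "may be changed a bit"
            z0[i] = pos[i, 2]
        elif membrane:  # kind none: XY translation + Z rotation, Z fixed
            pos[i, :2] = draw_xy()
            pos[i, 2] = ref[2]
            dof[i, 0] = dof[i, 1] = 1
            dof[i, 3] = 1 if k > 1 else 0
        else:  # solvated, unconstrained
            pos[i, :2] = draw_xy()
            pos[i, 2] = draw_z_outside_slabs(max_r)
            dof[i, :3] = 1
            slab_flag[i] = 1

    return CGSystem(
        target_box=target_box, pos=pos, theta=theta, offsets=offs, radii=radii,
        pmask=pmask, regions=regions_all, dof=dof, mass=mass, pmass=pmass_arr,
        inertia=inertia, ztether_k=ztk, ztether_z0=z0, slab_flag=slab_flag,
        copy_refs=copy_refs, slabs=slabs, rng_seed=int(seed),
        box_scale=schedule.start_scale,
    )


def anneal(cg: CGSystem, schedule: AnnealSchedule | None = None) -> CGSystem:
    """Run the shrinking-box protocol in place and return the system.

    At each stage boundary the unconstrained coordinates are remapped
    affinely to the new box scale (fixed values and constrained Z positions
    are left untouched), then one stage of Langevin dynamics is run.  The
    per-stage overlap energies are recorded for diagnostics.  Residual
    overlaps are allowed; the all-atom refinement resolves them.
    """
    schedule = schedule or AnnealSchedule()
    if cg.n_copies == 0:
        cg.box_scale = schedule.end_scale
        return cg
    cutoff = schedule.cutoff(float(cg.radii.max()))
    vel = np.zeros_like(cg.pos)
    vtheta = np.zeros_like(cg.theta)
    nsteps = schedule.steps_per_iteration
    for si, scale in enumerate(schedule.box_scales):
        factor = scale / cg.box_scale
        if factor != 1.0:
            for k in range(3):
                movable = cg.dof[:, k].astype(bool)
                if k == 2:
                    movable &= cg.ztether_k <= 0  # tethered Z values stay put
                cg.pos[movable, k] *= factor
        cg.box_scale = float(scale)
        stage_seed = (cg.rng_seed * 1000003 + si * 7919) % (2**31 - 1)
        energy = _kernels.run_langevin(
            cg.pos, cg.theta, vel, vtheta, cg.offsets, cg.radii, cg.pmask,
            cg.dof, cg.mass, cg.inertia, cg.ztether_k, cg.ztether_z0,
            cg.slabs, cg.slab_flag, cg.box, nsteps, schedule.timestep,
            schedule.temperature, schedule.friction, schedule.force_constant,
            cutoff, stage_seed,
        )
        cg.stage_energies.append(float(energy))
    return cg
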