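"""Synthetic rigid bodies with controlled asphericity, and the density sweep.

The blob generator emulates globular macromolecules as anisotropic Gaussian
atom clouds whose gyration-tensor asphericity is dialed to a target (0 for a
sphere, approaching 1 for a rod), standing in for real structures in tests
and benchmarks.  The density sweep reproduces the benchmark protocol of
packing a fixed set of rigid bodies at volume fractions rising in 1% steps
from 10%, 12 seeded replicas per density, until every replica fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .components import Component
from .geometry import asphericity, ensure_metrics
from .refine import PackingError, pack
from .sizing import Constraint, SystemSpec, default_constraints
from .cg import AnnealSchedule


def _axis_scales(target: float) -> tuple[float, float, float]:
    # prolate parametrization (t,1,1): sqrt(A) = (t^2-1)/(t^2+2)  for t >= 1
    s = np.sqrt(target)
    if s >= 1.0:
        raise ValueError("target asphericity must be < 1")
    t2 = (1 + 2 * s) / (1 - s)
    return float(np.sqrt(t2)), 1.0, 1.0


def generate_blob(
    n_atoms: int,
    target_asphericity: float,
    seed: int,
    radius: float = 1.7,
    size: float = 2.5,
    tol: float = 0.03,
    max_attempts: int = 200,
) -> Component:
    """A rigid Gaussian atom cloud with asphericity within ±tol of target.

    Atoms carry a uniform van der Waals radius (1.7 Å by default, carbon-like)
    and carbon masses; ``size`` scales the short-axis standard deviation in Å.
    Points beyond 3 standard radii are resampled so the cloud has no isolated
    outliers.  Deterministic per seed.
    """
    if n_atoms < 10:
        raise ValueError("n_atoms must be >= 10")
    if not 0.0 <= target_asphericity <= 0.6:
        raise ValueError("target asphericity must be in [0, 0.6]")
    scales = np.array(_axis_scales(target_asphericity)) * size
    ss = np.random.SeedSequence([seed, n_atoms])
    for attempt, child in enumerate(ss.spawn(max_attempts)):
        rng = np.random.default_rng(child)
        pts = rng.normal(size=(n_atoms, 3)) * scales
        r = np.linalg.norm(pts / scales, axis=1)
        while np.any(r > 3.0):  # resample outliers: keep the cloud connected
            bad = r > 3.0
            pts[bad] = rng.normal(size=(int(bad.sum()), 3)) * scales
            r = np.linalg.norm(pts / scales, axis=1)
        if abs(asphericity(pts) - target_asphericity) <= tol:
            n = n_atoms
            return Component(
                names=np.array([f"C{i % 99 + 1}" for i in range(n)]),
                elements=np.array(["C"] * n),
                positions=pts - pts.mean(axis=0),
                res_names=np.array(["BLB"] * n),
                res_indices=np.ones(n, int),
                seg_ids=np.array(["BLOB"] * n),
                comp_type="solvated",
            )
    raise RuntimeError(
        f"could not hit asphericity {target_asphericity} ± {tol} in {max_attempts} tries"
    )


@dataclass
class SweepCell:
    vv: float
    replica: int
    seed: int
    success: bool
    collisions: int
    runtime_s: float


@dataclass
class SweepResult:
    cells: list[SweepCell] = field(default_factory=list)

    @property
    def max_vv_any_success(self) -> float | None:
        succ = [c.vv for c in self.cells if c.success]
        return max(succ) if succ else None

    @property
    def first_vv_all_fail(self) -> float | None:
        by_vv: dict[float, list[bool]] = {}
        for c in self.cells:
            by_vv.setdefault(round(c.vv, 6), []).append(c.success)
        for vv in sorted(by_vv):
            if not any(by_vv[vv]):
                return vv
        return None

    def success_fraction(self, vv: float) -> float:
        mine = [c for c in self.cells if abs(c.vv - vv) < 1e-9]
        return sum(c.success for c in mine) / len(mine) if mine else float("nan")


def density_sweep(
    bodies: list[Component],
    counts: list[int] | None = None,
    replicas: int = 12,
    start_vv: float = 0.10,
    step: float = 0.01,
    seed: int = 0,
    max_vv: float = 0.60,
    schedule: AnnealSchedule | None = None,
    fix_largest: bool = False,
) -> SweepResult:
    """Pack a fixed molecule set at rising volume fractions until all replicas fail.

    Density is raised by shrinking the (cubic) box around constant molecule
    counts.  Each (density, replica) cell gets its own seed derived from
    ``seed``.  Stops at the first density where every replica fails, or at
    ``max_vv``.
    """
    import time

    if len(bodies) < 1:
        raise ValueError("need at least one rigid body")
    counts = counts or [1] * len(bodies)
    for b in bodies:
        ensure_metrics(b)
    occupied = sum(n * b.metrics.volume for n, b in zip(counts, bodies))
    floor = max(
        b.metrics.length for b, n in zip(bodies, counts) if n > 0
    ) + 2 * 2.5
    constraints = (
        default_constraints(bodies) if fix_largest
        else [Constraint("none") for _ in bodies]
    )
    result = SweepResult()
    ss = np.random.SeedSequence(seed)
    vv = start_vv
    while vv <= max_vv + 1e-9:
        side = (occupied / vv) ** (1 / 3)
        if side < floor:
            break  # the self-image floor makes this density unreachable
        spec = SystemSpec(lattice="cubic", dims=[side] * 3, counts=list(counts))
        any_success = False
        for rep in range(replicas):
            cell_seed = int(
                np.random.SeedSequence([seed, int(round(vv * 1000)), rep])
                .generate_state(1)[0] % (2**31 - 1)
            )
            t0 = time.perf_counter()
            try:
                res = pack(spec, bodies, constraints, cell_seed, schedule=schedule)
                ok, ncol = True, res.report.total
            except PackingError:
                ok, ncol = False, -1
            dt = time.perf_counter() - t0
            result.cells.append(SweepCell(round(vv, 6), rep, cell_seed, ok, ncol, dt))
            any_success = any_success or ok
        if not any_success:
            break
        vv += step
    return result


def easy_set(seed: int = 0, n_atoms: int = 150) -> list[Component]:
    """Three near-spherical bodies in the 0.07–0.15 asphericity band."""
    return [
        generate_blob(n_atoms, a, seed + i)
        for i, a in enumerate((0.08, 0.11, 0.14))
    ]


def hard_set(seed: int = 0, n_atoms: int = 150) -> list[Component]:
    """Bodies spanning the wide 0.02–0.48 asphericity range."""
    return [
        generate_blob(n_atoms, a, seed + 100 + i)
        for i, a in enumerate((0.02, 0.25, 0.48))
    ]


def paper_mode_sweep(paths: list[str], **kwargs) -> SweepResult:
    """Density sweep over user-supplied structure files (e.g. downloaded PDB
    entries) instead of synthetic bodies."""
    from .components import read_structure

    bodies = [read_structure(p) for p in paths]
    return density_sweep(bodies, **kwargs)
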