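"""Geometric characterization of rigid components.

Everything downstream of this module consumes the quantities computed here:
system sizing needs molecular volume, solvent-accessible volume (SAV) and the
maximum atom–atom length; the coarse-grained packer needs per-region centers
of mass and radii of gyration; membrane handling needs the partition of a
component against the implicit hydrophobic slab |Z| <= 12 Å.

Molecular volume is grid-based: cells of a regular 0.5 Å lattice whose center
lies within an atom's van der Waals radius are occupied, and interior cavities
unreachable from the exterior are counted toward the volume.  SAV repeats the
computation with every atomic radius inflated by the 1.4 Å water radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .components import Component

MEMBRANE_HALF_THICKNESS = 12.0  # Å, half of the 24 Å hydrophobic slab
WATER_RADIUS = 1.4  # Å


@dataclass
class GridSpec:
    """Parameters of the volume grid (spacing and probe range in Å)."""

    spacing: float = 0.5
    probe_range: float = 6.0
    water_radius: float = WATER_RADIUS

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.probe_range < self.spacing:
            raise ValueError("probe_range must be >= spacing")


@dataclass
class RegionMetrics:
    volume: float
    com: np.ndarray
    rg: float
    atom_count: int


@dataclass
class MembranePartition:
    """Per-region (above / intra / below the slab) volume, COM, Rg, count."""

    regions: dict[str, RegionMetrics] = field(default_factory=dict)

    def __contains__(self, name):
        return name in self.regions

    def __getitem__(self, name) -> RegionMetrics:
        return self.regions[name]


@dataclass
class ComponentMetrics:
    dimensions: np.ndarray  # principal-frame bounding box, Å
    length: float  # max pairwise atom distance, Å
    volume: float  # Å^3
    sav: float  # solvent-accessible volume, Å^3
    rg: float  # mass-weighted radius of gyration, Å
    asphericity: float
    mass: float  # amu
    net_charge: float
    n_residues: int
    partition: MembranePartition | None = None


# -- gyration tensor, frames, scalar shape measures -------------------------------

def gyration_tensor(positions: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    positions = np.asarray(positions, float).reshape(-1, 3)
    w = np.ones(len(positions)) if weights is None else np.asarray(weights, float)
    com = w @ positions / w.sum()
    d = positions - com
    return (w[:, None] * d).T @ d / w.sum()


def principal_frame(positions: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Proper rotation mapping the principal axes onto X, Y, Z.

    Rows are the gyration-tensor eigenvectors in descending eigenvalue order,
    each flipped so its largest-magnitude entry is positive; if the resulting
    matrix is improper the tertiary axis is negated.  Degenerate eigenvalues
    get an arbitrary but deterministic orthonormal completion (numpy's
    ``eigh`` ordering, which prefers the coordinate axes X > Y > Z for exactly
    degenerate diagonal tensors).
    """
    if len(np.atleast_2d(positions)) < 1:
        raise ValueError("need at least one atom")
    S = gyration_tensor(positions, weights)
    evals, evecs = np.linalg.eigh(S)  # ascending
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T  # rows = principal axes, descending
    for i in range(3):
        k = int(np.argmax(np.abs(axes[i])))
        if axes[i, k] < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def component_length(positions: np.ndarray) -> float:
    """Maximum distance between any two atoms (convex-hull accelerated)."""
    positions = np.asarray(positions, float).reshape(-1, 3)
    if len(positions) < 2:
        return 0.0
    pts = positions
    if len(pts) > 30:
        try:
            from scipy.spatial import ConvexHull

            pts = positions[ConvexHull(positions).vertices]
        except Exception:  # degenerate (coplanar/collinear) clouds
            pts = positions
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def radius_of_gyration(
    positions: np.ndarray, masses: np.ndarray | None = None, mass_weighted: bool = True
) -> float:
    positions = np.asarray(positions, float).reshape(-1, 3)
    w = masses if (mass_weighted and masses is not None) else np.ones(len(positions))
    w = np.asarray(w, float)
    com = w @ positions / w.sum()
    return float(np.sqrt(np.sum(w * np.sum((positions - com) ** 2, axis=1)) / w.sum()))


def asphericity(positions: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Normalized gyration-tensor asphericity: 0 for a sphere, 1 for a rod.

    A = [(l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2] / [2 (l1+l2+l3)^2] with l_i the
    gyration-tensor eigenvalues.
    """
    evals = np.linalg.eigvalsh(gyration_tensor(positions, weights))
    tr = evals.sum()
    if tr <= 0:
        return 0.0
    l1, l2, l3 = sorted(evals, reverse=True)
    return float(((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2) / (2 * tr**2))


# -- grid volume -------------------------------------------------------------------

def _voxelize(positions, radii, grid: GridSpec, inflate: float):
    """Occupancy and proximity masks on a lattice anchored to bbox - probe_range."""
    h = grid.spacing
    lo = positions.min(axis=0) - grid.probe_range
    hi = positions.max(axis=0) + grid.probe_range
    shape = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 1)
    occ = np.zeros(shape, dtype=bool)
    r_eff = radii + inflate
    # sample points sit at a quarter-cell offset: atoms at round coordinates
    # then never align with the sampling lattice, which would bias the count
    for p, r in zip(positions, r_eff):
        idx_lo = np.maximum(np.floor((p - r - lo) / h).astype(int) - 1, 0)
        idx_hi = np.minimum(np.ceil((p + r - lo) / h).astype(int) + 1, shape)
        if np.any(idx_hi <= idx_lo):
            continue
        ax = [lo[k] + h * (np.arange(idx_lo[k], idx_hi[k]) + 0.25) for k in range(3)]
        d2 = (
            (ax[0][:, None, None] - p[0]) ** 2
            + (ax[1][None, :, None] - p[1]) ** 2
            + (ax[2][None, None, :] - p[2]) ** 2
        )
        sub = tuple(slice(idx_lo[k], idx_hi[k]) for k in range(3))
        occ[sub] |= d2 <= r * r
    return occ


def grid_volume(
    positions: np.ndarray,
    radii: np.ndarray,
    grid: GridSpec | None = None,
    inflate: float = 0.0,
) -> float:
    """Grid-based molecular volume in Å^3, interior cavities included.

    A cell counts if its center lies within ``vdw_radius + inflate`` of any
    atom.  Empty cells not reachable from the grid exterior by a 6-connected
    flood fill are enclosed cavities and count toward the volume.
    """
    grid = grid or GridSpec()
    positions = np.asarray(positions, float).reshape(-1, 3)
    radii = np.asarray(radii, float)
    if len(positions) == 0:
        raise ValueError("no heavy atoms: cannot compute a molecular volume")
    occ = _voxelize(positions, radii, grid, inflate)
    # flood fill from the exterior: label the empty space, keep labels touching
    # the boundary; everything else is cavity
    labels, n = ndimage.label(~occ)  # default structure = 6-connectivity
    if n:
        boundary = set()
        for axis in range(3):
            for face in (0, -1):
                sl = [slice(None)] * 3
                sl[axis] = face
                boundary |= set(np.unique(labels[tuple(sl)]))
        boundary.discard(0)
        cavity = ~occ & ~np.isin(labels, sorted(boundary))
        occ |= cavity
    return float(occ.sum()) * grid.spacing**3


def solvent_accessible_volume(
    positions: np.ndarray, radii: np.ndarray, grid: GridSpec | None = None
) -> float:
    """Grid volume with every radius inflated by the water radius (1.4 Å)."""
    grid = grid or GridSpec()
    return grid_volume(positions, radii, grid, inflate=grid.water_radius)


# -- membrane partition ------------------------------------------------------------

def membrane_partition(
    component: Component,
    grid: GridSpec | None = None,
    half_thickness: float = MEMBRANE_HALF_THICKNESS,
) -> MembranePartition:
    """Split atoms by Z against the slab |Z| <= half_thickness.

    The component must already be aligned to a membrane parallel to the XY
    plane centered at Z = 0.  Empty regions are absent from the result.
    """
    z = component.positions[:, 2]
    masks = {
        "above": z > half_thickness,
        "intra": np.abs(z) <= half_thickness,
        "below": z < -half_thickness,
    }
    part = MembranePartition()
    for name, m in masks.items():
        if not m.any():
            continue
        pos = component.positions[m]
        masses = component.masses[m]
        heavy = component.heavy_mask[m]
        vol = (
            grid_volume(pos[heavy], component.vdw_radii[m][heavy], grid)
            if heavy.any()
            else 0.0
        )
        part.regions[name] = RegionMetrics(
            volume=vol,
            com=masses @ pos / masses.sum(),
            rg=radius_of_gyration(pos, masses),
            atom_count=int(m.sum()),
        )
    return part


# -- full metrics ------------------------------------------------------------------

def compute_metrics(
    component: Component,
    grid: GridSpec | None = None,
    net_charge: float = 0.0,
    with_partition: bool | None = None,
) -> ComponentMetrics:
    """Compute and cache the full metrics record for a component."""
    grid = grid or GridSpec()
    pos = component.positions
    masses = component.masses
    heavy = component.heavy_mask
    R = principal_frame(pos, masses)
    aligned = (pos - component.center_of_mass()) @ R.T
    dims = aligned.max(axis=0) - aligned.min(axis=0)
    if with_partition is None:
        with_partition = component.comp_type == "membrane_embedded"
    hp = pos[heavy]
    hr = component.vdw_radii[heavy]
    metrics = ComponentMetrics(
        dimensions=dims,
        length=component_length(pos),
        volume=grid_volume(hp, hr, grid),
        sav=solvent_accessible_volume(hp, hr, grid),
        rg=radius_of_gyration(pos, masses),
        asphericity=asphericity(pos, masses),
        mass=component.mass,
        net_charge=net_charge,
        n_residues=len({(s, int(r)) for s, r in zip(component.seg_ids, component.res_indices)}),
        partition=membrane_partition(component, grid) if with_partition else None,
    )
    component.metrics = metrics
    return metrics


def ensure_metrics(component: Component, grid: GridSpec | None = None) -> ComponentMetrics:
    if component.metrics is None:
        compute_metrics(component, grid)
    return component.metrics
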