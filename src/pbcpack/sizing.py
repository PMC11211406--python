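"""System sizing: lattice choice, box/count recommendation, positional constraints.

The recommendation balances two rules: (a) no box dimension may be short
enough for a component to touch its own periodic image (dimension >= longest
component length + twice the collision tolerance), and (b) the occupied
volume fraction should come as close as possible to the user's target, with
copy counts tied to the requested component ratios.  A feasibility heuristic
warns when the empty space falls below the total solvent-accessible volume of
all copies, and any target above 30% v/v draws a warning because such
densities usually need trial and error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .components import Component
from .geometry import ensure_metrics

COLLISION_TOLERANCE = 2.5  # Å, heavy-atom inter-copy cutoff
HIGH_VV_WARNING = 0.30

LATTICE_KINDS = ("cubic", "tetragonal", "orthorhombic")

#: legal constraint kinds per component type
CONSTRAINT_LEGALITY = {
    "solvated": ("none", "planar_z", "fixed_xyz"),
    "membrane_embedded": ("none", "planar_z", "fixed_xy"),
    "xy_periodic": ("com_z",),
    "solvent": ("none",),
    "ion": ("none",),
}


class SizingError(ValueError):
    pass


class FeasibilityWarning(UserWarning):
    pass


@dataclass
class Constraint:
    """Positional constraint on every copy of one component.

    kind ``none`` accepts any collision-free position; ``planar_z`` fixes the
    COM Z but allows XY translation and rotation; ``fixed_xyz`` pins the COM;
    ``fixed_xy`` (membrane-embedded) pins X and Y while Z stays at the
    uploaded value; ``com_z`` places an XY-periodic sheet at a given Z.
    """

    kind: str = "none"
    x: float | None = None
    y: float | None = None
    z: float | None = None

    def validate_for(self, comp_type: str) -> None:
        legal = CONSTRAINT_LEGALITY[comp_type]
        if self.kind not in legal:
            raise SizingError(
                f"constraint {self.kind!r} is illegal for component type "
                f"{comp_type!r} (allowed: {legal})"
            )
        need = {
            "planar_z": ("z",), "com_z": ("z",),
            "fixed_xyz": ("x", "y", "z"), "fixed_xy": ("x", "y"),
        }.get(self.kind, ())
        for f in need:
            if getattr(self, f) is None:
                raise SizingError(f"constraint {self.kind!r} requires {f}")


@dataclass
class Slab:
    """A reserved Z-interval [z_min, z_max] excluded from packing."""

    z_min: float
    z_max: float

    @property
    def thickness(self) -> float:
        return self.z_max - self.z_min

    def contains(self, z) -> np.ndarray:
        return (np.asarray(z) >= self.z_min) & (np.asarray(z) <= self.z_max)


@dataclass
class SystemSpec:
    lattice: str
    dims: np.ndarray  # Å
    counts: list[int]
    target_vv: float | None = None
    achieved_vv: float = 0.0
    reserved_slabs: list[Slab] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.dims = np.asarray(self.dims, float)
        if np.any(self.dims <= 0):
            raise SizingError("box dimensions must be positive")

    @property
    def volume(self) -> float:
        return float(np.prod(self.dims))

    @property
    def reserved_volume(self) -> float:
        return float(sum(s.thickness for s in self.reserved_slabs) * self.dims[0] * self.dims[1])

    @property
    def available_volume(self) -> float:
        return self.volume - self.reserved_volume


def choose_lattice(components: list[Component], generate_membrane: bool = False) -> str:
    """Cubic for pure solution, tetragonal with a membrane, orthorhombic
    when an XY-periodic component pins the X and Y dimensions."""
    periodic = [c for c in components if c.comp_type == "xy_periodic"]
    if periodic:
        dims_xy = []
        for c in periodic:
            m = ensure_metrics(c)
            ext = c.positions.max(axis=0) - c.positions.min(axis=0)
            dims_xy.append(ext[:2])
        for d in dims_xy[1:]:
            if not np.allclose(d, dims_xy[0], atol=1.0):
                raise SizingError("xy_periodic components must share the same XY dimensions")
        return "orthorhombic"
    if generate_membrane or any(c.comp_type == "membrane_embedded" for c in components):
        return "tetragonal"
    return "cubic"


def reserved_slab_from_component(
    com_z: float, thickness: float, box_z: float | None = None
) -> Slab:
    """Reserved slab [com_z - t/2, com_z + t/2] for a membrane or sheet."""
    if thickness < 0:
        raise SizingError("thickness must be >= 0")
    slab = Slab(com_z - thickness / 2.0, com_z + thickness / 2.0)
    if box_z is not None and (slab.z_min < -box_z / 2 or slab.z_max > box_z / 2):
        raise SizingError("reserved slab extends outside the box")
    return slab


def check_slabs_disjoint(slabs: list[Slab]) -> None:
    ordered = sorted(slabs, key=lambda s: s.z_min)
    for a, b in zip(ordered, ordered[1:]):
        if b.z_min < a.z_max and a.thickness > 0 and b.thickness > 0:
            raise SizingError("reserved slabs overlap")


def default_constraints(components: list[Component]) -> list[Constraint]:
    """All 'none', except the largest component (by molecular volume, ties to
    the first input) is fixed at the system center."""
    packable = [
        i for i, c in enumerate(components)
        if c.comp_type in ("solvated", "membrane_embedded")
    ]
    cons = [Constraint("none") for _ in components]
    for i, c in enumerate(components):
        if c.comp_type == "xy_periodic":
            cons[i] = Constraint("com_z", z=0.0)
    if not packable:
        return cons
    vols = [ensure_metrics(components[i]).volume for i in packable]
    largest = packable[int(np.argmax(vols))]
    if components[largest].comp_type == "solvated":
        cons[largest] = Constraint("fixed_xyz", x=0.0, y=0.0, z=0.0)
    return cons


def _min_dims(components, counts, tolerance):
    """Self-image floor per dimension and the limiting component index."""
    longest, limiting = 0.0, None
    for i, (c, n) in enumerate(zip(components, counts)):
        if n <= 0 or c.comp_type in ("solvent", "ion"):
            continue
        ln = ensure_metrics(c).length
        if ln > longest:
            longest, limiting = ln, i
    return longest + 2 * tolerance, limiting


def _occupied(components, counts, use_sav=False):
    tot = 0.0
    for c, n in zip(components, counts):
        if n <= 0:
            continue
        m = ensure_metrics(c)
        tot += n * (m.sav if use_sav else m.volume)
    return tot


def recommend(
    components: list[Component],
    ratios_or_counts: list[float],
    mode: str,
    target_vv: float | None = None,
    dims: np.ndarray | None = None,
    approx_dims: np.ndarray | None = None,
    lattice: str | None = None,
    reserved: list[Slab] | None = None,
    tolerance: float = COLLISION_TOLERANCE,
    use_sav: bool = False,
    k_max: int = 10_000,
) -> SystemSpec:
    """Recommend box dimensions and integer copy counts.

    mode ``exact``: counts and dims are taken as given.  mode ``fit_counts``:
    dims are fixed, the integer multiplier k of the component ratios is chosen
    so the occupied fraction is closest to ``target_vv`` (ties to smaller k).
    mode ``fit_dims``: counts are fixed (the ratios, rounded), dimensions are
    solved so the occupied fraction equals ``target_vv``, then clamped up to
    the self-image floor with a warning if that binds.
    """
    if mode not in ("exact", "fit_counts", "fit_dims"):
        raise SizingError(f"unknown sizing mode {mode!r}")
    reserved = list(reserved or [])
    check_slabs_disjoint(reserved)
    lattice = lattice or choose_lattice(components)
    notes: list[str] = []

    def finish(dims_out, counts_out):
        dims_out = np.asarray(dims_out, float)
        spec = SystemSpec(
            lattice=lattice, dims=dims_out, counts=[int(n) for n in counts_out],
            target_vv=target_vv, reserved_slabs=reserved, warnings=notes,
        )
        avail = spec.available_volume
        occ = _occupied(components, counts_out, use_sav)
        spec.achieved_vv = occ / avail if avail > 0 else float("inf")
        free = avail - occ
        sav_total = sum(
            n * ensure_metrics(c).sav for c, n in zip(components, counts_out) if n > 0
        )
        if free < sav_total:
            msg = (
                f"empty space {free:.0f} Å³ is below the total solvent-accessible "
                f"volume {sav_total:.0f} Å³; packing may fail"
            )
            notes.append(msg)
            warnings.warn(msg, FeasibilityWarning, stacklevel=2)
        if spec.achieved_vv > HIGH_VV_WARNING:
            msg = f"volume fraction {spec.achieved_vv:.1%} above 30% usually needs trial and error"
            notes.append(msg)
            warnings.warn(msg, FeasibilityWarning, stacklevel=2)
        return spec

    if mode == "exact":
        if dims is None:
            raise SizingError("mode 'exact' needs dims")
        counts = [int(round(r)) for r in ratios_or_counts]
        floor, limiting = _min_dims(components, counts, tolerance)
        if np.any(np.asarray(dims, float) < floor - 1e-9):
            raise SizingError(
                f"a dimension is below the self-image floor {floor:.2f} Å "
                f"(limiting component index {limiting})"
            )
        return finish(dims, counts)

    if mode == "fit_counts":
        if dims is None or target_vv is None:
            raise SizingError("mode 'fit_counts' needs dims and target_vv")
        dims = np.asarray(dims, float)
        probe_counts = [1 if r > 0 else 0 for r in ratios_or_counts]
        floor, limiting = _min_dims(components, probe_counts, tolerance)
        if np.any(dims < floor - 1e-9):
            raise SizingError(
                f"target unreachable: dimension below self-image floor {floor:.2f} Å "
                f"(limiting component index {limiting})"
            )
        tmp = SystemSpec(lattice, dims, [0] * len(components), reserved_slabs=reserved)
        avail = tmp.available_volume

        def vv_of(k):
            counts = [int(round(k * r)) for r in ratios_or_counts]
            return _occupied(components, counts, use_sav) / avail, counts

        best_k, best_err, best_counts = None, None, None
        for k in range(1, k_max + 1):
            vv, counts = vv_of(k)
            err = abs(vv - target_vv)
            if best_err is None or err < best_err - 1e-12:
                best_k, best_err, best_counts = k, err, counts
            if vv > target_vv and k > (best_k or 1) + 2:
                break  # vv is nondecreasing in k; no better match ahead
        return finish(dims, best_counts)

    # fit_dims
    if target_vv is None or target_vv <= 0:
        raise SizingError("mode 'fit_dims' needs target_vv > 0")
    counts = [int(round(r)) for r in ratios_or_counts]
    if sum(counts) == 0:
        raise SizingError("all counts zero")
    occ = _occupied(components, counts, use_sav)
    reserved_t = sum(s.thickness for s in reserved)
    floor, _ = _min_dims(components, counts, tolerance)
    if lattice == "cubic":
        side = (occ / target_vv) ** (1.0 / 3.0)
        if side < floor:
            notes.append(
                f"cube side clamped to self-image floor {floor:.2f} Å; "
                f"target {target_vv:.2%} not reachable"
            )
            side = floor
        dims_out = [side, side, side]
    else:
        if approx_dims is None:
            raise SizingError("non-cubic fit_dims needs approx XY dims")
        x, y = float(approx_dims[0]), float(approx_dims[1])
        z = occ / target_vv / (x * y) + reserved_t
        z = max(z, floor)
        dims_out = [x, y, z]
    return finish(dims_out, counts)
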