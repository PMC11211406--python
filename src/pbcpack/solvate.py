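"""Solvent and ion counting, template-box packing, tiling, carving, assembly.

Solvent molecules are not packed one by one into the final system.  Instead a
small template box is packed once (with the same coarse-grained + greedy
machinery used for solutes), replicated to cover the system, trimmed to the
box, and carved: any solvent molecule with a heavy atom within 2.8 Å of a
non-solvent heavy atom — or with its COM inside a reserved slab — is deleted
whole.  Excess molecules beyond the target counts are deleted at random;
shortfalls are reported but never refilled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.spatial import cKDTree

from .components import Component, copy_segment_id
from .geometry import ensure_metrics
from .refine import PackingError, detect_collisions
from .sizing import COLLISION_TOLERANCE, Constraint, Slab, SystemSpec
from .cg import AnnealSchedule, minimum_image

AVOGADRO = 6.02214076e23
A3_TO_L = 1e-27
CARVE_CUTOFF = 2.8  # Å, solvent-solute heavy-atom deletion distance
ION_MIN_SPACING = 5.0  # Å, minimum ion-ion distance at insertion


class SolvationError(ValueError):
    pass


@dataclass
class SolventSpecies:
    """A solvent molecule type plus its target amount.

    Exactly one target mode applies per run: a molar concentration (mol/L),
    or a shared mass density (g/L) with per-species volume ratios.
    """

    structure: Component
    molar_mass: float  # g/mol
    concentration: float | None = None  # mol/L
    volume_ratio: float | None = None  # with density mode
    name: str = "SOLV"

    def __post_init__(self):
        if self.structure.comp_type != "solvent":
            raise SolvationError("solvent species must have comp_type 'solvent'")


@dataclass
class IonSpec:
    structure: Component
    charge: int
    name: str = "ION"

    def __post_init__(self):
        if self.charge == 0 or self.charge != int(self.charge):
            raise SolvationError("ion charge must be a nonzero integer")
        if self.structure.n_atoms > 7:
            raise SolvationError("ions may contain at most 7 atoms")


@dataclass
class SolventBox:
    """A packed template: per-molecule coordinate blocks and species labels."""

    dims: np.ndarray
    molecules: list[np.ndarray]  # full-atom coordinates per molecule
    species_index: list[int]

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)


# -- counting ---------------------------------------------------------------------

def solvent_counts(
    free_volume: float,
    species: list[SolventSpecies],
    density: float | None = None,
) -> list[int]:
    """Target molecule counts for a free volume in Å^3.

    Concentration mode: N = round(c · N_A · V).  Density mode (``density`` in
    g/L shared by all species): N_i = round(rho · f_i · V · N_A / M_i) with
    f_i the species' volume-ratio fraction.
    """
    if free_volume <= 0:
        raise SolvationError("free volume must be positive")
    v_l = free_volume * A3_TO_L
    counts = []
    if density is None:
        for sp in species:
            if sp.concentration is None:
                raise SolvationError(f"species {sp.name}: no concentration given")
            counts.append(int(round(sp.concentration * AVOGADRO * v_l)))
    else:
        fractions = np.array([sp.volume_ratio for sp in species], float)
        if np.any(np.isnan(fractions.astype(float))):
            raise SolvationError("density mode requires volume ratios for all species")
        fractions = fractions / fractions.sum()
        for sp, f in zip(species, fractions):
            counts.append(int(round(density * f * v_l * AVOGADRO / sp.molar_mass)))
    return counts


def ion_counts(
    net_solute_charge: int,
    positive: IonSpec,
    negative: IonSpec,
    concentration: float,
    free_volume: float,
) -> tuple[int, int]:
    """Neutralize the solute charge, then add salt to the requested molarity.

    Neutralization uses the minimal-excess rule: the smallest counter-ion
    count that overshoots (or meets) the solute charge, balanced by the
    opposite ion so the total system charge is exactly zero.  Salt formula
    units are ``round(c · N_A · V)``, each adding ions in the stoichiometric
    ratio |z-| : |z+| (reduced).
    """
    zp, zn = positive.charge, negative.charge
    if zp <= 0 or zn >= 0:
        raise SolvationError("need a positive and a negative ion species")
    q = int(net_solute_charge)
    # minimal-excess neutralization: smallest total (n_pos, n_neg) with
    # zp*n_pos + zn*n_neg + q == 0
    best = None
    limit = abs(q) + abs(zp) * abs(zn) + 2
    for npos in range(0, limit):
        rem = q + zp * npos  # remaining charge to cancel with negatives
        if rem < 0:
            continue
        if rem % abs(zn) == 0:
            nneg = rem // abs(zn)
            if best is None or npos + nneg < best[0] + best[1]:
                best = (npos, nneg)
    if best is None:
        raise SolvationError("cannot neutralize the solute charge with these ions")
    n_pos, n_neg = best
    if concentration > 0:
        if free_volume <= 0:
            raise SolvationError("free volume must be positive")
        n_formula = int(round(concentration * AVOGADRO * free_volume * A3_TO_L))
        g = np.gcd(abs(zp), abs(zn))
        n_pos += n_formula * (abs(zn) // g)
        n_neg += n_formula * (abs(zp) // g)
    assert zp * n_pos + zn * n_neg + q == 0
    return n_pos, n_neg


# -- template box ------------------------------------------------------------------

def _mole_ratio_counts(species, density, n_target):
    """Integer template counts realizing the target mole ratios, scaled so the
    total is closest to n_target (minimal multiple of the reduced ratio)."""
    if density is None:
        weights = [sp.concentration for sp in species]
    else:
        weights = [density * sp.volume_ratio / sp.molar_mass for sp in species]
    total = sum(weights)
    fracs = [Fraction(w / total).limit_denominator(24) for w in weights]
    denom = np.lcm.reduce([f.denominator for f in fracs])
    base = [int(f * denom) for f in fracs]
    base_sum = sum(base)
    k = max(1, int(round(n_target / base_sum)))
    return [k * b for b in base]


def build_template_box(
    species: list[SolventSpecies],
    seed: int,
    density: float | None = None,
    schedule: AnnealSchedule | None = None,
    tolerance: float = COLLISION_TOLERANCE,
) -> SolventBox:
    """Pack a small periodic solvent template realizing the target mix.

    Template edge: max(20 Å, 2·(longest solvent length + tolerance)).  The
    molecule counts hit the target number density (from the concentrations, or
    from the mass density) at exact mole ratios, packed collision-free under
    the template's own PBC with the standard CG + greedy machinery.
    """
    if not species:
        raise SolvationError("need at least one solvent species")
    for sp in species:
        ensure_metrics(sp.structure)
    longest = max(sp.structure.metrics.length for sp in species)
    edge = max(20.0, 2 * (longest + tolerance))
    vol = edge**3
    n_target = sum(
        solvent_counts(vol, species, density=density)
    )
    counts = _mole_ratio_counts(species, density, n_target)
    if sum(counts) == 0:
        counts = [max(c, 1) for c in counts]
    occupied = sum(n * sp.structure.metrics.volume for n, sp in zip(counts, species))
    sav = sum(n * sp.structure.metrics.sav for n, sp in zip(counts, species))
    if occupied > 0.55 * vol:
        raise SolvationError(
            f"solvent density infeasible in a {edge:.0f} Å template "
            f"({occupied / vol:.0%} occupied); use a larger template or a lower density"
        )
    if vol - occupied < sav:
        warnings.warn(
            "template empty space below the total solvent-accessible volume; "
            "packing may be slow or fail",
            UserWarning, stacklevel=2,
        )
    # the template pack treats each solvent molecule as a (tiny) solute
    from dataclasses import replace as _replace

    comps = [_replace(sp.structure, comp_type="solvated") for sp in species]
    spec = SystemSpec(
        lattice="cubic", dims=np.array([edge] * 3), counts=counts,
    )
    cons = [Constraint("none") for _ in comps]
    from .refine import pack  # late import to avoid a cycle

    result = pack(spec, comps, cons, seed, schedule=schedule, tolerance=tolerance)
    molecules, sindex = [], []
    for p in result.placements:
        ci = p.copy_ref[0]
        xyz = p.apply(comps[ci].positions)
        com = xyz.mean(axis=0)
        # wrap whole molecules by COM into the template cell
        xyz = xyz + minimum_image(com, spec.dims) - com
        molecules.append(xyz)
        sindex.append(ci)
    return SolventBox(dims=np.array([edge] * 3), molecules=molecules, species_index=sindex)


def tile_and_trim(template: SolventBox, system_dims: np.ndarray) -> tuple[list[np.ndarray], list[int]]:
    """Replicate the template from the box corner and keep molecules whose COM
    lies inside the system box (box-centered coordinates)."""
    dims = np.asarray(system_dims, float)
    reps = np.ceil(dims / template.dims).astype(int)
    kept, kept_species = [], []
    origin = -dims / 2.0
    for ix in range(reps[0]):
        for iy in range(reps[1]):
            for iz in range(reps[2]):
                shift = origin + template.dims * np.array([ix, iy, iz]) + template.dims / 2.0
                for mol, si in zip(template.molecules, template.species_index):
                    # template molecules are box-centered; re-center per tile
                    moved = mol + shift
                    com = moved.mean(axis=0)
                    if np.all(com >= -dims / 2) and np.all(com < dims / 2):
                        kept.append(moved)
                        kept_species.append(si)
    return kept, kept_species


# -- carving and trimming ----------------------------------------------------------

def carve(
    solvent_molecules: list[np.ndarray],
    solvent_heavy_masks: list[np.ndarray],
    solute_heavy_coords: np.ndarray,
    box: np.ndarray,
    reserved_slabs: list[Slab] | None = None,
    cutoff: float = CARVE_CUTOFF,
) -> list[int]:
    """Indices of solvent molecules that survive carving.

    A molecule dies whole if any of its heavy atoms is within ``cutoff`` of
    any non-solvent heavy atom under the minimum image, or if its COM lies
    inside a reserved slab.
    """
    box = np.asarray(box, float)
    reserved_slabs = reserved_slabs or []
    tree = None
    if len(solute_heavy_coords):
        wrapped = solute_heavy_coords - box * np.floor(solute_heavy_coords / box)
        tree = cKDTree(wrapped, boxsize=box)
    keep = []
    for i, (mol, hmask) in enumerate(zip(solvent_molecules, solvent_heavy_masks)):
        com = mol.mean(axis=0)
        if any(s.contains(com[2]) for s in reserved_slabs):
            continue
        if tree is not None:
            heavy = mol[hmask]
            w = heavy - box * np.floor(heavy / box)
            if any(len(h) for h in tree.query_ball_point(w, cutoff)):
                continue
        keep.append(i)
    return keep


def trim_excess(
    kept_indices: list[int],
    species_index: list[int],
    targets: list[int],
    seed: int,
) -> list[int]:
    """Randomly delete surplus molecules per species down to the targets.

    Shortfalls draw a warning but are never refilled.
    """
    rng = np.random.default_rng(seed)
    out = []
    for si, target in enumerate(targets):
        mine = [i for i in kept_indices if species_index[i] == si]
        if len(mine) > target:
            sel = rng.choice(len(mine), size=target, replace=False)
            mine = [mine[k] for k in sorted(sel)]
        elif len(mine) < target:
            warnings.warn(
                f"species {si}: only {len(mine)} of {target} solvent molecules "
                "fit after carving; extras are never created",
                UserWarning, stacklevel=2,
            )
        out.extend(mine)
    return sorted(out)


def place_ions(
    n_pos: int,
    n_neg: int,
    positive: IonSpec,
    negative: IonSpec,
    solvent_molecules: list[np.ndarray],
    kept_indices: list[int],
    box: np.ndarray,
    seed: int,
    min_spacing: float = ION_MIN_SPACING,
) -> tuple[list[np.ndarray], list[int], list[int]]:
    """Convert randomly chosen solvent sites into ions.

    Ions take the COM of a surviving solvent molecule (which is consumed),
    keeping every ion at least ``min_spacing`` from previously placed ions
    under the minimum image.  Returns (ion coordinate blocks, ion species
    flags: +1/-1, consumed solvent indices).
    """
    box = np.asarray(box, float)
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(kept_indices))
    placed_coords: list[np.ndarray] = []
    flags: list[int] = []
    consumed: list[int] = []
    centers: list[np.ndarray] = []
    want = [(1, positive)] * n_pos + [(-1, negative)] * n_neg
    for flag, spec_ion in want:
        site = None
        while order:
            idx = order.pop()
            com = solvent_molecules[idx].mean(axis=0)
            if all(
                np.linalg.norm(minimum_image(com - c, box)) >= min_spacing
                for c in centers
            ):
                site = (idx, com)
                break
        if site is None:
            raise SolvationError("not enough solvent sites to place all ions")
        idx, com = site
        consumed.append(idx)
        centers.append(com)
        ion_xyz = spec_ion.structure.positions
        placed_coords.append(ion_xyz - ion_xyz.mean(axis=0) + com)
        flags.append(flag)
    return placed_coords, flags, consumed


# -- assembly ----------------------------------------------------------------------

@dataclass
class AssembledSystem:
    component: Component
    report: dict = field(default_factory=dict)


def assemble(
    placements,
    components: list[Component],
    spec: SystemSpec,
    solvent_molecules: list[np.ndarray] | None = None,
    solvent_species: list[SolventSpecies] | None = None,
    solvent_species_index: list[int] | None = None,
    rename_map=None,
    tolerance: float = COLLISION_TOLERANCE,
) -> AssembledSystem:
    """Merge solute placements and solvent molecules into one system.

    Copy segment ids get the copy code appended (PAA → PAA1); all segments
    named MEMB merge into a single MEMB segment; solvent molecules share one
    segment per species with sequential residue numbers.  A fresh collision
    certificate over the non-solvent copies is computed and any violation
    aborts the assembly.
    """
    coords_per_copy = []
    for p in placements:
        comp = components[p.copy_ref[0]]
        coords_per_copy.append(p.apply(comp.positions[comp.heavy_mask]))
    cert = detect_collisions(coords_per_copy, spec.dims, tolerance)
    if cert.total:
        raise PackingError(
            f"assembly aborted: {cert.total} residual non-solvent collisions"
        )

    names, elements, resnames, resids, segids = [], [], [], [], []
    pos_blocks = []
    counts_by_comp: dict[int, int] = {}
    for p in placements:
        ci, copy = p.copy_ref
        comp = components[ci]
        counts_by_comp[ci] = counts_by_comp.get(ci, 0) + 1
        pos_blocks.append(p.apply(comp.positions))
        names.extend(comp.names)
        elements.extend(comp.elements)
        resnames.extend(comp.res_names)
        resids.extend(comp.res_indices)
        for sid in comp.seg_ids:
            base = sid
            if rename_map is not None:
                try:
                    base = rename_map.apply(f"{ci}:{sid}")
                except KeyError:
                    pass
            if base == "MEMB" or sid == "MEMB":
                segids.append("MEMB")
            else:
                segids.append(copy_segment_id(base, copy))

    solvent_counts_out: dict[str, int] = {}
    if solvent_molecules:
        for mi, (mol, si) in enumerate(zip(solvent_molecules, solvent_species_index)):
            sp = solvent_species[si]
            comp = sp.structure
            pos_blocks.append(mol)
            names.extend(comp.names)
            elements.extend(comp.elements)
            resnames.extend(comp.res_names)
            resids.extend([solvent_counts_out.get(sp.name, 0) + 1] * comp.n_atoms)
            segids.extend([sp.name[:4]] * comp.n_atoms)
            solvent_counts_out[sp.name] = solvent_counts_out.get(sp.name, 0) + 1

    merged = Component(
        names=np.array(names), elements=np.array(elements),
        positions=np.concatenate(pos_blocks) if pos_blocks else np.zeros((0, 3)),
        res_names=np.array(resnames), res_indices=np.array(resids, int),
        seg_ids=np.array(segids), comp_type="solvated",
    )
    occ = sum(
        n * ensure_metrics(components[ci]).volume for ci, n in counts_by_comp.items()
        if components[ci].comp_type not in ("solvent", "ion")
    )
    report = {
        "dims": [float(d) for d in spec.dims],
        "counts": {int(ci): int(n) for ci, n in counts_by_comp.items()},
        "solvent_counts": solvent_counts_out,
        "achieved_vv": occ / spec.available_volume,
        "collisions": cert.total,
    }
    return AssembledSystem(merged, report)
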