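"""Molecular components: containers, structure I/O, segment typing and renaming.

A :class:`Component` is a rigid molecular body — atoms never move relative to
each other during packing.  Atoms are stored as flat numpy arrays (positions in
Å, masses in amu, van der Waals radii in Å) plus per-atom labels.  Structure
files are read and written through MDAnalysis, so both PDB (segid column
73–76, falling back to the chain ID) and CHARMM CRD are accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

COMPONENT_TYPES = ("solvated", "solvent", "ion", "membrane_embedded", "xy_periodic")

SEGMENT_TYPES = ("protein", "dna", "rna", "heterogen", "carbohydrate", "water")

#: first letter of a renamed segment id, per segment type
TYPE_LETTER = {
    "protein": "P",
    "dna": "D",
    "rna": "R",
    "heterogen": "H",
    "carbohydrate": "C",
    "water": "W",
}

# Bondi-style van der Waals radii (Å); elements absent from the table get
# DEFAULT_VDW.  Hydrogens carry a radius but are excluded from collision checks.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "NA": 2.27, "K": 2.75,
    "MG": 1.73, "CA": 2.31, "ZN": 1.39, "FE": 2.00, "MN": 2.00, "CU": 1.40,
    "LI": 1.82, "SI": 2.10, "B": 1.92, "SE": 1.90, "AL": 1.84,
}
DEFAULT_VDW = 2.00

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "MN": 54.938, "CU": 63.546, "LI": 6.94, "SI": 28.085,
    "B": 10.81, "SE": 78.971, "AL": 26.982,
}
DEFAULT_MASS = 12.011

_AMINO = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # CHARMM histidine protonation variants
    "HSD", "HSE", "HSP",
}
_DNA = {"DA", "DC", "DG", "DT", "DU"}
_RNA = {"A", "C", "G", "U", "RA", "RC", "RG", "RU", "ADE", "CYT", "GUA", "URA"}
_WATER = {"HOH", "TIP3", "TIP4", "TIP5", "SPC", "SPCE", "WAT", "SOL", "W"}
_CARB = {
    "GLC", "BGC", "GAL", "GLA", "MAN", "BMA", "NAG", "NDG", "FUC", "FUL",
    "XYL", "XYS", "RIB", "AGLC", "BGLC", "AGAL", "BGAL", "AMAN", "BMAN",
    "SIA", "GLCNAC", "GALNAC",
}


class StructureFormatError(ValueError):
    """A structure file could not be parsed or an atom could not be typed."""


@dataclass
class Segment:
    """A contiguous run of atoms sharing one segment id."""

    id: str
    seg_type: str
    atom_range: tuple[int, int]  # half-open [start, stop)

    @property
    def n_atoms(self) -> int:
        return self.atom_range[1] - self.atom_range[0]


@dataclass
class Component:
    """A rigid molecular component: atom arrays, segments and a type tag.

    Parameters mirror the fields of the structure file.  ``comp_type`` is one
    of ``solvated`` (large solute), ``solvent`` (small neutral molecule),
    ``ion`` (small charged molecule), ``membrane_embedded`` (pre-aligned to a
    membrane slab at Z = 0) or ``xy_periodic`` (sheet whose area defines the
    system X and Y).
    """

    names: np.ndarray
    elements: np.ndarray
    positions: np.ndarray
    res_names: np.ndarray
    res_indices: np.ndarray
    seg_ids: np.ndarray
    comp_type: str = "solvated"
    source_path: str | None = None
    vdw_radii: np.ndarray = field(default=None)  # type: ignore[assignment]
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]
    metrics: "object | None" = None  # cached ComponentMetrics

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.positions)):
            raise StructureFormatError("non-finite atom coordinates")
        self.elements = np.asarray([str(e).upper() for e in self.elements])
        if self.vdw_radii is None:
            self.vdw_radii = np.array(
                [VDW_RADII.get(e, DEFAULT_VDW) for e in self.elements]
            )
        if self.masses is None:
            self.masses = np.array(
                [ATOMIC_MASSES.get(e, DEFAULT_MASS) for e in self.elements]
            )
        if self.comp_type not in COMPONENT_TYPES:
            raise ValueError(f"unknown component type {self.comp_type!r}")

    # -- basic derived quantities -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def is_hydrogen(self) -> np.ndarray:
        return self.elements == "H"

    @property
    def heavy_mask(self) -> np.ndarray:
        return ~self.is_hydrogen

    @property
    def mass(self) -> float:
        return float(self.masses.sum())

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.positions / self.masses.sum()

    @property
    def segments(self) -> list[Segment]:
        """Segments as contiguous runs of equal segment id, typed by residues."""
        segs = []
        ids = self.seg_ids
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or ids[i] != ids[start]:
                seg = Segment(str(ids[start]), "", (start, i))
                seg.seg_type = classify_segment(seg, self)
                segs.append(seg)
                start = i
        return segs

    def with_positions(self, positions: np.ndarray) -> "Component":
        return replace(self, positions=np.asarray(positions, float), metrics=None)


# -- classification ---------------------------------------------------------------

def classify_segment(segment: Segment, component: Component) -> str:
    """Classify a segment by residue-name lookup.

    Each residue votes for one class (protein / dna / rna / water /
    carbohydrate / heterogen); the majority wins and ties fall back to
    heterogen.  The result depends only on the multiset of residue names.
    """
    lo, hi = segment.atom_range
    if hi <= lo:
        raise ValueError("empty segment")
    res = {}
    for name, idx in zip(component.res_names[lo:hi], component.res_indices[lo:hi]):
        res[(int(idx), str(name).upper())] = None
    votes: dict[str, int] = {}
    for _, rname in res:
        if rname in _AMINO:
            cls = "protein"
        elif rname in _DNA:
            cls = "dna"
        elif rname in _RNA:
            cls = "rna"
        elif rname in _WATER:
            cls = "water"
        elif rname in _CARB:
            cls = "carbohydrate"
        else:
            cls = "heterogen"
        votes[cls] = votes.get(cls, 0) + 1
    best = max(votes.values())
    winners = [c for c, v in votes.items() if v == best]
    return winners[0] if len(winners) == 1 else "heterogen"


# -- structure I/O ----------------------------------------------------------------

def _mda_universe(path, fmt):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(path), format=fmt, to_guess=("elements", "masses"))


def read_structure(path, format: str | None = None, comp_type: str = "solvated") -> Component:
    """Read a PDB or CHARMM CRD file into a :class:`Component`.

    Elements come from the PDB element column when present, otherwise from
    atom-name heuristics (MDAnalysis guesser).  Segment ids use the PDB segid
    column and fall back to the chain ID.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "crd" if path.suffix.lower() in (".crd", ".cor") else "pdb"
    if format not in ("pdb", "crd"):
        raise ValueError(f"unsupported format {format!r}")
    try:
        u = _mda_universe(path, format)
    except Exception as exc:  # noqa: BLE001 - map parser errors to our own type
        raise StructureFormatError(f"{path}: {exc}") from exc
    atoms = u.atoms
    if len(atoms) == 0:
        raise StructureFormatError(f"{path}: no atoms")
    elements = np.array([str(e).upper() for e in atoms.elements])
    for i, e in enumerate(elements):
        if not e:
            raise StructureFormatError(
                f"{path}: cannot resolve element of atom {atoms.names[i]!r} (index {i})"
            )
    seg_ids = np.array([str(s).strip() for s in atoms.segids])
    if hasattr(atoms, "chainIDs"):
        chains = np.array([str(c).strip() for c in atoms.chainIDs])
        blank = (seg_ids == "") | (seg_ids == "SYSTEM")
        seg_ids = np.where(blank & (chains != ""), chains, seg_ids)
    seg_ids = np.where(seg_ids == "", "MAIN", seg_ids)
    return Component(
        names=np.array([str(n) for n in atoms.names]),
        elements=elements,
        positions=atoms.positions.astype(float),
        res_names=np.array([str(r) for r in atoms.resnames]),
        res_indices=atoms.resids.astype(int),
        seg_ids=seg_ids,
        comp_type=comp_type,
        source_path=str(path),
    )


def write_structure(component: Component, path, format: str | None = None) -> None:
    """Write a component to PDB (default) or CRD via MDAnalysis."""
    import MDAnalysis as mda

    path = Path(path)
    if format is None:
        format = "crd" if path.suffix.lower() in (".crd", ".cor") else "pdb"
    n = component.n_atoms
    _keys, order = _residue_keys(component)
    u = mda.Universe.empty(
        n, n_residues=len(order), n_segments=len(set(component.seg_ids)),
        atom_resindex=_residue_index_map(component),
        residue_segindex=_residue_seg_map(component),
        trajectory=True,
    )
    u.add_TopologyAttr("names", component.names)
    u.add_TopologyAttr("elements", [e.capitalize() for e in component.elements])
    resnames, resids = _residue_tables(component)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("segids", _segment_table(component))
    u.atoms.positions = component.positions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # MDAnalysis picks the writer from the file suffix (.pdb / .crd)
        u.atoms.write(str(path))


def _residue_keys(component: Component):
    """Per-atom residue key (segid, resid) -> dense residue index."""
    keys = list(zip(component.seg_ids, component.res_indices))
    order: dict = {}
    for k in keys:
        if k not in order:
            order[k] = len(order)
    return keys, order


def _residue_index_map(component: Component) -> np.ndarray:
    keys, order = _residue_keys(component)
    return np.array([order[k] for k in keys])


def _residue_seg_map(component: Component) -> np.ndarray:
    _, order = _residue_keys(component)
    seg_order: dict = {}
    for s in component.seg_ids:
        if s not in seg_order:
            seg_order[s] = len(seg_order)
    return np.array([seg_order[seg] for (seg, _r) in order])


def _residue_tables(component: Component):
    keys, order = _residue_keys(component)
    resnames = [""] * len(order)
    resids = [0] * len(order)
    for (k, name) in zip(keys, component.res_names):
        resnames[order[k]] = name
        resids[order[k]] = k[1]
    return resnames, resids


def _segment_table(component: Component):
    out = []
    for s in component.seg_ids:
        if s not in out:
            out.append(s)
    return out


# -- segment renaming -------------------------------------------------------------

_ALPHA = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class SegmentRenameMap:
    """Ordered injective mapping from input segment ids to type-letter ids."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def apply(self, original_id: str) -> str:
        for old, new in self.entries:
            if old == original_id:
                return new
        raise KeyError(original_id)

    def write(self, path, seed: int | None = None) -> None:
        lines = ["# segment rename map (original⟶new)"]
        if seed is not None:
            lines.append(f"# seed: {seed}")
        lines += [f"{old}\t{new}" for old, new in self.entries]
        Path(path).write_text("\n".join(lines) + "\n")


def rename_segments(components: list[Component]) -> SegmentRenameMap:
    """Assign unique type-letter segment ids across an ordered component list.

    The i-th segment of a type (1-based) becomes ``<letter><A..Z><A..Z>``
    with letters ``alphabet[(i-1) // 26]`` and ``alphabet[(i-1) % 26]``, so the
    first protein segment is PAA and the 27th is PBA.  Capacity is 676
    segments per type letter.
    """
    counters = {t: 0 for t in SEGMENT_TYPES}
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    for ci, comp in enumerate(components):
        for seg in comp.segments:
            key = f"{ci}:{seg.id}"
            if key in seen:
                continue
            seen.add(key)
            counters[seg.seg_type] += 1
            i = counters[seg.seg_type]
            if i > 676:
                raise ValueError(f"more than 676 {seg.seg_type} segments")
            new = TYPE_LETTER[seg.seg_type] + _ALPHA[(i - 1) // 26] + _ALPHA[(i - 1) % 26]
            entries.append((key, new))
    return SegmentRenameMap(entries)


def copy_segment_id(base_id: str, copy_index: int) -> str:
    """Append a copy id to a segment id: PAA,1 -> PAA1; copies >= 10 use base-36."""
    if copy_index < 1:
        raise ValueError("copy_index must be >= 1")
    if copy_index <= 9:
        return base_id + str(copy_index)
    # base-36 extension: 10 -> 'A', 35 -> 'Z', then two-character codes
    i = copy_index - 10
    if i < 26:
        return base_id + _ALPHA[i]
    i -= 26
    if i < 36 * 36:
        digits = "0123456789" + _ALPHA
        return base_id + digits[i // 36] + digits[i % 36]
    raise ValueError("copy index beyond base-36 capacity")
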