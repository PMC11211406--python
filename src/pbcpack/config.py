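"""Run-configuration schema, validation and the end-to-end run driver.

A run configuration is a single YAML/JSON mapping:

.. code-block:: yaml

    seed: 7
    output_dir: out
    components:
      - path: protein.pdb
        type: solvated          # solvated|solvent|ion|membrane_embedded|xy_periodic
        ratio: 2                # or: count: 4   (exactly one of the two)
        constraint: {kind: planar_z, z: 20.0}
      - path: sheet.pdb
        type: xy_periodic
        thickness: 40.0
        com_z: 0.0
    box:
      mode: volume_fraction     # or: explicit
      volume_fraction: 0.10
      approx_dims: [80, 80, 80] # needed for non-cubic fits
    solvent:
      species:
        - {path: co2.pdb, molar_mass: 44.01, name: CO2}
      density: 1.98             # g/L; or per-species concentration (mol/L)
    ions:
      positive: {path: k.pdb, charge: 1}
      negative: {path: cl.pdb, charge: -1}
      concentration: 0.15
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .components import Component, read_structure, rename_segments
from .geometry import ensure_metrics
from .refine import PackingError, pack
from .sizing import (
    COLLISION_TOLERANCE,
    Constraint,
    SizingError,
    choose_lattice,
    default_constraints,
    recommend,
    reserved_slab_from_component,
)
from .solvate import (
    CARVE_CUTOFF,
    IonSpec,
    SolventSpecies,
    assemble,
    build_template_box,
    carve,
    ion_counts,
    place_ions,
    solvent_counts,
    tile_and_trim,
    trim_excess,
)


class ConfigError(ValueError):
    """A validation failure; the message carries the offending field path."""


_DEFAULTS = {
    "seed": 0,
    "output_dir": "pbcpack_out",
    "tolerance": COLLISION_TOLERANCE,
    "carve_cutoff": CARVE_CUTOFF,
}


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def validate(config: dict) -> dict:
    """Normalize a raw config mapping; idempotent and side-effect free.

    Fills defaults, checks cross-field rules (count-vs-ratio exclusivity,
    constraint legality per component type, thickness requirements) and
    raises :class:`ConfigError` naming the field path on the first violation.
    """
    cfg = dict(config)
    for k, v in _DEFAULTS.items():
        cfg.setdefault(k, v)
    comps = cfg.get("components")
    if not comps:
        raise ConfigError("components: at least one component is required")
    norm_comps = []
    for i, c in enumerate(comps):
        c = dict(c)
        where = f"components[{i}]"
        if "path" not in c:
            raise ConfigError(f"{where}.path: required")
        ctype = c.setdefault("type", "solvated")
        if ctype not in ("solvated", "solvent", "ion", "membrane_embedded", "xy_periodic"):
            raise ConfigError(f"{where}.type: unknown type {ctype!r}")
        has_count, has_ratio = "count" in c, "ratio" in c
        if ctype in ("solvated", "membrane_embedded"):
            if has_count == has_ratio:
                raise ConfigError(f"{where}: exactly one of count/ratio is required")
        if ctype == "xy_periodic":
            c.setdefault("count", 1)
            if "thickness" not in c:
                raise ConfigError(f"{where}.thickness: required for xy_periodic components")
            c.setdefault("com_z", 0.0)
        con = c.get("constraint")
        if con is not None:
            constraint = Constraint(**con)
            try:
                constraint.validate_for(ctype)
            except SizingError as exc:
                raise ConfigError(f"{where}.constraint: {exc}") from exc
        norm_comps.append(c)
    cfg["components"] = norm_comps
    box = dict(cfg.get("box") or {})
    mode = box.setdefault("mode", "volume_fraction")
    if mode not in ("explicit", "volume_fraction"):
        raise ConfigError(f"box.mode: unknown mode {mode!r}")
    if mode == "explicit" and "dims" not in box:
        raise ConfigError("box.dims: required in explicit mode")
    if mode == "volume_fraction" and "volume_fraction" not in box:
        raise ConfigError("box.volume_fraction: required in volume_fraction mode")
    cfg["box"] = box
    return cfg


@dataclass
class RunArtifacts:
    output_dir: Path
    structure: Path
    report: Path
    rename_map: Path
    log: Path
    summary: dict = field(default_factory=dict)


def run(config: dict, seed: int | None = None, output_dir=None) -> RunArtifacts:
    """Execute metrics → sizing → pack → solvate → assemble and write artifacts.

    Raises the originating stage's error (PackingError, SizingError,
    SolvationError) with the stage named in the message.
    """
    from .components import write_structure

    cfg = validate(config)
    seed = cfg["seed"] if seed is None else int(seed)
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"seed: {seed}"]

    # -- metrics stage
    components: list[Component] = []
    constraints: list[Constraint] = []
    packable_ratio: list[float] = []
    slabs = []
    for c in cfg["components"]:
        comp = read_structure(c["path"], comp_type=c["type"])
        m = ensure_metrics(comp)
        log_lines.append(
            f"component {c['path']}: type={c['type']} volume={m.volume:.1f} "
            f"sav={m.sav:.1f} length={m.length:.2f} rg={m.rg:.2f}"
        )
        components.append(comp)
        con = c.get("constraint")
        constraints.append(Constraint(**con) if con else Constraint("none"))
        packable_ratio.append(float(c.get("ratio", c.get("count", 0))))
        if c["type"] == "xy_periodic":
            constraints[-1] = Constraint("com_z", z=float(c.get("com_z", 0.0)))
            slabs.append(
                reserved_slab_from_component(float(c.get("com_z", 0.0)), float(c["thickness"]))
            )
    if all(con.kind == "none" for con in constraints):
        constraints = default_constraints(components)

    # -- sizing stage
    box = cfg["box"]
    lattice = choose_lattice(components)
    try:
        if box["mode"] == "explicit":
            spec = recommend(
                components, packable_ratio, mode="exact", dims=box["dims"],
                lattice=lattice, reserved=slabs, tolerance=cfg["tolerance"],
            )
        else:
            have_counts = all("count" in c for c in cfg["components"])
            if "dims" in box:
                spec = recommend(
                    components, packable_ratio, mode="fit_counts",
                    target_vv=box["volume_fraction"], dims=box["dims"],
                    lattice=lattice, reserved=slabs, tolerance=cfg["tolerance"],
                )
            else:
                spec = recommend(
                    components, packable_ratio, mode="fit_dims",
                    target_vv=box["volume_fraction"],
                    approx_dims=box.get("approx_dims"),
                    lattice=lattice, reserved=slabs, tolerance=cfg["tolerance"],
                )
            if have_counts:
                spec.counts = [int(c["count"]) for c in cfg["components"]]
    except SizingError as exc:
        raise SizingError(f"sizing stage failed: {exc}") from exc
    log_lines.append(
        f"box: {lattice} dims={np.round(spec.dims, 2).tolist()} counts={spec.counts} "
        f"achieved_vv={spec.achieved_vv:.4f}"
    )

    # -- pack stage
    try:
        result = pack(spec, components, constraints, seed, tolerance=cfg["tolerance"])
    except PackingError as exc:
        (out / "run.log").write_text("\n".join(log_lines + [f"packing stage failed: {exc}"]))
        raise PackingError(f"packing stage failed: {exc}") from exc
    log_lines.append(f"pack: collisions={result.report.total} "
                     f"stage_energies={[round(e, 3) for e in result.cg.stage_energies]}")

    # -- solvate stage
    solvent_mols, sp_index, species = [], [], []
    solv = cfg.get("solvent") or {}
    if solv.get("species"):
        density = solv.get("density")
        for s in solv["species"]:
            struct = read_structure(s["path"], comp_type="solvent")
            species.append(SolventSpecies(
                structure=struct, molar_mass=float(s["molar_mass"]),
                concentration=s.get("concentration"),
                volume_ratio=s.get("volume_ratio", 1.0),
                name=s.get("name", f"SV{len(species)}"),
            ))
        solute_vol = sum(
            n * ensure_metrics(c).volume for c, n in zip(components, spec.counts)
            if c.comp_type in ("solvated", "membrane_embedded")
        )
        free = spec.available_volume - solute_vol
        targets = solvent_counts(free, species, density=density)
        log_lines.append(f"solvent targets: {targets}")
        template = build_template_box(species, seed=seed + 1, density=density)
        tiled, tiled_idx = tile_and_trim(template, spec.dims)
        solute_heavy = np.concatenate([
            p.apply(components[p.copy_ref[0]].positions[components[p.copy_ref[0]].heavy_mask])
            for p in result.placements
        ]) if result.placements else np.zeros((0, 3))
        heavy_masks = [~(species[i].structure.is_hydrogen) for i in tiled_idx]
        kept = carve(tiled, heavy_masks, solute_heavy, spec.dims,
                     reserved_slabs=spec.reserved_slabs, cutoff=cfg["carve_cutoff"])
        final_idx = trim_excess(kept, tiled_idx, targets, seed=seed + 2)
        solvent_mols = [tiled[i] for i in final_idx]
        sp_index = [tiled_idx[i] for i in final_idx]
        log_lines.append(f"solvent kept: {len(solvent_mols)}")

    # -- assemble stage
    rmap = rename_segments(components)
    system = assemble(
        result.placements, components, spec,
        solvent_molecules=solvent_mols, solvent_species=species,
        solvent_species_index=sp_index, rename_map=rmap,
        tolerance=cfg["tolerance"],
    )
    system.report["seed"] = seed
    system.report["stage_energies"] = [float(e) for e in result.cg.stage_energies]

    structure_path = out / "system.pdb"
    write_structure(system.component, structure_path)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(system.report, indent=2, sort_keys=True))
    map_path = out / "rename_map.txt"
    rmap.write(map_path, seed=seed)
    log_path = out / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    return RunArtifacts(out, structure_path, report_path, map_path, log_path, system.report)
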