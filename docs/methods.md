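# Methods

This note documents the models, numerical choices and limitations behind
`pbcpack`. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external runs.

## Component model

A component is a rigid set of atoms. Atoms carry element symbols, Bondi-style
van der Waals radii (user-overridable per element; 2.0 Å default for elements
outside the table), standard atomic masses, residue labels and a segment id.
Hydrogens carry a radius and mass but are excluded from every collision
check. Force-field topology (partial charges, bonded terms) is deliberately
out of scope: all geometry the packing method needs is derivable from
coordinates, elements and radii. Net charge, where needed for ion counting,
is a user input.

Five component types drive positioning: *solvated* (free solutes),
*solvent* (small neutral molecules placed by template replication), *ion*
(small charged molecules placed onto solvent sites), *membrane_embedded*
(pre-aligned to a membrane parallel to XY centered at Z = 0; only XY
translation and Z rotation are ever applied, so uploaded Z coordinates are
preserved), and *xy_periodic* (sheets whose lateral extent fixes the system
X and Y, kept static at a chosen COM-Z with a reserved Z-slab around them).

## Geometric metrics

* **Principal frame** — eigenvectors of the mass-weighted gyration tensor,
  descending eigenvalues onto X, Y, Z; each eigenvector is flipped so its
  largest-magnitude entry is positive, and the tertiary axis is negated if
  needed to keep the rotation proper. Exactly degenerate tensors fall back
  to `eigh`'s deterministic ordering.
* **Length** — exact maximum pairwise atom distance (convex-hull accelerated
  above 30 atoms; equal to the O(N²) scan, which the tests verify).
* **Grid volume** — cells of a 0.5 Å lattice (anchored at the bounding box
  minus the 6 Å probe range) count when their sample point lies within an
  atom's radius. Sample points sit at a quarter-cell offset so atoms placed
  at round coordinates never align with the lattice; with that offset,
  halving the spacing changes a single-sphere volume by under 2% and the
  value stays within 5% of (4/3)πr³. Interior cavities — empty cells
  unreachable from the grid boundary by a 6-connected flood fill
  (`scipy.ndimage.label`) — count toward the volume. The probe range bounds
  the candidate region; pockets that open to the exterior wider than the
  probe are therefore never sealed.
* **Solvent-accessible volume (SAV)** — the same computation with every
  radius inflated by the 1.4 Å water radius; SAV ≥ volume always.
* **Asphericity** — A = [(λ₁−λ₂)² + (λ₂−λ₃)² + (λ₃−λ₁)²] / [2(λ₁+λ₂+λ₃)²]
  from the gyration-tensor eigenvalues: 0 for spherically symmetric mass
  distributions, 1 for an ideal rod. Published asphericity bands quoted for
  benchmark sets are treated as labels for this formula, not as values with
  an independent definition.
* **Membrane partition** — atoms split by Z against |Z| ≤ 12 Å (the 24 Å
  hydrophobic slab); per-region volume, mass-weighted COM and Rg. Empty
  regions are absent.

## System sizing

Volume fraction is occupied volume over available (non-reserved) volume.
Constraint (a): every dimension ≥ longest participating component + 2 × 2.5 Å,
so no copy can touch its own periodic image at the collision tolerance.
Constraint (b): counts follow the requested ratios (counts = k·ratios, the
integer k whose occupied fraction is nearest the target; ties prefer the
smaller k). When solving dimensions for a target fraction, a dimension
clamped by constraint (a) is reported as a warning with the actually
achieved fraction; fixed user dimensions that violate (a) are an error.
Feasibility heuristics: a warning when empty space falls below the total SAV
of all copies, and a warning above 30% v/v, where packing empirically
requires trial and error. Lattices: cubic (solution), tetragonal (membrane
present or to be generated), orthorhombic (XY-periodic component pins X, Y;
multiple sheets must agree on XY).

## Coarse-grained annealing

Each copy is 1–3 spheres: one at the COM with radius Rg for solvated copies;
one per non-empty membrane region (above/intra/below) at the region COM with
the region's mass-weighted Rg, rigidly linked, for membrane-embedded copies.
The spheres interact through a purely repulsive harmonic overlap term
½k(rᵢ+rⱼ−d)² (k = 10 kcal·mol⁻¹·Å⁻²) force-switched to zero over the last
2 Å before the cutoff (10 Å plus the largest sphere radius). The exact pair
form, friction (5 ps⁻¹) and CG masses (component/region masses) are free
choices: only the endpoint quality matters, and the all-atom refinement
resolves residual overlaps.

Dynamics: five stages of Langevin leapfrog (v ← av + (1−a)F/γm + thermal
noise, a = e^(−γΔt)) at 500 K, 100 ps per stage, 2 fs timestep, with the box
at 150%, 137.5%, 125%, 112.5% and 100% of the target. At each stage boundary
unconstrained coordinates are remapped affinely; fixed values, planar-Z
values and tethered membrane Z positions are not rescaled. Constraints are
enforced by masking degrees of freedom: fixed copies do not move, planar-Z
copies keep Z exactly, membrane copies translate in XY and rotate about Z
only (the planar-Z variant carries a soft 1 kcal·mol⁻¹·Å⁻² Z tether instead
of a hard fix). Copies are kept out of reserved slabs by a harmonic wall
acting on sphere surfaces. The inner loop is a numba kernel drawing noise
from a per-stage seeded RNG, so a seed reproduces trajectories bitwise on a
single thread.

## Atomistic refinement

Solvated copies are realized by a uniform random SO(3) rotation about the
COM, which is then moved to the annealed sphere center (fixed copies skip
the rotation). Membrane copies apply the least-squares Z-rotation/XY-
translation best fit between the uploaded region COMs and the annealed
sphere centers, leaving atomic Z values untouched.

Collisions are heavy-atom pairs of different copies closer than 2.5 Å under
the minimum image, found with scipy's periodic KD-tree; the tests check the
result equals a brute-force O(N²) scan exactly. The greedy conformation
search runs up to 7 sweeps; per sweep, copies are visited in descending
collision count, and each colliding copy receives up to 20 candidate moves
(rotations ≤ 30°, translations ≤ 2 Å, filtered by the copy's constraint:
planar-Z copies move in XY and rotate, fixed copies only rotate about their
pinned COM, membrane copies Z-rotate and XY-translate). Half the candidates
translate along the copy's net overlap direction (the radius-weighted sum of
separation vectors of its colliding pairs) with a small jitter; this biased
move escapes face-to-face contacts that uniform moves rarely fix. A
candidate is accepted only if it strictly improves the copy's
(collision count, total overlap depth) lexicographically — the copy's and
therefore the system's collision count never increase. Remaining collisions
after 7 sweeps are a packing failure (an error naming the residual count).

## Solvation

Counts: N = round(c·N_A·V) in concentration mode; N = round(ρ·f·V·N_A/M) in
mass-density mode with volume-ratio fractions f. Ions first neutralize the
solute charge with the minimal-excess integer solution, then add salt
formula units at the requested molarity in the reduced |z₋| : |z₊|
stoichiometry; total charge is exactly zero by integer arithmetic.

The solvent template edge is max(20 Å, 2·(longest solvent length + 2.5 Å)),
large enough that a molecule cannot collide with its own image. Template
counts realize the target mole ratios (rational approximation, denominator
≤ 24) at the target number density, packed with the standard CG + greedy
machinery under the template's own PBC and wrapped whole-molecule into the
cell. Templates whose occupied fraction would exceed 55% are rejected as
infeasible; densities whose empty space falls below the template SAV draw a
warning. Liquid-water-like densities are therefore near the practical limit
of this generic path — the template approach is designed for gaseous and
moderately concentrated solvents, and pre-equilibrated template libraries
are out of scope.

Tiling replicates the template from the box corner ⌈L/edge⌉ times per axis
and keeps molecules whose COM lies inside the box. Carving deletes a solvent
molecule whole when any heavy atom comes within 2.8 Å of a non-solvent heavy
atom (minimum image) or its COM lies inside a reserved slab. Excess
molecules per species are deleted uniformly at random (seeded); shortfalls
warn and are never refilled, so final counts never exceed targets. Ions
replace randomly chosen surviving solvent sites with a 5 Å minimum ion–ion
spacing. Assembly appends copy codes to renamed segment ids (digits 1–9,
then base-36 characters to stay within the 4-character segment field),
merges all MEMB segments into one, gives each solvent species one segment
with sequential residue numbers, and recomputes a zero-collision certificate
over the non-solvent copies before writing anything.

## Synthetic bodies and the density sweep

The blob generator emulates globular macromolecules as anisotropic Gaussian
clouds of uniform 1.7 Å atoms. The short-axis scale defaults to 2.5 Å with
150 atoms, chosen so the bodies match the compactness of real globular
proteins (volume/length³ ≈ 0.2, as for ubiquitin); samples beyond 3 standard
radii are redrawn so no isolated outlier inflates the length. The prolate
axis ratio is solved in closed form from the target asphericity
(t² = (1+2√A)/(1−√A)) and clouds are redrawn until the realized value is
within ±0.03. What these bodies do not emulate: real surface chemistry,
concavities, and specific shape families — a passing benchmark shows the
packer handles size/shape heterogeneity at realistic compactness, not any
particular protein.

The density sweep packs a fixed molecule set at volume fractions rising in
1% steps from 10%, 12 seeded replicas per density, raising density by
shrinking the box around constant counts, and stops at the first density
where every replica fails — or where the self-image floor makes the density
geometrically unreachable for the set (reported as the end of the sweep, not
as packing failure). The shipped sets use three bodies with asphericities
0.08/0.11/0.14 ("easy") and 0.02/0.25/0.48 ("hard"); the acceptance script
packs two copies of each easy body and four of each hard body (the elongated
hard bodies otherwise hit the self-image floor before the packer is
stressed). These problem sizes keep a full sweep in the minutes range on one
CPU while leaving the failure onset governed by the packer, not the floor.

## Trajectory statistics

* Contact probability: fraction of frames with at least one Cα–Cα pair
  within 7 Å (minimum image when a box is given).
* Z-density: histogram with 2.46 Å bins, odd bin count with the middle bin
  centered at Z = 0 so that ±z symmetrization maps bins onto bins;
  normalization scales heights to unit sum.
* Diffusion: time-and-ensemble averaged 2-D MSD over all lags in the window
  (default 1–250 ns); D = slope/4, reported in µm²/s (1 Å²/ns = 10 µm²/s).

These are analysis definitions exercised on synthetic trajectories; the
package does not run MD, and no biological diffusion or contact values are
claimed.

## Known limitations

* Rigid bodies only: flexible polymers that pack by deforming are out of
  scope, as is lipid-bilayer construction.
* The greedy search is stochastic; near its feasibility ceiling individual
  replicas fail, which is why benchmarks run 12 replicas per density.
* Collision tolerance is a single global 2.5 Å heavy-atom cutoff, not
  per-element vdW sums.
* Charges, force fields and simulation-input generation are not handled;
  the output is coordinates plus a JSON report.
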