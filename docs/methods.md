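# Methods

`isletvasc` simulates oxygen supply in vascularized pancreatic islets: it
builds a 3-D islet of spherical α/β/δ-cells on a 1 µm voxel lattice, threads
capillaries through it, grows them with a cellular Potts model, solves the
steady-state oxygen diffusion–consumption problem with capillaries as the
only oxygen source, classifies each cell's viability from its mean oxygen
partial pressure, and summarizes the capillary-count/viability relationship
with a two-factor Hill sigmoid.

## Islet geometry

Cells are spheres with radii drawn from a truncated normal (mean 5.5 µm,
sd 0.8 µm, support [3.5, 8] µm). This distribution is a documented stand-in
sized so that realistic human cell counts fit their environments; substitute
an empirical table (`RadiiDistribution(family="empirical", samples=...)`)
when measured radii are available. Default type compositions are 29/53/18 %
(α/β/δ) for human and 25/75 % (α/β) for mouse; mouse architectures carry no
δ-cells.

The environment box is the cell bounding box plus a 30 µm buffer per side.
Overlap minimization follows a simulated-annealing-like scheme: one cell at
a time (chosen among cells currently involved in an overlap) gets a proposed
new center (uniform offset within ±r per axis) and a redrawn radius;
non-worsening proposals are always taken, worsening ones are accepted with a
geometrically decaying probability p₀γᵏ (p₀ = 0.5, γ set so p ≈ 10⁻³ halfway
through the iteration budget). The best configuration seen is returned,
together with its overlap trajectory. Two spheres overlap when their center
distance is strictly below the sum of radii — tangency does not count, so a
tight packing can reach exactly zero.

Synthetic islets place cell centers uniformly in a ball of the target
diameter and constrain optimization proposals to keep centers inside that
ball; spheres may protrude by up to one radius, like boundary cells on a
real islet surface. Packings whose total sphere volume exceeds 0.64 of the
ball volume are rejected as infeasible before optimization.

Rasterization assigns a voxel to a cell when the voxel center (i+0.5, j+0.5,
k+0.5) lies within the sphere. At r = 5 µm this carries a ~5 % surface-
dilation bias relative to the continuum volume — inherent to center-in-sphere
membership at 1 µm resolution, and irrelevant downstream because all stages
share the same discretization.

## Capillary seeding

Seed capillaries are greedy best-first searches between uniformly random
medium voxels on opposite grid faces (100 per axis by default, 300 total).
The frontier is ordered by Euclidean distance to the goal with FIFO
tie-breaking and a fixed +x,−x,+y,−y,+z,−z neighbor order, making paths
reproducible; steps are 6-connected so centerlines are watertight. Endocrine
cells are the only obstacles; paths may cross each other. The search is
complete: a failure means the goal is unreachable through medium, and
endpoints are then resampled (up to 50 times per requested path).

Greedy paths detour around cells: measured centerlines are ~1.5–1.7× the
face-to-face distance in a ~50 %-packed islet.

## Capillary growth (cellular Potts model)

Each seed path becomes one Potts entity of type capillary. The Hamiltonian
is the standard GGH form: contact energies J over the 2nd-order (18-site)
neighborhood between unlike entities, plus λc (v − V)² volume penalties for
capillaries only. Medium is unconstrained and endocrine cells are frozen —
they are excluded as both source and target of copy attempts, which realizes
"fixed obstacles" exactly and removes any need for a cell volume term.
Defaults: J(capillary,medium) = 70, J(cell,medium) = 80,
J(capillary,cell) = 10, J(capillary,capillary) = 1000 (suppresses merging of
distinct vessels), λc = 10³, T = 10.

One Monte Carlo step performs as many copy attempts as lattice sites; each
attempt picks a random site and one of its 6 face neighbors, and applies the
Metropolis rule (ΔH ≤ 0 always accepted — including exactly zero — else
probability e^(−ΔH/T)). The kernel keeps running ΔH bookkeeping and
recomputes the Hamiltonian at checkpoints; the two must agree to 10⁻⁶
relative or the run aborts. Outside-lattice sites contribute no interface
energy (free boundary). The default run is 300 MCS with a convergence report
(relative energy change below 10⁻³ over the last 50 MCS).

Two published readings of the capillary target volume exist: the printed
formula 2πr_c²L_c0 and the geometric cylinder volume πr_c²L_c0 (2πr_cL_c0 is
the lateral *area* of that cylinder, suggesting a melded formula). The
reported capillary diameters (6.44 µm ≈ 2r_c = 7 µm, i.e. cross-section
≈ πr_c²) and vascular densities are consistent only with the cylinder
volume, which is therefore the default; `doubled_target_volume=True`
restores the printed formula. L_c0 is the grid dimension along the path's
axis — the nominal face-to-face vessel length "determined from the grid
dimensions" — not the meandering centerline length, which would inflate
every vessel's volume by the detour factor above.

The Monte Carlo kernel uses an internal xorshift64* generator (seeded per
run), so identical seeds give bit-identical lattices across platforms.

## Oxygen transport

Units are µm/ms/µM throughout. D = 2.1 µm²/ms; solubility 0.234 µM/mmHg
(= 2.34×10⁻⁴ mol·mmHg⁻¹·m⁻³), so the 30 mmHg capillary oxygen level is
exactly 7.02 µM. Capillary voxels are Dirichlet-clamped at that
concentration — the "constant concentration along capillary voxels" reading
of the source term. Endocrine voxels consume at constant (zeroth-order)
rates per voxel: at 6 mM glucose 0.1313/0.1810/0.1170 µM/ms (α/β/δ) and at
20 mM 0.2040/0.4850/0.2450 µM/ms. The transport equation as printed couples
the rate to the local PO₂ (first-order), but the tabulated units (µM/ms) are
a rate, not a rate constant; zeroth-order uptake with a clamp at zero is the
default, and `first_order=True` provides the other reading for sensitivity
analysis. Medium consumes nothing. Domain boundaries are zero-flux, so
capillaries are the sole oxygen source — the phenomenon under study;
avascular islets here correctly lose all cells.

The depletion clamp makes the steady state an obstacle problem: anoxic dead
cores form wherever consumption would drive the concentration negative (for
a 1-D slab of span L this happens once λL²/8D exceeds the clamp
concentration, and the profile becomes two wall parabolas meeting a C = 0
plateau). It is solved by projected successive over-relaxation
(ω = 2/(1+sin(π/N)), capped at 1.97) on a 2×-coarsened grid hierarchy used
for initialization, with warm starts between related conditions (glucose
levels, successive capillary counts). Convergence requires the discrete
rate-of-change residual |dC/dt| below `tol` (default 10⁻⁶ µM/ms) at every
non-clamped voxel, one-sided where the field is depleted; the converged
field satisfies the discrete steady-state balance to that tolerance, and
maximum principles (0 ≤ C ≤ 7.02 µM, monotonicity in sources and in
consumption) hold to solver tolerance.

## Viability classification and morphometry

Each cell's state comes from the mean PO₂ over its own voxels: functional
above 10 mmHg, hypoxic between 0.45 and 10 mmHg, non-viable below
0.45 mmHg; viable = functional + hypoxic. Exact boundary values go to the
lower class — the published inequalities are strict, leaving the boundary
(measure-zero in practice) to a documented convention. Reports give per-cell
tables plus whole-islet and per-type proportions (strata with no cells are
omitted, not zeroed) and the mean oxygen over medium voxels.

Morphometry mirrors the histology protocol on the middle z slice. Vessel
diameters: random capillary cross-sections (connected components per
capillary label) get a profile line at a random orientation through their
centroid; the chord between the two wall crossings is the estimate.
Border-touching components are skipped, as are components under 5 px — the
protocol measures the distance between the two vessel-wall peaks, which
sub-resolution film fragments cannot produce. Vascular density is
100 × capillary pixels inside the islet mask / mask pixels. The default
mask is the convex hull of the endocrine-cell pixels, emulating the
whole-islet area delineated by the insulin stain; a closing-based mask
(5 µm disc over cell+capillary pixels) is retained as `mask_rule="closing"`
for sensitivity, but at mid-plane the sphere cross-sections of a packed
islet are sparse and the closing under-segments the islet roughly twofold.
Density reports state the mask rule used.

## Viability model

V(N_cap, N_cells) = V_min + (V_max − V_min) / (1 + (C50/N_cap)^{n_C}
(N50/N_cells)^{n_N}), with n_C > 0 (capillaries help) and n_N < 0 (islet
size hurts). At (C50, N50) the model passes exactly through the midpoint
(V_min+V_max)/2. Note the model depends on C50 and N50 only through
C50^{n_C}·N50^{n_N}: the two half-maximum constants are jointly but not
individually identifiable, so fitted C50/N50 values depend on the bounds and
starting points (the identifiable combination is exposed as
`Results.log_gauge`); predictions, R² and MSE are unaffected.

Fitting is multi-start (16 Latin-hypercube starts by default) bounded
nonlinear least squares, deterministic under a seed, reporting R² (on the
fitted data) and MSE. Default bounds derive from the data ranges
(C50 ∈ [0.5·min, 2·max] of the observed counts, similarly N50; V_min ∈
[0, 0.5], V_max ∈ [0.8, 1], n_C ∈ [0.5, 4], n_N ∈ [−4, −0.5]) so the same
code fits full-size and scaled-down sweeps; explicit bounds can be passed.
Constant-response data raises (R² undefined). Bundled published human
parameter sets back the `predict` tool; mouse parameters were not published,
so mouse predictions require a user-supplied fitted parameter file. Inputs
outside N_cap ∈ [5, 300] or N_cells ∈ [583, 3516] are flagged as
extrapolation.

## Reduced-scale study protocols

Full-size simulated islets (~3×10⁷ voxels) are workstation-scale; the
package's reference studies run on scaled-down synthetic human islets with
the capillary loading preserved per unit grid cross-sectional (face) area,
referenced to the mean face area of the published human environments
(78,211 µm²). Face area is the right invariant because seed endpoints are
uniform over the grid faces: with n capillaries, n·A_islet/A_face of them
traverse the islet, so capillaries per unit islet area — the quantity the
density measurement reports and the through-islet spacing (hence
oxygenation) depends on — equals n/A_face. Scaling by islet area instead
would under-load small environments, where the fixed 30 µm buffer takes a
much larger share of the face.

Reference conditions: morphometry/viability islets of 200 cells in a 98 µm
ball at ≈30 % sphere packing — the packing fraction of real reconstructed
human islets (their published cell counts against their bounding
ellipsoids), and the property the vessel morphology is most sensitive to:
at ~50 % packing the seed paths meander through the islet and the grown
capillaries coat cell surfaces, roughly doubling the measured vascular
density, while at ~30 % they remain tube-like. Environment ≈165 µm per
side, three islets, 300 MCS, 100-capillary-equivalent loading (~34
capillaries at this size). Sweep islets of 30/60/90 cells (balls of
43/54/61 µm) packed at ≈52 % rather than 30 %: the oxygen penetration depth
(~13 µm at 6 mM glucose) does not shrink with the islet, so a sparse small
islet never reaches the oxygen-starved arm of the dose–response (every cell
ends viable at every capillary count and the sigmoid cannot be fitted);
restoring the governing ratio of islet radius to penetration depth by
raising the volumetric consumption — denser cells — is the scaled-down
design that preserves the dose–response shape. The sweep uses the scaled
equivalents of the full-size counts {5, 10, 25, 50, 100, 200, 300}
(deduplicated per islet), 100 MCS, one replicate, both glucose conditions. Study solves use a 10⁻⁵ µM/ms residual
tolerance (the classification margin is ~0.1 µM, four orders above the
steady-state error this leaves); the solver default elsewhere is 10⁻⁶.
The test suite runs the same protocols at slightly smaller sizes.

The stack-averaged vascular density remains the most scale-sensitive
readout: in larger scaled islets an increasing share of each vessel's
volume migrates onto intra-islet cell surfaces (capillary–cell contact is
strongly favorable, J_cα ≪ J_cm), pushing the measured density upward; the
reported value corresponds to the ~165 µm condition.

What the synthetic generator emulates: size/composition statistics,
overlap-free sphere packing, buffer geometry and areal capillary loading of
the published islets. What it does not: real islets' non-spherical cell
shapes, mantle/core type sorting, measured radii distributions, arteriole/
venule hierarchy, and full-size diffusion path lengths — so scaled runs
preserve local capillary spacing and per-vessel geometry but not whole-islet
core depth. Passing studies therefore demonstrate the mechanism and its
quantitative calibration at matched areal vascular density, not a cell-level
reproduction of any specific experimental islet.

## Numerical choices and degenerate inputs

- Tie rules: ΔH = 0 accepted; PO₂ exactly at a threshold goes to the lower
  class; tangent spheres do not overlap.
- Bounded randomness: all stage seeds derive from one master seed (CRC-mixed
  SeedSequence, kept below 2³¹); the Potts kernel uses xorshift64*; python-
  level stages use numpy Generators.
- Degenerate inputs: grids without capillaries yield the zero field with a
  warning (and 100 % non-viable cells); empty strata are omitted from
  reports; constant-viability sweeps refuse to fit; architectures that
  cannot reach zero overlaps report non-convergence rather than failing
  silently (synthesis retries three annealing rounds, then raises).
- Labeled volumes are exported as .npy plus a JSON metadata sidecar
  (entity types, volumes, provenance echo).

## Known limitations

- No hemodynamics: no blood flow, no intravascular oxygen depletion, no
  hemoglobin kinetics; capillaries are independent face-to-face tracks
  without branching or anastomosis.
- The contact-energy set places capillary wetting of cell surfaces at the
  margin (J_cα + J_cm = J_αm), so grown vessels partially spread along cell
  surfaces at T = 10; cross-sections are irregular rather than circular,
  which the profile-line protocol handles but a circularity assumption would
  not.
- Scaled-down studies preserve areal capillary density, not absolute islet
  size; size-dependent quantities (e.g. the cell-number term of the
  viability sigmoid) are fitted on scaled cell counts.
- The oxygen solver is serial; full-size environments are feasible but take
  workstation-scale time.
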