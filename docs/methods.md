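# Methods

This note documents the models and estimators implemented in
`dendricomplex`, the assumptions behind them, the defaults and why they were
chosen, what the synthetic-data generators do and do not emulate, and the
numerical choices that affect results.

## Dendrimer charge model

A dendrimer is represented combinatorially, not atomistically: an ordered
stack of amine layers from the terminal primaries (depth 0) inward to a
2-amine core layer, with counts halving at each depth. Generations are
labelled by terminal count — G3 has 32 and G4 has 64 terminal primary
amines for both PAMAM and PPI; half-generation (ester-terminated) species
are out of scope.

Protonation at neutral pH follows the standard schemes for these polymers:
PAMAM protonates exactly its terminal primary layer (interior tertiary
amines have strongly depressed pKa), while PPI protonates the terminal
primaries plus alternating tertiary layers. "Alternating" is implemented as
*even depths from the terminal layer* (0, 2, 4, …): this is the unique
alternation that charges two thirds of all amines, the occupancy predicted
by Ising-type models of PPI acid–base behaviour — 42 of 62 amines for G3
and 84 of 126 for G4. The statistical (Ising) model itself is not
implemented; only its resulting layer occupancy is. Net formal charge is
the count of protonated amines, one elementary charge each: +32, +64, +42,
+84 for PAMAM G3/G4 and PPI G3/G4.

## Ensembles and units

The in-memory container holds frames of (N, 3) coordinates in nm (the GRO
convention; Å-based formats are converted on ingest), per-atom masses,
element symbols, optional charges/residue ids/radii, and a group tag per
atom (`core`, `dendrimer`, `RB`, `water`, `ion_Na`, `ion_Cl`, `other`). All
descriptor modules select atoms through these tags. At most one core group
exists; it is the radial reference. Analytic reference solids deliberately
omit it — a physical bead at the center would occupy cavity volume and bias
the hollow-shell void oracle — and operations that need the core raise when
it is absent.

File IO uses MDAnalysis for multi-frame PDB and XYZ and mdtraj for
(multi-frame) GRO. GRO and PDB round-trip both coordinates (to format
precision, 10⁻³ nm) and group labels via residue names; XYZ stores only
element symbols, so reloading an XYZ file needs an explicit name→tag map.
Descriptors assume an intact molecule and measure plain Euclidean
distances; an optional unwrap step (orthorhombic minimum image about the
core) repairs molecules split across periodic boundaries, and the radial
module has a PBC-aware distance mode.

## Shape descriptors

RoG is the mass-weighted RMS distance from the selection's center of mass.
Inertia moments are eigenvalues of the mass-weighted inertia tensor about
the center of mass, sorted ascending so both aspect ratios lie in (0, 1].
Asphericity uses moments of inertia,

    δ = 1 − 3⟨I₂⟩ / ⟨I₁²⟩,  I₁ = Ix+Iy+Iz,  I₂ = IxIy+IyIz+IxIz,

with ⟨·⟩ averaging over the analysed frames. Note this is the
inertia-moment form: its thin-rod limit is 0.25 (Ix≈0, Iy=Iz), not the 1 of
gyration-tensor asphericity. δ ≥ 0 always (Cauchy–Schwarz), 0 iff the
inertia is isotropic. Aspect ratios are reported as time averages of the
per-frame ratios with sample SDs; δ is computed from the time-averaged
⟨I₂⟩ and ⟨I₁²⟩, and a per-frame δ series is exposed separately.

Reported SDs are frame-level sample SDs (ddof = 1) over the analysed
window; replicas are concatenated before averaging. The pipeline's
production default analyses the trailing 25 % of frames (the equilibrated
tail of a trajectory); library functions default to all supplied frames and
take an explicit `last_fraction`.

The RoG probability density is a normalised histogram (integrates to 1 over
its support); requesting more bins than samples coarsens the binning with a
warning rather than failing, and a constant series yields a single narrow
spike of unit integral.

## Radial profiles

Distances are measured per frame from the core group's center of mass.
`density` mode divides mean per-shell counts by exact shell volumes, so
Σ value·V_shell reproduces the mean selection count to round-off (count
conservation — asserted at 10⁻⁶ relative). `rdf` mode divides the density
by a reference density; for a finite, inhomogeneous system no canonical
bulk density exists, so the default reference is the selection's mean
density over the largest sampled sphere (the outermost bin edge) and the
choice — default or user-supplied — is recorded in the profile metadata.
Absolute g(r) heights therefore depend on that normalisation; shape and
ordering comparisons are the meaningful outputs. Default bin width 0.05 nm.
The internalization fraction interpolates the cumulative count linearly
inside the bin containing the query radius (bin-resolution accuracy) and
rejects radii outside the profile support — pass an explicit bin range when
querying beyond the sampled distances.

## Hydrogen bonds

Donor/hydrogen pairs and acceptors are explicit input lists; no chemical
perception is attempted. A bond requires donor–acceptor distance ≤ 0.35 nm
and deviation at the donor (angle between D→H and D→A) ≤ 30°, a widely used
geometric definition; both cutoffs and the angle convention travel with
every result. Hydrogens more than 0.15 nm from their donor in any frame are
treated as a list inconsistency and rejected. Classes (`internal`,
`with_water`, `with_RB`, `other`) come from the group labels of the two
heavy atoms; counts are disjoint by construction. Summaries report
per-frame mean ± SD; the SD convention (sample by default) is recorded.
Detection uses a k-d tree over acceptors but is validated against an
exhaustive triple loop on dense random frames.

## Void volume

`sasa_volume` rasterises atoms inflated by the probe radius onto a cubic
grid (default spacing 0.05 nm; a warning fires when spacing exceeds half
the probe radius) and labels the connected components of free space. Free
components that do not touch the box boundary are unreachable by the probe
and count as enclosed along with the occupied points. This
boundary-flood-fill definition is what makes the estimator see cavities:
at large probes sealed pockets are included in V_sasa, at small probes they
are not.

The cavity estimate fits a + b·r to V_sasa^⅓ over probes ≥ 0.4 nm (cube
roots grow linearly with inflation once internal structure is invisible)
and evaluates the deviation at 0.3 nm. The deviation is converted in volume
space — void = (a + b·0.3)³ − V_sasa(0.3) — because that yields nm³
directly and reproduces the hollow-shell oracle; the alternative of cubing
the cube-root-space deviation is available behind
`deviation_space="cuberoot"`. Negative estimates are clipped to zero and
flagged. Default probe set 0.3–1.0 nm in 0.1 nm steps. Atom radii come from
the ensemble's explicit per-atom radii when present (bead models), else
from the Bondi van der Waals table by element.

For complexes, RB-labelled atoms are deleted before the sweep, so the
complex/neat void ratio reflects scaffold deformation, not the volume the
ligand itself occupies. Grid discretisation error is a few percent for
0.05 nm spacing (validated by sphere/shell closed forms, grid-refinement
convergence, and rotation invariance within 5 %).

## Titration analytics

F564/F575 is read off each spectrum with linear interpolation between
sampled wavelengths; the peak position is the intensity maximum refined by
a 3-point parabola (plateaued maxima return the plateau midpoint with a
warning).

The stoichiometry estimator implements the titration form of Job's method:
candidate breakpoints are every interior x and the midpoints between
consecutive x values; for each candidate two least-squares lines are fitted
(points at the breakpoint belong to both segments, minimum 3 points per
segment), and the candidate minimising total SSE wins, ties broken toward
the smaller intersection. The estimate n is the intersection of the two
lines, reported both as a continuous value and as a half-up-rounded "1:n"
string. The estimator is exact on noiseless two-segment data for any
interior breakpoint and is invariant under affine rescaling of the response
(fluorescence units are arbitrary). Degenerate inputs are contracts, not
silent numbers: a series a single global line explains as well as two
segments raises (no breakpoint information); parallel-but-offset segments
(a step) fall back to the plateau onset with a flag; an intersection
outside the sampled ratio range is clipped and flagged.

The saturation (plateau) estimator returns the post-breakpoint line's mean
over its x-range, accepting the plateau only when its slope magnitude is
below 25 % of the binding limb's; an everywhere-flat series is its own
plateau, and a decreasing-only series raises. The singlet-oxygen statistic
is the OLS slope of a reporter time course divided by the control slope,
× 100.

## Synthetic-data generators

The generators define the study conditions; they are statistical stand-ins
with recorded ground truth, not physics.

*Titrations.* The zeta generator produces a linear fall from +40 mV at the
first grid point to a −30 mV plateau exactly at the true stoichiometry n,
on a molar-ratio grid 1–50 (the experimentally scanned range), plus seeded
Gaussian noise. The spectral generator mixes two equal-width Gaussians
(free dye peaking at 564 nm, bound at 575 nm) with bound fraction
θ = min(x/n, 1) and a transient quench A = 1 − 4qθ(1−θ); the F564/F575
curve derived from it is mildly convex in the binding limb, so the
breakpoint estimator recovers n with a bias of up to ~10 % there —
consistent with treating the two readouts as independent estimates that
agree to a few units of n, which is the level of agreement the closed-loop
tests assert.

*Bead ensembles.* One bead per amine is grown outward from a core bead
along the topology's branching tree with persistent random branch
directions (segment length 0.35 nm, bead radius 0.12 nm, equal masses).
Frames perturb the directions with Gaussian noise of SD 1/stiffness;
stiffness 50 gives the near-frozen, narrow-RoG behaviour of rigid PPI,
stiffness 4 the broad fluctuations of flexible PAMAM. All frames are
rescaled uniformly so the ensemble-mean RoG equals the requested target
exactly; the analysis drivers use the experimentally reported mean RoG
values (1.460, 1.859, 1.284, 1.590 nm for PAMAM G3/G4, PPI G3/G4) as
targets. Ligand beads keep fixed directions and RoG-relative radial factors
about the core (U(0.3, 0.8) for internalized, U(1.2, 1.8) for
surface-bound), so they co-move with scaffold breathing;
`scaffold_compaction` < 1 shrinks the dendrimer about its core in complex
frames, emulating the binding-induced contraction of a flexible scaffold.
Water/ion beads are uniform-in-volume labelled clouds; planted
hydrogen-bond frames contain an exact number of near-collinear
donor–H–acceptor triplets per frame with decoys far outside the cutoffs.

What the generators do **not** emulate: force fields, binding kinetics,
solvent structure, counterion condensation, or any energetics. Passing
tests therefore demonstrate that the estimators recover known geometric and
statistical ground truth and reproduce the rigid-vs-flexible orderings
(narrower RoG distribution, deeper ligand internalization, and larger
complex/neat void ratio for the rigid model); they do not validate absolute
descriptor values against experiment, and published per-system descriptor
tables or H-bond counts are not reproduction targets — those require the
original explicit-solvent trajectories.

*Reference solids* provide closed-form oracles: uniform balls
(RoG = √(3/5)·R), isotropic Gaussian clouds (δ → 0), thin rods (δ → 0.25),
overlapping-bead balls (no cavities), and hollow bead shells whose
antipodally paired construction puts the center of mass exactly at the
origin (bead-center RoG = shell radius to round-off). The shell wall is
dense (bead spacing twice the bead radius, gaps far below any probe) with
exact circular apertures at both poles rimmed by a ring of beads at axis
distance r_bead + 0.35 nm, so a 0.3 nm probe enters and a 0.4 nm probe does
not — the geometry the probe-sweep estimator is designed to detect, with
cavity volume (4/3)π r_in³ known analytically.

## Problem sizes and determinism

Every generator takes an explicit seed (numpy `default_rng`) and is
byte-reproducible; truth parameters are stored in series/ensemble metadata.
The test suite and analysis drivers use deliberately modest sizes — tens of
frames per ensemble, 10⁵-point Monte-Carlo solids, 200 seeded titration
replicates, 0.05 nm void grids (0.075 nm for multi-frame ratio scans) —
chosen so the full battery runs in minutes on one core while keeping
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The charge model is formal (integer protonation counts); no pKa shifts,
  no partial charges, no electrostatics.
* The bead model's aspect ratios and asphericity depend on the random base
  conformation; only distributional contrasts between stiffness regimes are
  meaningful, not absolute shape values.
* RDF absolute heights depend on the recorded reference-density choice.
* The two-segment estimator assumes a single breakpoint; multi-step binding
  is out of scope.
* The void estimator's grid pays a few percent discretisation error; very
  narrow channels near the grid spacing may be misjudged (the spacing
  warning guards the probe/spacing ratio).
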