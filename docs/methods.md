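# Methods

## The common-constraints elastic network

Coarse-grained MARTINI-style protein models keep their fold through an
elastic network (EN): harmonic restraints between backbone beads (one bead
per residue, at the Cα position) whose pair distance lies in a cutoff
shell. Because the restraint lengths are taken from one experimental
structure, the EN pins the model to that conformational state. Given two
states A and B of the same (or a homologous) transporter, `comdyn` builds
the EN of each state and then removes every restraint whose reference
distance differs between the states by more than a threshold:

    keep (i, j, d0)   iff   |d0 − d_other(m(i), m(j))| ≤ t,

with `m` the interstate residue correspondence and `t = 0.1 nm` (1 Å) by
default. What survives is the geometry both states agree on; what is
removed is exactly the set of state-specific contacts that would otherwise
forbid the transition. The filter is applied per state, so the two states'
kept counts generally differ; an intersection mode exists but is not the
default.

Build parameters follow the standard martinize convention — shell
0.5–0.9 nm, force constant 500 kJ·mol⁻¹·nm⁻², restraints only between
residues ≥ 3 apart in sequence (closer neighbours are bonded terms, not
EN; cross-chain pairs are always eligible). All of them are first-class
configuration, because published kept/total counts can only be reproduced
modulo the original build parameters. The threshold comparison is
inclusive (≤); a strict flag exists.

Unmapped endpoints: a restraint whose bead pair has no image in the other
state cannot be checked for interstate agreement and is dropped
(conservative default; `unmapped="keep"` is available).

## Residue correspondence

Three modes: `identity` (same numbering), `alignment` (global, end-gap
free, BLOSUM62, gap open −10 / extend −0.5 — appropriate for homolog
pairs of ~70 % identity such as GLUT1/GLUT3), and `explicit` (user spans,
e.g. a conserved-segment table). Alignment mode is the default for
cross-homolog use since it requires no extra input; explicit spans
override it when a curated segment table is available.

## Order parameters

The rocker-switch motion is tracked by distances between the unweighted
centroids of 10-residue helix windows at the intracellular ("in") and
extracellular ("out") ends of the transport-cavity helices, around the
ring TM2–TM1–TM5–TM8–TM7–TM11(–TM2): 12 series (6 adjacent pairs × 2
sides), plus configurable cross-rim extras (e.g. TM5/TM11). Centroids are
unweighted means of the backbone beads (single-site beads; no
mass-weighting). Closest-approach definitions were considered and
rejected: centroid distances are smooth, rigid-body invariant and match
the arrow-between-helix-bodies picture used for this family. No periodic
boundary handling is performed; trajectories are assumed whole and
centered.

## Overlap and shift

Ensembles are compared per order parameter through uniform histograms on
a shared, zero-anchored grid (default bin width 0.05 nm):

* overlap = Σ_b min(p_b, q_b)·Δ — a fraction in [0, 1]; identically
  1 − ½·L1 distance between the densities (asserted numerically in the
  tests);
* shift = peak(mut) − peak(ref) in nm, positive = opening, negative =
  closing; peaks are raw modal bin centers, ties broken toward the
  smaller distance, no smoothing.

Histograms (not KDE) keep the minimum-integral definition exact bin
arithmetic. The wild-type reference is the pooled series of both
wild-type state ensembles by default. Deviating order parameters are
flagged at overlap < 0.6 or |shift| > 0.15 nm (configurable).

## Essential dynamics

Frames (optionally restricted to a conserved bead subset) are
least-squares fitted (Kabsch, proper rotation enforced) to a reference
(first frame by default, configurable to a crystal state). The
mass-unweighted covariance of the fitted coordinates is diagonalized;
projections use the leading eigenvectors. The population covariance
(divisor N) is used, so the projection variance along eigenvector k
equals eigenvalue k exactly on the training ensemble. PCA sign ambiguity
is fixed deterministically (largest component positive), and an `orient`
structure can force a negative EV1 projection, which puts the
outward-occluded state on the left of the usual transition plots.

## Toy Brownian-dynamics sampler

Overdamped Euler–Maruyama on the bead-spring energy
U = Σ ½k(d − d0)², with optional stiff chain springs between consecutive
beads (k = 4000 kJ·mol⁻¹·nm⁻²; rest lengths default to the start
structure's own virtual-bond lengths so an energy-minimum start is
exactly stationary at kT = 0). First-order dynamics is the cheapest
scheme with the correct stationary distribution; no inertia, solvent,
nonbonded terms or kinetic realism is claimed. Default dt = 2·10⁻⁵
satisfies dt·k_max/γ < 0.1 for the stiffest default spring. A `frozen`
bead set implements position restraints for static context. A divergence
guard aborts on any coordinate passing 10³ nm.

Energies and kT are reduced units on the martinize force-constant scale;
the single-spring equipartition identity var(d − d0) = kT/k is the
calibration check.

## The synthetic two-state bundle

The generator emulates an MFS-fold rocker switch at desk scale: six
mobile 24-bead helix rods (rise 0.15 nm) on a ring, tilting radially
about their mid-height so the inside (z = 0) ring radius closes from
1.0 nm (state A) to 0.8 nm (state B) while the outside opens from 1.0 to
1.2 nm. Both states share the mid-height radius, making the interstate
motion a pure per-helix rocker tilt. Helices are straight bead rods (no
helical twist): centroid order parameters are twist-insensitive and the
geometry stays closed form.

The mobile ring alone is not a usable two-state system for a
common-constraints network: with only intra-helix constraints kept, the
six tilts are independent soft coordinates and a joint visit of the
opposite state is exponentially suppressed, while any smooth inter-helix
coupling necessarily carries kept restraints with near-threshold
interstate changes whose summed energy walls off state B. The fixture
therefore embeds the ring in a static scaffold playing the role of the
rest of the protein:

* valley columns between the helices, placed at the radius equidistant
  from each bead's two state positions, (r_A + r_B)/(2·cos(π/6)), tilted
  with height. Their restraints cost almost nothing anywhere along the
  A→B path but rise quadratically beyond either endpoint — they confine
  each helix to the transition corridor (azimuthal and vertical wobble is
  first-order pinned) without opposing the transition itself. The filter
  keeps them.
* pin anchors, single beads 0.75 nm radially outside each helix end.
  Every pin contact changes by more than 1 Å between the states, so the
  filter drops all of them while each full single-state network keeps
  them — they are the state-specific tertiary contacts whose removal is
  the whole point of the method.

With martinize-default parameters the filter keeps ~95 % of the state-A
network (the dropped 5 % being exactly the pin contacts and the
outermost valley contacts), the residual energy of state B under the
A-built filtered network is ~3.5 reduced units, and the walls outside
the corridor are ≥ 13. The scaffold is position-restrained during the
sampling assay.

Truth tables (every eligible pair's interstate distance change; segment
centroid distances) are computed by brute-force enumeration, independent
of the KD-tree code path.

Gaussian-mixture series emulate wild-type (two-basin) versus mutant
(single-basin or displaced) order-parameter sampling with analytic
overlap/shift.

### What the fixture does not emulate

Real side-chain packing, sequence heterogeneity, membrane and solvent,
helical twist and bending anisotropy, and the slow collective kinetics of
a real transporter. Passing the toy assay shows the constraint-filtering
logic creates a transition-permissive network where a single-state
network pins — it does not quantify real GLUT transition rates or mutant
phenotypes.

## The sampling assay

Three runs: full state-A network from A, full state-B network from B,
and the filtered network from A. The spec-level claim is comparative:
each single-state network should pin its run near its own state (high
minimum RMSD to the opposite state), while the filtered-network run
approaches both states and spends time in both basins. Starting the
state-B-network run from state B (rather than from A) is deliberate:
started from A, that run either trivially touches A (min-RMSD 0) or is
actively pulled into B by its own minimum, so neither direction yields a
well-posed comparison; from B it is the conventional single-state CG
simulation the method is contrasted against.

Assay conditions, fixed once from energy profiles and pilot runs:
kT = 0.5, 80 000 steps, frames every 100 steps, basin cutoff 0.6 × the
interstate RMSD (just above the soft network's thermal cloud,
comfortably below the pinned networks' separation). Basin-visit
fractions are averaged over ≥ 5 seeds; the strict min-RMSD comparison
holds per seed.

## Numerical choices and degenerate inputs

* Coordinates are nm internally; PDB Å are converted on read/write.
  PDB precision (0.001 Å) flips pair eligibility exactly at the cutoff
  boundary (e.g. 6 × 0.15 nm = the 0.9 nm upper cutoff); end-to-end
  file-based comparisons therefore recompute references from the
  round-tripped files.
* Altloc: highest occupancy wins. Insertion codes get synthetic monotone
  resids (logged). Residues without Cα are skipped.
* Superposition requires ≥ 3 beads and non-collinear configurations;
  mirror pairs keep det(R) = +1 and a nonzero residual.
* Histogram grids are anchored at zero so independently binned series
  with a shared range are bin-compatible; constant series get one
  covering bin.
* Empty residue maps, zero-width histogram ranges, malformed topology
  lines (reported with line number) and unknown funct values are hard
  errors.

## Problem sizes

Tests and the acceptance script use the default bundle (192 beads,
~1900-constraint networks), 80 k-step assays over 5 seeds, 41-frame ED
ensembles and 4000-sample mixture series — sizes chosen so the full
pipeline, including the stochastic assay, runs on a laptop-class single
core in minutes while keeping the assay's basin statistics resolvable.

## Known limitations

* The published kept/total counts for GLUT1/GLUT3 depend on the original
  (unrecorded) martinize parameters; the check on the real structures
  carries a ±5 % engineering tolerance and requires the two PDB files.
* The overlap/shift module reports no significance measures.
* The BD sampler makes no kinetic claims; only stationary-distribution
  properties are tested.
* Cross-homolog mapping by global alignment can misalign loop regions;
  explicit conserved-segment spans are preferred when available.
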