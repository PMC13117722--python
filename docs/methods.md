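# Methods

This note records the models, conventions and design choices behind
`vesikit`, in the order a user meets them: lipid templates, vesicle
construction, file emission, analysis operators, and the synthetic
fixtures the test suite relies on.

## Lipid templates and force-field subset

Each phosphatidylcholine is a twelve-bead chain: choline (bead 1, +1 e),
phosphate (bead 2, −1 e), two glycerol beads (3–4), and two four-bead
tails (5–8 and 9–12), so the tail ends are beads 8 and 12 and every lipid
is net-neutral. A cis double bond is modelled at the third tail bead
(7 and/or 11): DPPC has none, POPC one (bead 11, the sn-2 oleoyl chain),
DOPC two. Unsaturated beads take the C3 bead type and a `D` name prefix,
which is also how templates flag them when read back from the parameter
file.

Bonded terms follow the published MARTINI 2.x lipid values: bonds
b₀ = 0.47 nm (0.37 nm for the glycerol–glycerol bond), k = 1250
kJ/mol/nm²; cosine-harmonic angles V(θ) = (k/2)(cos θ − cos θ₀)² with
θ₀ = 180°, k = 25 kJ/mol on saturated triples and θ₀ = 120°, k = 45
kJ/mol on the triple centred on an unsaturated bead. Nonbonded pairs for
the six bead types in play (Q0, Qa, Na, C1, C3, P4) are transcribed from
the published interaction-level ladder (ε from 5.6 down to 2.0 kJ/mol,
σ = 0.47 nm except 0.62 nm for charged–apolar pairs), with ε_r = 15 and
r_c = 1.2 nm. All of this ships as a data file in the GROMACS itp dialect
(`data/martini_lipids.itp`) plus a plain-text species registry, so a user
can swap in a force-field revision without code changes.

`equilibrium_angle_mean` computes ⟨θ⟩ under the angle potential by
trapezoidal quadrature over θ ∈ (0, π) with the sin θ Jacobian
(200,001-point grid; the potential minimum is subtracted before
exponentiation so the stiff limit stays finite). At the kink parameters
(θ₀ = 120°, k = 45, T = 390 K) it gives 120.31°; the Jacobian pushes the
average slightly above θ₀. In-membrane packing pushes it a little higher
still, which is why simulated membranes show ~122°.

## Vesicle construction

Geometry is nm, the vesicle sits at the centre of a cubic box, and the
built structure is not wrapped. Leaflet populations come from
N = round(4πr²/APL) on the leaflet *reference spheres*. Their defaults,
r_out = 13.7009 nm and r_in = 11.5400 nm, are obtained by inverting that
formula at the reference populations (5128/3638) and APL 0.46 nm²; for
other diameters they scale proportionally. Head beads are anchored on the
reference sphere by a Fibonacci (golden-spiral) lattice — near-uniform
areal density, deterministic — composed with a random global rotation
drawn from the build seed, so two builds with the same spec and seed are
bitwise identical while different seeds decorrelate the lattices.

Each lipid starts as a straight chain along the local radial axis at
template bond lengths, the second tail parallel to the first at a 0.25 nm
lateral offset (hence a freshly built lipid has |r₈ − r₁₂| = 0.25 nm
exactly, a useful structural fingerprint in tests). Outer-leaflet chains
point inward, inner-leaflet chains outward. For a 30 nm vesicle the two
leaflets' tails interdigitate radially; this is deliberate — downstream
energy minimisation by the MD engine removes the residual strain, and the
initial structure only needs to be unambiguous and overlap-free at the
bead scale.

Solvation fills a jittered simple-cubic lattice clipped by two radial
exclusion shells: water is kept strictly below min(lipid radii) −
min_separation and strictly above max(lipid radii) + min_separation
(min_separation = 0.40 nm). The lattice constant defaults to 0.41 nm with
a ±0.004 nm per-axis jitter, so the closest possible water–water contact
(0.408 − 0.008 nm) also respects min_separation; jitter is applied before
the radial clip so water–lipid separations are exact. The spacing is set
slightly below the CG bead diameter because the inner core — capped by the
outer leaflet's tail ends at r ≈ 10.5 nm — must hold the packaged 67,522
core beads; a 0.47 nm lattice holds only ~45k sites there. The packaged
default water counts (67,522 / 334,358) are configuration, not derived
quantities: no single water-bead volume reproduces both counts in a 40 nm
box, so the builder pins them and trims the lattice deterministically,
dropping the sites closest to the exclusion shells (ties broken by site
index). Requesting more water than the clipped lattice holds raises a
capacity error that reports the maximum.

The three thermostat groups partition the beads by construction: all
lipid beads are BILAYER, core water INNER_WATER, box water OUTER_WATER.
Group order is fixed everywhere as (INNER_WATER, BILAYER, OUTER_WATER) so
the per-group `ref_t` line in run parameters is unambiguous.

## File emission

GRO, NDX, TOP and MDP writers are deterministic byte-for-byte. GRO uses
the fixed-width dialect with the standard modulo-100000 residue/atom
numbering; round-tripping preserves names exactly and coordinates to the
format's 0.001 nm. NDX always emits the three groups, validating the
partition on every write. TOP includes the packaged parameter file and
run-length-encodes molecule counts in build order; it refuses systems
without build provenance (an analysis-only structure has no meaningful
molecule ordering contract). MDP emits the leap-frog integrator,
Verlet cutoff scheme with rvdw = rcoulomb = 1.2 nm, v-rescale thermostat
over the three groups, Parrinello–Rahman barostat with τ_p = 13 ps and
1 bar reference, and semi-isotropic pressure coupling by default
(isotropic is a constructor switch; semi-isotropic is kept as the default
protocol even though the system is spherical, matching the heating-run
convention this toolkit targets). The equilibration protocol is 300 ps of
NPT at 300 K with 10 fs steps; production protocols run 230 ns with one
group's reference temperature raised to 390 K. 10 fs is used for
production too, as the only step size the protocol family specifies.

Trajectory reading is delegated to MDAnalysis (XTC/TRR/multi-frame GRO)
behind a streaming `TrajectorySlice` contract: constant memory in
trajectory length, strictly increasing frame times enforced, selections
resolved from index-file groups or residue names, bead-count mismatches
rejected up front and truncated files reported as a partial-read warning
with the frame count reached.

## Analysis conventions

*Vesicle centre* is the centre of geometry of the lipid beads of the
frame being analysed; the minimum-image convention applies to all
distances. Frame-averaged structural operators default to the final 10 %
of frames, since they are meant to describe the relaxed end state of a
run; the fraction is a parameter.

*Molecular RDF.* Distances between molecules are minima over all bead
pairs; counts land in 0.01 nm bins centred on multiples of 0.01 nm and are
averaged over reference lipids and frames. Values are raw neighbour
counts (their sum is the mean neighbour count within range); a
density-normalised variant sits behind a flag. Neighbour search is a
periodic KD-tree; molecule-pair minima are taken by a sort-reduce, so
cost scales with the number of bead pairs inside r_max, not N².

*Area per lipid.* Leaflets are assigned per lipid by the sign of the dot
product between the head→tail vector and the radial direction of the
lipid's centre of geometry — orientation, not radius, so the assignment
stays correct for small vesicles whose inner-leaflet phosphates sit
outside the outer-leaflet ones. The combined APL is the area-weighted
mean of the two leaflet values and is the headline number; per-leaflet
values are always reported alongside. On a freshly built default vesicle
the combined value recovers the input 0.46 nm² to well under 1 %: the
phosphate spheres sit one bond length below/above the head anchors, and
the two deviations cancel almost exactly in the area weighting.

*MSD / diffusion.* Phosphate-bead positions (or single beads for
point-particle fixtures) have the selection's per-frame centre of
geometry removed, then the MSD is averaged over molecules and all time
origins via the FFT autocorrelation identity. D = slope/d_fit where
d_fit = 2 × dimensionality: 4 by default ("lateral" — lipid motion on the
shell is quasi-two-dimensional) or 6 for free 3-D diffusion, which
recovers D = σ²/(2Δt) on a Gaussian random walk. The default fit window
is lag 10–50 % of the trajectory. Unwrapped coordinates are assumed.

*Group energies.* Shifted-potential Lennard-Jones and Coulomb sums at
r_c = 1.2 nm, ε_r = 15, f = 138.935 kJ·nm/(mol·e²), intramolecular pairs
excluded, tree-based neighbour search verified against an O(N²) oracle.
Group order is canonicalised internally so swapping arguments returns
bit-identical values. Lipid–water electrostatics are exactly zero for
every system this toolkit builds, because the water bead is uncharged —
a structural identity, not a numerical coincidence. Absolute agreement
with a particular engine's energy-file output is *not* promised (long-
range treatment and modifiers differ); trends and the electrostatic zero
are.

*Kink angles / end-to-end.* Angles are computed from the two bond vectors
of each triple centred on an unsaturated bead; for a fully saturated
species the saturated tail triples are reported instead, flagged
`saturated_only`. End-to-end is the Euclidean distance between beads 8
and 12 per lipid per frame.

*Pore detection.* Lipid beads are projected to directions on the
mid-radius sphere (R_mid = mean lipid-bead radius). An equal-area
latitude-band grid at ~0.5 nm linear resolution marks a cell occupied if
any bead direction falls within half a cell diagonal plus one bead radius
(0.235 nm, half the CG σ) of its centre — the bead-radius dilation is
what keeps a pristine vesicle pore-free even though the grid is finer
than the lipid spacing. Connected empty patches (adjacency within 1.5
cell sizes) are reported with angular radius α = max centroid–member
angle + half a cell + one bead radius and diameter 2·R_mid·α; the
punched-hole fixtures show this estimator lands within ~15 % of the
constructed truth across hole sizes. A resolution coarser than the
per-leaflet lipid spacing (≈ √APL) is refused.

## Synthetic fixtures

The fixture generators provide *statistical* ground truth, not MD physics
(no nonbonded forces act during sampling):

* **Random walks** — independent per-axis Gaussian increments of variance
  σ² per frame; D = σ²/(2Δt) per axis, MSD(kΔt) = 3kσ² in 3-D.
* **Boltzmann chains** — bonds fixed at b₀; each angle with a template
  potential drawn exactly from its Boltzmann density: in c = cos θ the
  density is a Gaussian truncated to [−1, 1] (the sin θ Jacobian cancels),
  so rejection against the untruncated Gaussian is exact and fast for all
  stiffness values; angles without a potential are uniform in cos θ and
  dihedrals uniform. Conformers are independent and laid out on a grid.
* **Punched vesicles** — all lipids whose head-bead direction lies in a
  cone are removed (expected removals N(1 − cos α)/2), water untouched,
  giving constructed truth for the pore detector.

Everything derives from an explicit seed and reproduces bit-for-bit.

What passing fixture tests shows: the operators compute their definitions
correctly and recover known parameters at the stated statistical
precision. What it does not show: fidelity of real MD output — fixtures
have no inter-lipid correlations, no solvent structure, no thermostat
artefacts, and the built vesicle is a pre-minimisation idealisation. The
post-heating observables themselves (APL 0.5–0.9 nm², diffusion of order
0.05–0.12 × 10⁻⁵ cm²/s, ~2.5 nm notches) require the external 230 ns
engine runs whose inputs this toolkit emits.

## Problem sizes used in the test suite

The suite exercises the full 507,072-bead reference build (construction
plus composition and APL checks, a few seconds), a 10 nm miniature
vesicle for geometric and energy invariants, ≤ 50-molecule systems for
the O(N²) oracles, 1000 particles × 1000 frames for diffusion recovery
(statistical error comfortably inside the 5 % band) and 2–3 × 10³
conformers for angle statistics. These sizes were chosen so each check's
statistical resolution is several times finer than the tolerance it
enforces.

## Known limitations

* Single-species leaflets only; no cholesterol, mixed compositions,
  asymmetric per-leaflet APL, or MARTINI 3 mappings.
* The builder's initial conformation is strained by design; structures
  must be energy-minimised before dynamics.
* Energy recomputation uses plain shifted-cutoff potentials; it is not a
  drop-in replacement for a specific engine's energy bookkeeping.
* Pore diameters assume roughly isometric patches; long thin cracks are
  reported by their angular radius, which overstates their width.
* No EDR parsing, no checkpoint/tpr handling, and the toolkit never
  invokes the MD engine itself.
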