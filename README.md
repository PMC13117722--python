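# vesikit

Coarse-grained spherical liposome construction and membrane trajectory
analysis.

`vesikit` is for people who simulate whole vesicles rather than planar
bilayer patches: it builds a complete spherical liposome of MARTINI-style
twelve-bead phosphatidylcholines (DPPC, DOPC or POPC), solvated inside and
out, and emits the GROMACS file set (`.gro`, `.ndx`, `.top`, `.mdp`) for
*portion-selective heating* runs — non-equilibrium simulations in which one
of three thermostat groups (inner water core, lipid bilayer, outside water)
is raised from 300 K to 390 K while the others stay at 300 K. It then
computes the membrane observables that characterise the resulting structure
change from the engine's output trajectories.

## The model

**Construction.** A leaflet of radius *r* at area per lipid *APL* holds

&nbsp;&nbsp;&nbsp;&nbsp;*N* = round(4π*r*² / *APL*)

lipids. With the packaged reference radii (r_out = 13.7009 nm,
r_in = 11.5400 nm, from inverting the formula at the reference populations)
and APL = 0.46 nm², the default 30 nm vesicle carries 5128 outer- and 3638
inner-leaflet lipids. Head beads are anchored on the leaflet sphere by a
golden-spiral (Fibonacci) lattice with a seeded random global rotation;
each lipid is a straight radial chain at template bond lengths, tails
parallel at a 0.25 nm lateral offset, leaving residual strain to the MD
engine's energy minimiser. Water beads (one bead = four waters) fill a
jittered cubic lattice inside and outside radial exclusion shells around
the bilayer; the packaged configuration pins the counts at 67,522 (core)
and 334,358 (outside) beads.

**Analysis.** The toolkit implements, among others:

* *molecular radial distribution* — for each reference lipid, the count of
  lipid/water molecules per 0.01 nm bin of the **molecular** distance, the
  minimum over all inter-bead distances (raw counts, not a normalised g(r));
* *vesicle area per lipid* — leaflets assigned by head-to-tail orientation
  against the radial direction, leaflet radius from the mean phosphate
  distance to the vesicle centre, APL = 4πR²/N per leaflet plus an
  area-weighted combination;
* *MSD / diffusion* — drift-corrected, time-origin-averaged phosphate MSD;
  D = slope/d_fit with the lateral convention d_fit = 4 (units 10⁻⁵ cm²/s);
* *group–group nonbonded energies* — shifted-cutoff Lennard-Jones and
  Coulomb sums (r_c = 1.2 nm, ε_r = 15) between thermostat groups, with
  lipid–water electrostatics exactly zero by construction (water beads are
  uncharged);
* *kink angles and end-to-end distances* — tail angles centred on
  unsaturated (cis) beads, whose cosine-harmonic potential (θ₀ = 120°,
  k = 45 kJ/mol) makes unsaturated tails bend, and the distance between the
  two tail end beads (8 and 12);
* *pore detection* — an equal-area occupancy grid on the mid-radius sphere
  that reports lipid-depleted patches with diameter 2·R·α.

A synthetic-fixture module (Brownian walks, Boltzmann-sampled conformers,
hole-punched vesicles) provides statistically exact ground truth so every
operator is testable without an MD engine.

## Worked example

```sh
vesikit build --species DPPC --diameter 30 --apl 0.46 --box 40 --seed 1 \
              --heated-group BILAYER --out scratch/vesicle
```

prints

```
built DPPC vesicle: 5128 outer + 3638 inner lipids, 67522 inner + 334358 outer water beads
  gro: scratch/vesicle.gro
  ndx: scratch/vesicle.ndx
  top: scratch/vesicle.top
  mdp: scratch/vesicle.mdp
```

i.e. the 507,072-bead reference system, its three-group index file, its
topology (`DPPC 8766` / `W 401880`) and a production protocol whose
`ref_t = 300 390 300` heats the bilayer group to 390 K. Measuring the
packing density of the build:

```sh
vesikit analyze apl --structure scratch/vesicle.gro --ndx scratch/vesicle.ndx
```

```
leaflet	apl_nm2	radius_nm	n_lipids
outer	0.428982	13.2309	5128
inner	0.498233	12.01	3638
combined	0.460265	nan	8766
```

The combined area-weighted APL recovers the 0.46 nm² the build was asked
for (the outer/inner split reflects the two phosphate spheres sitting one
bond below/above the head anchors). The same subcommands (`rdf`, `msd`,
`energy`, `angles`, `endtoend`, `pores`) run on any structure/trajectory
pair, e.g. the XTC written by the engine after a heating run.

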