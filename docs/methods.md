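# Methods

`ringtier` quantifies the quaternary geometry of ring- and spiral-shaped
protein assemblies — the stacked domain "tiers" of hexameric replicative
helicases and their loader complexes — together with the two orthogonal
measurements used to validate such models: native mass spectrometry
stoichiometry arithmetic and crosslinking-MS distance restraints. This note
records the models, conventions and numerical choices behind each number
the package reports.

## Tier geometry

A *tier* is an ordered series of domains (e.g. the six C-terminal ATPase
domains of a helicase hexamer, bottom of the staircase to top). Each domain
is reduced to a center of mass; all geometry operates on that ordered COM
series plus, where needed, the underlying atoms.

**Centers of mass.** By default COMs are computed over non-hydrogen atoms
with element average masses. Published analyses of this kind rarely state
whether "center of gravity" meant mass-weighted or uniform, or whether side
chains were included, so the weighting (`atomic_mass`/`uniform`) and an
all-atom/Cα-only switch are explicit options recorded in every report.
Partially unmodelled intervals contribute the COM of their modelled atoms,
with the modelled fraction logged.

**Plane fits and inter-tier angles.** Planes are total-least-squares fits:
centroid plus the smallest principal component of the centered points. The
angle between tiers is the acute dihedral, `arccos |n_a · n_b|`, bounded in
[0°, 90°]. (The acute fold makes the result independent of the arbitrary
sign of a fitted normal.)

**Pseudo-helical parameters.** The axis of an ordered COM series is fitted
in two deterministic stages:

1. *Initialisation.* The direction comes from the chord-bisector
   construction: for a uniform helix the second differences
   `p[k-1] − 2p[k] + p[k+1]` all point from the curve toward the axis, so
   cross products of consecutive ones are parallel to the axis. This is
   exact for ideal helices and planar rings. (Degenerate cases fall back to
   the plane normal.) The lateral position is an algebraic circle fit of
   the projected points.
2. *Refinement.* Four parameters (two direction tilts, two lateral
   offsets) are refined by Levenberg–Marquardt least squares on the joint
   spread of (a) point-to-axis radii and (b) per-step axial climbs — both
   constant for a uniform helix. Radial spread alone is *not* used as the
   objective: with six points and four axis parameters, spurious tilted
   cylinders can interpolate the radii almost exactly while scrambling the
   rises, and an unconstrained radial-variance minimiser will find them.
   The iteration budget is 200 evaluations with 1e-15 tolerances; on
   non-convergence the initial axis is returned and flagged.

The fitted axis is oriented so the mean rise along the stated domain order
is non-negative. Per-step rise is the difference of axial coordinates;
per-step twist is the signed angle between consecutive radial vectors
(right-hand rule about the axis), so positive mean twist means a
right-handed staircase. A series whose |mean rise| is below 1e-6 Å is
reported `planar`; for such rings the axis orientation, and hence the twist
sign, is arbitrary — consumers should compare twist magnitudes.

**Pitch.** Two quantities are reported side by side and neither is
privileged: the *turn pitch* `mean_rise × 360 / |mean_twist|` (axial climb
per full turn) and the *axial extent* (total climb across the observed
series). Published "pitch" values for short open protein spirals do not
consistently follow either convention, so the package never reduces the
pair to one number.

**Chamber diameter.** Atoms are partitioned into axial slabs (default 5 Å);
each slab's diameter is twice the smallest van-der-Waals-corrected
atom-to-axis distance, and the reported diameter is the tightest positive
slab value, with the full axial profile attached. A diagnostic flags an
axis that does not thread the atom cloud (largest angular gap of projected
atoms ≥ 180°).

**Gaps, rotations, isomers.** Interface gaps are minimum pairwise
distances, by default all-atom center-to-center (Cα-only and
vdW-surface-subtracted modes are selectable, since a published "~15 Å gap"
rarely states its convention). Subunit rotations come from two Kabsch
superpositions — anchor first, probe second — with the residual rotation
angle extracted as `arccos((tr R − 1)/2)`. The cis/trans classification of
a subunit asks whether its N-terminal hairpin COM points toward (< 90°) or
away from its own C-terminal domain COM, seen from the NTD globe.

## Surface areas

SASA is Shrake–Rupley sampling on a deterministic Fibonacci lattice
(default 960 points/atom, probe 1.4 Å) over a fixed, versioned Bondi radius
table (`bondi64-v1`). Buried surface area between disjoint groups is the
two-sided total `SASA(a) + SASA(b) − SASA(a∪b)`; because the literature
uses both the total and the per-surface convention without saying which,
every report carries the two-sided value and its half. Hydrogens have a
tabulated radius but mid-resolution cryo-EM models contain none. Contact
residues use a 4 Å any-atom cutoff; footprints list residues of one group
within 10 Å of a Cα of the other.

## Native-MS arithmetic

All masses are average (not monoisotopic) — appropriate for intact
assemblies in the 10^5–10^6 Da range — computed from an in-package,
versioned residue table (`avg-2021-iupac-v1`) so reported masses cannot
drift with third-party updates. Protein masses support N-terminal Met loss;
ssDNA masses are explicit about 5'/3' hydroxyl vs phosphate termini (a
synthesised oligo is 5'-OH, one HPO₃ = 79.98 Da below the 5'-phosphate
form).

Stoichiometry assignment enumerates every composition within the stated
copy-number ranges and keeps those within the mass tolerance. Ranking puts
first the compositions whose expected mass does **not** exceed the
measurement (beyond a configurable slack, default 0): under native
electrospray conditions residual salt, solvent and metal adducts only add
mass, so measured masses sit systematically above sequence masses and a
candidate hundreds of Da *heavier* than the measurement is physically
implausible even when its |Δ| is numerically smaller. Within each sign
class, candidates are ordered by |Δ|, then by fewer total subunits, then
lexicographically (deterministic parsimony ties). Charge-state
deconvolution assumes consecutive charges: the charge of the top pair is
`round((m₁ − A)/(m₁ − m₂))`, each peak then yields an independent mass
`z(m − A)`, and a relative SD above 10⁻³ of the mass rejects the series;
per-peak masses are returned so single corrupted peaks can be spotted
against the median.

## Crosslink restraints

Crosslink tables (protein, residue, protein, residue, annotation) are
evaluated against a model at a configurable cutoff, default 30 Å — the
conventional Cα–Cα compatibility bound for a DSS-length spacer. Distances
default to Cα–Cα because lysine side chains are commonly unmodelled at
~4 Å resolution; NZ–NZ is selectable and both are worth reporting when the
underlying convention is unknown. In a homo-oligomer a protein name maps to
several chains; the default takes the minimum distance over all allowed
chain assignments, with a fixed-chain mode for reproducing a specific
published panel. A pair touching a residue absent from the model is
`unmapped`, never `violated`: an unbuilt loop is missing evidence, not a
violation.

## Synthetic assemblies

The generator builds ideal N-subunit helices/rings with known rise, twist
and radius; each subunit is a seeded carbon pseudo-atom cloud re-centered
so its COM lies *exactly* on its helix point. Defaults are the study
conditions for an open loader-bound helicase spiral: 6 subunits, rise
4.1 Å, twist 56.4°, COM radius 35 Å (a hexamer of ~250-residue domains
puts domain COMs roughly that far from the ring axis), with planted breach
openings of 15–20 Å and an inter-tier tilt of 15° where those features are
requested. Breaches are planted by translating the subunits past the
breach along the closest-approach line until the minimum atom–atom gap
equals the request (iterated, so the achieved value is exact and recorded
as ground truth). The second tier is first aligned to the first tier's COM
plane, then tilted, so the planted inter-tier angle is exact.

All randomness flows through NumPy PCG64 generators seeded from the
parameter records, and every fixture returns its ground truth alongside,
so tests compare recovered values against emitted truth rather than copied
constants.

What the generator does *not* emulate: real domain shapes and packing
(clouds are isotropic), sequence content, residue-level contacts, map
noise, or partially modelled chains. Passing the recovery tests therefore
demonstrates correctness of the estimators on known geometry, not
robustness to the full messiness of experimental models; the deposited-
model battery (CLI `report`, shipped tier config) exists for that purpose
and requires the coordinate files locally.

## Problem sizes and defaults

Synthetic fixtures use 6 subunits × 40 atoms (240–480 atoms), SASA uses
960 lattice points (1,920 for convergence checks), stoichiometry searches
enumerate 7 × 9 count grids, and charge series use 11 charge states — the
scales of the assemblies and spectra the methods target. The Monte-Carlo
calibration of charge-series inference runs 100 seeds at 0.05 Th m/z noise.

## Known limitations

* The helical-axis fit assumes an approximately *uniform* helix; strongly
  non-uniform staircases are better summarised by the per-step lists than
  the means.
* BSA sidedness and the operational definition of published pitch values
  are genuinely ambiguous; the package reports both candidates in each
  case rather than guessing.
* SASA is O(atoms × lattice points × neighbours) pure NumPy; it is meant
  for tier-scale selections (10³–10⁴ atoms), not proteome-scale batches.
* Cross-species comparisons require an explicit residue-correspondence
  map; no automatic sequence alignment is performed.
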