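# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic study models emulate, and the
limits of what the test suite can show.

## Structures, trajectories, selections

PDB files are parsed through gemmi into a flat atom table (author residue
numbering, Å, B in Å²); a cheap fixed-column validation pass runs first so
malformed coordinate/occupancy/B fields fail with the offending line
number. Alternate locations default to one conformer per atom — highest
occupancy, ties broken alphabetically — because downstream distances must
be single-valued; `keep_alt` accepts `all`, `first`, or a conformer
letter for exact replication of any deposited entry. Structures may lack
hydrogens; every core analysis is defined heavy-atom-only, with hydrogens
used only where explicitly supplied (H-bond angle criterion).

Trajectories are coordinate frames over a fixed topology, read from
multi-model PDB or plain xyz blocks (`N`, comment, `element x y z` × N).
Frame/topology atom-count mismatches and truncated final frames are
errors naming the frame index, never silent drops. An optional
orthorhombic box enables minimum-image distances; the neighbor search
refuses cutoffs above half the smallest box length.

The selection grammar (`chain/resname/resnum/name/element/hetero`,
ranges, `and/or/not`, parentheses) is deliberately small; it covers every
selection the analyses need (e.g. `chain A and resnum 473 and name OH`)
and parse errors carry the character position.

## Superposition and RMSD

Superposition is weighted least squares via SVD with the determinant
correction, so reflections are excluded and the rotation is always
proper. RMSD series use a fit-then-measure convention: each frame is
superposed on the reference over a *fit* selection (typically protein),
then the RMSD of an *analyze* selection (typically a ligand) is taken
without refitting. This reads as "ligand mobility within its site"; both
selections are configurable, and passing the same set gives conventional
fitted RMSD. Published ligand-RMSD distributions rarely state which
convention they used, so both modes are available.

RMSD distributions are histogrammed over [0, max] with 50 bins by
default. The biphasic call — two average positions rather than one —
compares 1- versus 2-component Gaussian mixtures by BIC and requires the
two-component model to win by ≥ 10 (a conventional "very strong
evidence" margin); samples are sorted before the seeded fit so the call
is invariant to frame order. The margin and bin count are parameters, as
visual "biphasic" judgements in the literature correspond to no specific
test.

## Contacts and hydrogen bonds

A contact is a ligand–protein heavy-atom pair within 4.5 Å (default);
it is polar when both atoms are N/O/S. Named distances are minima over
group cross pairs, reported with the achieving atom pair, which is how
crystallographic papers print carboxylate→residue distances. Hydrogen
bonds default to donor–acceptor ≤ 3.5 Å, plus D–H···A ≥ 120° when
hydrogens are present — conventional first-shell values; both are
configurable because published persistence figures rarely state their
criteria, and distance-only versus distance+angle results can be
reported side by side. Persistence is the fraction of frames with at
least one qualifying bond between the selections; it is order-invariant
and monotone under loosening the criteria.

## Pocket volumetrics

Cavity detection is grid-based. A voxel center is small-probe-accessible
when farther than r_vdW + 1.4 Å from every protein atom. Because the
target pockets are partly open to the protein surface, bulk solvent is
defined by a second, larger probe (3.0 Å default): the
large-probe-accessible region flood-filled from the box boundary is
exterior, and only voxels inside the remaining envelope are pocket
candidates. The pocket is the 26-connected candidate component containing
the seed (a ligand selection or point); volume is voxel count × spacing³.
If the component still reaches the grid boundary the region is flagged
open rather than silently truncated; a seed voxel inside the protein, or
stranded in bulk, is an error. Published pocket volumes almost never name
their capping convention — ours is explicit and both probes are sweep
parameters.

Ligand volumes are unions of van-der-Waals spheres (Bondi radii shipped
as the default table; per-atom-name overrides supported) rasterized on a
grid, so overlaps count once. Occupancy rasterizes the ligands on the
cavity's own grid, making fraction × total = occupied exact by
construction. Defaults: 0.5 Å spacing for production, 0.4 Å in tests;
on the analytic hollow-cage fixture the 0.4 Å volume is within ~1% of
the closed form and refining to 0.2 Å moves it by well under 3%.

## Hydration

The hydration number is the count of distinct water molecules whose
oxygen (one per molecule; residue names HOH/WAT/TIP3/SOL) lies within a
cutoff of any solute atom; a water near both carboxylate oxygens counts
once. The default 3.5 Å is the conventional first-shell water–oxygen
bound; since the cutoff behind published per-site averages is usually
unstated, it is a sweep parameter and the count is provably monotone in
it. Occupancy density maps record per-voxel fractions of frames with any
selected atom present (center mode by default, vdW-dilated optional) and
export as OpenDX text; no isosurface threshold is baked in.

## Interaction energies

Energies are intermolecular ligand × environment-group sums of
k_e·q_iq_j/r (k_e = 332.0636 kcal·Å·mol⁻¹·e⁻²) plus 12-6 Lennard-Jones
with Lorentz–Berthelot combining; LJ sizes may be given as σ or R_min/2.
The 12 Å default cutoff is the customary van-der-Waals cutoff; modes are
hard truncation, a CHARMM-style C¹ switching ramp (default on–off window
cutoff−2 → cutoff), or no cutoff. Decomposition over environment groups
(protein / water / ions / other ligands) requires the groups to partition
the non-ligand environment, which makes the complete-system column equal
the row sum exactly, frame by frame — the consistency pattern such tables
should satisfy. Statistics are mean ± sample sd (n−1) over frames, pooled
across trajectories when several are given; Coulomb-only and LJ-only
breakdowns are emitted alongside totals because published tables often do
not say which terms they include. Ewald electrostatics are deliberately
not offered here: a per-group split is only well-defined for pairwise
sums, so decomposition uses cutoff/switched Coulomb even when the
trajectories themselves were generated with mesh Ewald.

## B-factor profiles

Per-residue profiles average member-atom B (backbone N/CA/C/O only in
backbone mode). Cross-crystal comparison requires normalization (overall
B scales differ between crystals): z-score (population sd) or min-max,
both idempotent. Region comparisons report the mean normalized difference
(a − b) over shared residues and call a direction when |Δ| ≥ 0.25
normalized units — an explicit, tunable stand-in for the visual
judgements such comparisons usually rest on. Default region ranges for
the PPARγ ligand-binding domain (H12 466–477, H11–H12 loop 455–465,
H2–H3/β-sheet 264–275 + 338–352, author numbering) are config entries,
since secondary-structure annotations vary between depositions.

## Synthetic study models

The generators produce every input the analyses need, each with exact
ground truth:

- **Hollow cage** — quasi-uniform shell (Fibonacci lattice, seeded random
  global rotation) around a cavity of closed-form volume
  (4/3)π(R − r_atom − r_probe)³; construction fails loudly if the shell
  gap could leak the probe.
- **Binding-site model** — three schematic C9 fatty acids with polar
  partner residues planted at the printed crystal-contact distances
  (2.90/2.92/2.75/3.05 Å at site I, 3.2 Å and 3.87 Å to the shared
  arginine at sites II/III, 3.2 Å to a backbone amide) and hydrophobic
  shells at ~3.9 Å from the tails; the generator audits every planted
  minimum at build time. Site-I B-factors are planted low and
  sites II/III high, mirroring the well-ordered/poorly-ordered contrast.
- **Pocket model** — a cage tuned to a 1300 Å³ accessible cavity with
  three pseudo-ligand spheres (a central sphere solved by root-finding
  plus two disjoint flankers, overlap volumes in closed form) jointly
  filling exactly 52% of it.
- **Hydration frames/trajectories** — exactly n waters inside the shell
  and the rest beyond cutoff + 0.5 Å; trajectory counts follow a planted
  schedule or Poisson(λ) with λ = 1/7/8 for sites I/II/III, the reported
  per-site averages.
- **H-bond trajectories** — donor–acceptor distance d_on in exactly
  round(p·N) frames, d_off otherwise; prefix schedule (bond ruptures
  after the on-block) or random. Study conditions: the C9 and C10 chain
  lengths persist throughout (p = 1.0); the C12 condition ruptures
  mid-run (p = 0.5) — the rupture is reported qualitatively in the
  source material, so the fraction is a documented choice, not a
  reproduced number.
- **Displacement trajectories** — i.i.d. Gaussian per-coordinate
  displacements (E[RMSD²] = 3σ²), optionally two-state for planted
  biphasic distributions.
- **Charge systems** — two-atom closed forms and random 50-atom systems
  (rejection-sampled minimum separation, so no pair sits on the LJ
  singularity) for brute-force oracle checks.
- **B-factor pairs** — identical geometry; one shared baseline profile
  (two crystals of the same protein share their architecture-driven B
  profile) plus small independent per-structure noise, with planted
  region elevations in either structure.

What these models do *not* emulate: force-field-consistent geometry,
correlated protein dynamics, water–water structure, crystal packing, or
experimental B-factor error models. Passing tests therefore demonstrate
that the measurement machinery is correct against analytic and planted
truths — not that the scientific conclusions would re-derive from real
deposited data, which the package consumes but does not bundle. In
particular, the printed contact distances, the 1300 Å³ / 52% pocket
figures and the tri-region B-factor pattern enter the synthetic models as
planted inputs; recovering them validates the pipeline, not the
crystallography.

## Problem sizes

Defaults were chosen so the whole suite and the acceptance script run in
seconds on one core: 100-instance oracle sweeps for neighbor search and
energies, 1000–2000-frame trajectories for sampling-error bounds,
300-frame hydration runs per site, 0.4 Å grids (0.2 Å only in the
convergence check). All sizes are parameters; nothing in the method
limits them.

## Known limitations

- Cavity capping depends on the envelope probe: mouths wider than the
  6 Å probe diameter leak to bulk and raise the open-pocket flag rather
  than producing a silently wrong volume.
- The BIC mixture call can report two components for heavily skewed
  unimodal samples; the Δ ≥ 10 margin suppresses most such calls but is
  a heuristic.
- Energy decomposition is pairwise by design; it will not match
  Ewald-consistent per-group energies for strongly periodic systems.
- mmCIF, symmetry expansion and binary trajectory formats (DCD/XTC) are
  out of scope; text formats keep every fixture bit-checkable.
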