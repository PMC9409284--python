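# Methods

## The system and the questions

Pyrethroid insecticides act on insect voltage-gated sodium channels,
single-chain proteins of four homologous domains whose pore module (PM)
is built from four S5 outer helices, four S6 inner helices and four
re-entrant P-loops, coupled to four voltage-sensing modules (VSMs)
through S4-S5 linker-helices. Two lipid-facing receptor sites are
established: PyR1 in the II/III domain interface and PyR2 in the I/II
interface. The package asks three questions at desk scale: where do
pyrethroid-like ligands bind (docking), what happens to their contacts
when the channel changes gating state (morphing + interaction
fingerprints), and how do catalogued resistance mutations relate to the
two sites (atlas + classification).

## Universal residue labels

Positions are addressed as `<domain><segment><index>` with segment codes
`k` (S4-S5 linker-helix), `o` (S5), `p` (P-loop), `i` (S6): `2k11` is
position 11 of the domain-II linker-helix. The literature doubles these
with house-fly channel numbers (`M918/2k11`). The index origin of each
segment is not derivable from any single sequence, because the scheme is
alignment-based across the P-loop channel family; the package therefore
treats anchors as data (`SegmentAnnotation`, TSV). The shipped housefly
table was solved from the dual labels of the packaged mutation
catalogue, and two segments need split spans with different anchors
(domain-I S6 around position 435, domain-II P-loop around position 983)
because the universal indices skip relative to the housefly sequence.
Loading the atlas re-derives every dual label from the anchors and
aborts on any mismatch, so the convention is self-checking.

## The reduced force field

The energy model is a deliberately small, named, swappable component
(`EnergyModel` + `data/force_field.tsv`), not a calibrated biomolecular
force field:

- United-atom Lennard-Jones on heavy atoms. σ values (2.9–3.5 Å) are
  set to *heavy-atom contact scale* so that pair minima fall at
  3.3–3.9 Å — consistent with the 4 Å geometric contact criterion used
  throughout. ε values 0.08–0.4 kcal/mol.
- Coulomb with distance-dependent dielectric ε(r) = 4r (an implicit
  membrane/protein surrogate), constant 332.0637 kcal·Å/(mol·e²),
  reduced partial charges on polar groups only.
- Hydrogen bonds: a radial 10–12 well (r₀ = 2.9 Å, depth 4 kcal/mol)
  that **replaces** the whole LJ+Coulomb pair for donor–acceptor pairs.
  Only side-chain polar groups carry donor/acceptor flags; helical
  backbone amides are internally satisfied and would otherwise litter
  the receptor surface with spurious wells.
- Halogen bonds: a directional 10–12 well between C–X (X = Cl, Br, I)
  and N/O/S acceptors, r₀ = vdW sum − 0.2 Å, depth 4 kcal/mol, weighted
  by ((1 − cos θ)/2)² so the σ-hole term is maximal at C–X···A = 180°
  and, unlike a hard cutoff, has a restoring gradient at any geometry.
- 3-term cosine torsions on rotatable bonds; harmonic angle terms where
  declared elastic; harmonic positional restraints E = k·|x − x₀|².
- Exclusions: bonded paths 1-2/1-3/1-4 (1-4 interactions are folded into
  the torsion terms). For protein structures, intra-residue pairs and
  all pairs between sequence neighbours within two positions, plus
  backbone–backbone pairs within four positions, are additionally
  excluded: residues and idealized helices are internally rigid in this
  model, so those constant interactions must not generate artificial
  forces from the toy backbone geometry.
- Nonbonded cutoff 8 Å, no switching.

Interaction energies of docked poses are cross terms against a frozen
receptor plus the ligand's internal strain; the receptor self-energy is
excluded by construction.

## Minimization

Degrees of freedom are torsion angles and rigid-body placements
(internal coordinates); bond lengths/angles never change. The local
minimizer is cyclic coordinate descent with a bounded Brent line search
per degree of freedom — slower than gradient methods but exactly
reproducible and robust on cliff-like LJ walls. Monte Carlo minimization
(MCM) perturbs a random subset of the degrees of freedom, re-minimizes
and accepts greedily (Metropolis optional); with a fixed seed the entire
trajectory is bit-reproducible. Line-search brackets double as the
definition of locality: narrow brackets (12°, 0.4 Å) keep a minimization
in its basin, wide ones allow basin hopping.

## Docking protocol

Random starting poses (uniform centroid in a box around the site's
side-chain centroids, uniform orientation and torsions) are refined in
two phases: a cheap single-sweep local minimization of every start
resolves clashes and ranks the ensemble, then full MCM is spent on the
lowest-energy ≥12 poses, where the low-energy structure lives. Both
phases are greedy, so no pose's energy rises. Poses within 5 kcal/mol of
the *apparent* global minimum (the best energy found, never a proven
optimum) form the reported ensemble, and the final pose maximizes the
number of contacted pyrethroid-sensing residues, ties broken by energy —
reflecting that a reduced scoring function cannot rank near-degenerate
poses but mutational data can. Opposite ligand orientations are
annotated by the sign of the ester-axis projection on the pore axis and
never merged.

Problem sizes used by the test suite and the acceptance script: 200
starting poses per run, 10 (tests) or 4 (acceptance script) independent
seeds.

## Targeted state morphing

A gating transition is imposed by driving selected Cα atoms toward
template coordinates through linearly interpolated harmonic restraints
(default 10 steps, k = 10 kcal/mol/Å²), relaxing at each step. The
backbone moves as rigid blocks of three restrained residues — a
generalized-coordinate move set whose joints stay consistent because the
interpolated targets of a rigid-shift transition are themselves
consistent. Relaxation uses **excluded volume plus restraints only**: the
attractive terms are switched off and the vdW term becomes a reduced-core
(82 % σ) WCA repulsion, so a clash-free structure feels no force besides
its restraints. This makes the null morph exact, keeps the
restrained-RMSD decay monotone, and still resists genuinely blocked
paths, which surface as a loud non-convergence flag. Bound ligands are
re-refined against the moved receptor at every step with the full
interaction model, and their energies recorded.

Voltage-sensor deactivation displaces one domain's S4 Cα atoms along the
pore axis (selectivity-filter centroid → gate centroid, i.e.
extracellular → cytoplasmic) by a configurable distance (default 4.5 Å —
an operational value, not a biophysical claim), with the first three
linker residues softly restrained (k/10) to follow.

## Interaction criteria

One configuration block (`navpyr.constants`) holds every geometric
threshold: contacts ≤ 4.0 Å between ligand heavy atoms and residue
side-chain heavy atoms (glycine falls back to Cα; any-atom mode by
flag), hydrogen bonds D···A ≤ 3.5 Å with D–H···A ≥ 120° (H inferred
along D→A when absent, making the distance gate operative for
heavy-atom-only models), halogen bonds X···A ≤ vdW sum + 0.2 Å with
C–X···A ≥ 140°, salt bridges ≤ 4.0 Å, "weakened" = min distance grown by
more than 0.5 Å between states. All distance gates are
boundary-inclusive. Missing side-chain atoms make the salt-bridge
detector return indeterminate, never false.

## The synthetic fixtures

The mini-channel is a test instrument, not a channel model: four domains
of ideal poly-alanine helices (1.5 Å rise, 100°/residue) — S5 at radius
26 Å, S6 at 7.5 Å with the gate half at 11 Å when open, an 8-residue
P-loop hairpin, a horizontal S4-S5 linker-helix at 19.5 Å, optional S4
helices at 30 Å carrying three arginines each. The two gating states
share the S5/P-loop/S4 coordinates exactly and differ only by a rigid
radial shift of the S6 cytoplasmic halves (3.5 Å by default) and a 1 Å
vertical linker displacement, so P1 superposition, morph targets and
contact differences all have closed-form ground truth. A small set of
planted side chains sits exactly where the detectors need partners: a
pocket-bottom methionine (halogen-bond sulfur), a cysteine and a
threonine on S5, a phenylalanine on the neighbouring S6 that retreats
with the gate, a Ser–Asn intersegment hydrogen-bond pair, and an
Asp–Arg salt bridge on S4. Sensing side chains are aimed by two-sphere
solves (tip at its side chain's reach from Cα and at vdW standoff from
the planned ligand anchor), so the planted contact set is realized by
construction and verified by the brute-force contact oracle at
generation time.

Toy ligands are built from SMILES with RDKit (deterministic ETKDG
embedding): the Type-II ligand has an ester core, an α-cyano (nitrile)
group and two bromine σ-hole donors; the Type-I ligand has chlorines and
no nitrile. The planted docking truth tilts the ligand through the
interface crevice — halogens deep at the methionine, nitrile up at the
threonine — relaxes it to a genuine local minimum, and retries with
smaller torsional jitter if a seed's conformer cannot realize the
planted contacts.

What passing these tests does *not* show: the fixtures have no membrane,
no water, no realistic sequence or helix packing, and the reduced force
field has no calibrated accuracy — agreement here demonstrates that the
pipeline's logic (labeling, superposition, sampling, filtering,
selection, morphing, detection, classification) is correct, not that its
predictions on real channels would be.

## Known limitations

- Pose-level docking recovery is limited by the model's pose
  specificity: the planted interface crevice supports a shelf of
  near-degenerate poses (within ~1 kcal/mol over several Å), so
  multi-start docking reliably recovers the pocket and its sensing
  contacts but not always the exact planted coordinates. This mirrors
  the reason the selection step uses mutational contacts rather than raw
  energy in the first place.
- Entropy, explicit solvent and lipid are ignored; energies are rough
  enthalpy surrogates.
- The morph path is an in silico transformation with no claim of
  physicality and no free-energy profile.
- The atlas covers the four transcribed tables only; species strings are
  verbatim, and components of combination rows are linked records.
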