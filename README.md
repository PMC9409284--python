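# navpyr

Structural modelling of pyrethroid insecticides bound to insect
voltage-gated sodium channels, at desk scale.

Pyrethroids kill insects by locking the sodium channel open: they bind
two lipid-facing receptor sites on the pore module — **PyR1** at the
domain II/III interface (helices IIS4-S5, IIS5, IIIS6) and **PyR2** at
the I/II interface — and resist the conformational transitions that
close or inactivate the pore. Naturally occurring *knockdown resistance*
(kdr) mutations cluster in and around these sites. `navpyr` implements
the computational workflow used to study this system:

- **Universal residue labels** for P-loop channels (`M918/2k11` = the
  housefly methionine 918, domain II S4-S5 linker-helix position 11),
  with parsing, formatting, and mapping between native numbering schemes
  (`navpyr.channel_io`).
- **P1-helix superposition** of channel models in different gating
  states (SVD Kabsch with reflection correction, `navpyr.geometry`).
- A **reduced molecular-mechanics model** — united-atom Lennard-Jones,
  distance-dependent dielectric ε(r) = 4r, 10–12 hydrogen-bond wells and
  a directional σ-hole halogen-bond term — with **Monte Carlo energy
  minimization in internal coordinates** (`navpyr.energetics`).
- **Multi-start docking**: thousands of random starting poses, MCM
  refinement, an energy-window filter above the apparent global minimum,
  and selection of the pose contacting the most experimentally known
  pyrethroid-sensing residues (`navpyr.docking`).
- **Targeted state morphing**: stepwise harmonic-restraint driving of
  selected Cα atoms toward template positions (pore opening and
  re-inactivation) and cytoplasmic displacement of S4 voltage sensors,
  with bound ligands carried along (`navpyr.state_morph`).
- **Interaction fingerprints**: 4 Å side-chain contacts, hydrogen bonds
  (≤ 3.5 Å, ≥ 120°), halogen bonds (vdW sum + 0.2 Å, ≥ 140°), salt
  bridges (≤ 4 Å) and contact gain/loss between states
  (`navpyr.interactions`).
- A packaged, machine-readable **kdr mutation atlas** — every catalogued
  resistance mutation and engineered substitution with housefly
  numbering, universal label and PyR1/PyR2/beyond site class
  (`navpyr.atlas`).
- A **synthetic-data module** generating a four-domain pseudo-symmetric
  toy channel in two gating states, toy Type-I/Type-II pyrethroid-like
  ligands, and planted docking ground truth, so every pipeline stage is
  testable without structure prediction or downloads
  (`navpyr.synthetic`).

## Worked example

```python
>>> from navpyr.channel_io import parse_label
>>> from navpyr.atlas import classify_site
>>> label, native = parse_label("M918/2k11")
>>> native.resnum, str(label)
(918, 'M2k11')
>>> classify_site(label)          # super-kdr methionine, IIS4-S5 linker
'PyR1'
>>> classify_site(parse_label("L1014/2i16")[0])   # classic kdr leucine
'PyR2'
```

Docking a toy Type-II ligand into the planted pocket of the synthetic
channel and watching the state dependence:

```python
>>> from navpyr.synthetic import make_mini_channel, make_toy_ligand, \
...     make_docking_truth, sensing_labels
>>> from navpyr.interactions import ligand_contacts
>>> open_ch, inact_ch, annotation = make_mini_channel()
>>> ligand = make_toy_ligand("type2")
>>> truth = make_docking_truth(open_ch, ligand, seed=7, inactivated=inact_ch)
>>> sorted(str(l) for l in truth.sensing)
['2k6', '2o3', '2o6', '3i8']
>>> [str(l) for l in truth.lost_on_inactivation]
['2k6', '3i8']
```

The four planted sensing residues (a linker methionine, two outer-helix
polar residues and an inner-helix phenylalanine, mirroring the
composition of PyR1) are all within 4 Å of the placed ligand in the open
state; closing the gate retracts the S6 phenylalanine and the linker
shift pulls the methionine away — the qualitative signature of
state-dependent pyrethroid binding.

A command-line interface mirrors the library
(`navpyr simulate|label|superpose|dock|morph|classify|report`).

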