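"""Targeted in silico state transformations.

A gating transition is imposed on a channel model by stepwise moving
selected Calpha atoms toward template positions: at every step the
restraint targets are linearly interpolated between the start and the
template, harmonic restraints pull the Calphas there, and the structure
is energy-relaxed under those restraints.  The same machinery deactivates
a voltage-sensing module by displacing its S4 helix along the pore axis
toward the cytoplasm, with the N-end of the coupled S4-S5 linker softly
restrained so it can follow.

The path is an in silico transformation, not dynamics: no claim is made
that intermediate structures are physically visited, and no free-energy
profile is produced.  Backbone relaxation treats short contiguous blocks
of restrained residues as rigid bodies (a generalized-coordinate move
set); covalent continuity across block joints is maintained by the
consistency of the interpolated targets, which is exact for the
rigid-shift transitions modeled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channel_io import ChannelStructure
from .energetics import (
    Conformation,
    EnergyEvaluator,
    EnergyModel,
    MCMSchedule,
    RigidBodyDOF,
    Topology,
    local_minimize,
    with_restraints,
)
from .geometry import AtomSelection, paired_indices

__all__ = [
    "MorphSchedule",
    "MorphTrajectory",
    "build_targets",
    "morph",
    "deactivate_vsm",
    "pore_axis",
]


class MorphError(ValueError):
    pass


@dataclass
class MorphSchedule:
    """Stepwise-restrained transformation parameters."""

    n_steps: int = 10
    k_restraint: float = 10.0  # kcal/mol/A^2 on restrained Calphas
    tolerance: float = 0.5  # A, final restrained-Calpha RMSD to target
    block_size: int = 3  # residues per rigid backbone block
    per_step: MCMSchedule = field(
        default_factory=lambda: MCMSchedule(
            max_steps=0, tolerance=0.05, max_sweeps=4, ls_maxiter=10
        )
    )

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.k_restraint <= 0:
            raise ValueError("restraint constant must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class MorphTrajectory:
    """Structures and diagnostics along a stepwise transformation."""

    structures: list[ChannelStructure]
    rmsd_to_target: list[float]
    energies: list[float]
    ligand_energies: list[list[float]]
    converged: bool
    message: str = ""

    def __len__(self) -> int:
        return len(self.structures)


def build_targets(
    source: ChannelStructure,
    template: ChannelStructure,
    selection: AtomSelection,
) -> dict[int, np.ndarray]:
    """Template coordinates for paired selected atoms of `source`.

    The template must already be superposed onto the source frame (e.g.
    on the shared P1 Calphas); pairing is by universal label + atom name.
    """
    ia, ib, unpaired = paired_indices(source, template, selection)
    if len(ia) == 0:
        raise MorphError("selection pairs no atoms between source and template")
    if unpaired:
        import logging

        logging.getLogger(__name__).info(
            "build_targets: %d selected atoms had no pair", unpaired
        )
    return {int(i): template.coords[j].copy() for i, j in zip(ia, ib)}


def _restrained_blocks(
    structure: ChannelStructure, restrained_atoms, block_size: int
) -> list[np.ndarray]:
    """Rigid backbone blocks: contiguous restrained residues, chopped to
    `block_size`, each block carrying all atoms of its residues."""
    res_ids = sorted({int(structure.atom_res[i]) for i in restrained_atoms})
    runs: list[list[int]] = []
    for ri in res_ids:
        if runs and ri == runs[-1][-1] + 1:
            runs[-1].append(ri)
        else:
            runs.append([ri])
    blocks = []
    for run in runs:
        for off in range(0, len(run), block_size):
            chunk = run[off : off + block_size]
            atoms = np.concatenate(
                [structure.atoms_of_residue(ri) for ri in chunk]
            )
            blocks.append(np.asarray(sorted(atoms), dtype=int))
    return blocks


def _selected_rmsd(coords: np.ndarray, targets: dict[int, np.ndarray]) -> float:
    idx = np.array(sorted(targets), dtype=int)
    t = np.array([targets[i] for i in idx])
    d = coords[idx] - t
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def morph(
    structure: ChannelStructure,
    targets: dict[int, np.ndarray],
    schedule: MorphSchedule | None = None,
    model: EnergyModel | None = None,
    topology: Topology | None = None,
    ligands: list | None = None,
    soft_targets: dict[int, np.ndarray] | None = None,
) -> MorphTrajectory:
    """Stepwise restrained transformation toward `targets`.

    At step t (1..n) the restraint target of each atom is
    ``start + (t/n) * (target - start)``; the structure is relaxed under
    those restraints; bound ligand conformations (from
    :func:`navpyr.docking.ligand_conformation`) are re-refined at every
    step and their interaction energies recorded.  Non-convergence (final
    restrained-atom RMSD above tolerance) is flagged, never silent.
    """
    from .proteins import protein_topology

    schedule = schedule or MorphSchedule()
    model = model or EnergyModel.default()
    topology = topology or protein_topology(structure)
    if not targets:
        raise MorphError("no morph targets")

    work = structure.copy()
    start = {i: work.coords[i].copy() for i in targets}
    soft_targets = soft_targets or {}
    soft_start = {i: work.coords[i].copy() for i in soft_targets}

    restrained = list(targets) + list(soft_targets)
    blocks = _restrained_blocks(work, restrained, schedule.block_size)
    block_atoms = np.concatenate(blocks) if blocks else np.array([], int)
    frozen = np.ones(work.n_atoms, dtype=bool)
    frozen[block_atoms] = False

    lig_confs = list(ligands or [])

    structures = [work.copy()]
    rmsds = [_selected_rmsd(work.coords, targets)]
    energies = []
    lig_energies: list[list[float]] = [[]]

    n = schedule.n_steps
    for t in range(1, n + 1):
        frac = t / n
        step_t = {
            i: start[i] + frac * (targets[i] - start[i]) for i in targets
        }
        soft_t = {
            i: soft_start[i] + frac * (soft_targets[i] - soft_start[i])
            for i in soft_targets
        }
        # the receptor relaxes under excluded volume + restraints only;
        # attractive terms would drag blocks off a hand-built fixture
        from dataclasses import replace as _replace

        m = with_restraints(
            _replace(model, repulsive_only=True), step_t, schedule.k_restraint
        )
        if soft_t:
            m = with_restraints(m, soft_t, schedule.k_restraint / 10.0)
        evaluator = EnergyEvaluator(
            topology, m, pair_reference=work.coords, pair_padding=4.0,
            frozen=frozen,
        )
        conf = Conformation(
            work.coords,
            rigid_dofs=[
                RigidBodyDOF(b, step_trans=0.8, step_rot=0.15) for b in blocks
            ],
        )
        e0 = evaluator.total(conf.coords())
        if not np.isfinite(e0):
            raise MorphError(f"non-finite energy at morph step {t}")
        sched = schedule.per_step
        relaxed = local_minimize(
            conf, evaluator,
            tolerance=sched.tolerance,
            max_sweeps=sched.max_sweeps,
            ls_maxiter=sched.ls_maxiter,
        )
        work.coords = relaxed.coords()
        energies.append(relaxed.min_info["energy"])
        step_lig = []
        for lc in lig_confs:
            from .docking import InteractionEvaluator, _ScorerAdapter

            scorer = InteractionEvaluator(
                work, topology, lc["ligand"], model, lc["site"]
            )
            conf_l = Conformation(
                lc["conformation"].coords(),
                torsion_dofs=lc["conformation"].torsion_dofs,
                rigid_dofs=lc["conformation"].rigid_dofs,
            )
            refined = local_minimize(
                conf_l, _ScorerAdapter(scorer),
                tolerance=sched.tolerance, max_sweeps=2, ls_maxiter=8,
            )
            lc["conformation"] = refined
            step_lig.append(refined.min_info["energy"])
        lig_energies.append(step_lig)
        structures.append(work.copy())
        rmsds.append(_selected_rmsd(work.coords, targets))

    final_rmsd = rmsds[-1]
    converged = final_rmsd <= schedule.tolerance
    msg = (
        ""
        if converged
        else f"non-converged: final restrained-atom RMSD {final_rmsd:.2f} A "
        f"exceeds tolerance {schedule.tolerance:.2f} A"
    )
    return MorphTrajectory(
        structures=structures,
        rmsd_to_target=rmsds,
        energies=[float("nan")] + energies,
        ligand_energies=lig_energies,
        converged=converged,
        message=msg,
    )


def pore_axis(structure: ChannelStructure) -> tuple[np.ndarray, np.ndarray]:
    """(origin, unit vector) of the pore axis, oriented extracellular ->
    cytoplasmic (selectivity filter -> gate)."""
    p_ca, gate_ca = [], []
    seg_max: dict[tuple[int, str], int] = {}
    for res in structure.residues:
        if res.segment == "i" and res.seg_index is not None:
            key = (res.domain, "i")
            seg_max[key] = max(seg_max.get(key, 0), res.seg_index)
    for ri, res in enumerate(structure.residues):
        ca = structure.atom_index(ri, "CA")
        if ca is None:
            continue
        if res.segment == "p":
            p_ca.append(structure.coords[ca])
        elif res.segment == "i" and res.seg_index is not None:
            if res.seg_index >= seg_max[(res.domain, "i")] - 1:
                gate_ca.append(structure.coords[ca])
    if not p_ca or not gate_ca:
        raise MorphError("pore axis needs annotated p and i segments")
    filt = np.mean(p_ca, axis=0)
    gate = np.mean(gate_ca, axis=0)
    v = gate - filt
    return filt, v / np.linalg.norm(v)


def deactivate_vsm(
    structure: ChannelStructure,
    domain: int,
    displacement: float = 4.5,
    schedule: MorphSchedule | None = None,
    model: EnergyModel | None = None,
    topology: Topology | None = None,
) -> MorphTrajectory:
    """Shift one domain's S4 helix toward the cytoplasm (resting state).

    S4 Calpha targets are displaced by `displacement` A along the pore
    axis toward the cytoplasmic side; the first three residues of the
    same domain's S4-S5 linker are softly restrained (k/10) to follow,
    as the linker N-end is covalently continuous with S4.
    """
    if domain not in (1, 2, 3, 4):
        raise MorphError(f"domain must be 1-4, got {domain}")
    s4 = [
        ri
        for ri, r in enumerate(structure.residues)
        if r.domain == domain and r.segment == "s4"
    ]
    if not s4:
        raise MorphError(f"domain {domain} has no annotated S4 segment")
    _, axis = pore_axis(structure)
    shift = displacement * axis  # axis already points cytoplasmic
    targets = {}
    for ri in s4:
        ca = structure.atom_index(ri, "CA")
        if ca is not None:
            targets[ca] = structure.coords[ca] + shift
    soft = {}
    linker = sorted(
        (r.seg_index, ri)
        for ri, r in enumerate(structure.residues)
        if r.domain == domain and r.segment == "k"
    )[:3]
    for _, ri in linker:
        ca = structure.atom_index(ri, "CA")
        if ca is not None:
            soft[ca] = structure.coords[ca] + shift
    if displacement == 0:
        targets = {i: structure.coords[i].copy() for i in targets}
        soft = {i: structure.coords[i].copy() for i in soft}
    return morph(
        structure, targets, schedule=schedule, model=model, topology=topology,
        soft_targets=soft,
    )
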