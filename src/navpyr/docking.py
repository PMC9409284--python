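"""Multi-start ligand docking with ensemble filtering and contact-driven
pose selection.

The protocol: generate many random starting poses of the ligand inside a
box around the binding site, Monte-Carlo-minimize each against the rigid
(or side-chain-mobile) receptor, keep the poses whose ligand-channel
interaction energy lies within a window above the apparent global
minimum — i.e. the best energy *found*, not a proven optimum — and, from
that low-energy ensemble, select the pose that touches the largest
number of experimentally known sensing residues.  Selection by contacts
rather than raw energy reflects that reduced scoring functions cannot
reliably rank poses a few kcal/mol apart, while mutational data can.

Reported pose energies are ligand-channel interaction energies plus the
ligand's own internal strain; the frozen receptor's self-energy is
excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .channel_io import ChannelStructure, UniversalLabel
from .energetics import (
    Conformation,
    EnergyEvaluator,
    EnergyModel,
    MCMSchedule,
    RigidBodyDOF,
    Topology,
    local_minimize,
)
from .synthetic import ToyLigand

__all__ = [
    "SiteDefinition",
    "DockingConfig",
    "Pose",
    "PoseEnsemble",
    "InteractionEvaluator",
    "random_start_poses",
    "refine_poses",
    "filter_window",
    "select_by_sensing_contacts",
]


class DockingError(ValueError):
    pass


@dataclass(frozen=True)
class SiteDefinition:
    """A named binding site: lining residues plus a sampling box."""

    name: str
    residues: tuple[UniversalLabel, ...]
    center: np.ndarray
    half_extents: np.ndarray

    @classmethod
    def from_labels(
        cls,
        receptor: ChannelStructure,
        labels,
        name: str = "custom",
        margin: float = 2.0,
    ) -> "SiteDefinition":
        """Box = bounding box of the residues' side-chain centroids + margin."""
        cents = []
        labs = []
        for lab in labels:
            ri = receptor.residue_by_label(lab)
            if ri is None:
                raise DockingError(f"site residue {lab} absent from receptor")
            idx = receptor.side_chain_atoms(ri)
            cents.append(receptor.coords[idx].mean(axis=0))
            labs.append(lab.bare())
        cents = np.asarray(cents)
        lo, hi = cents.min(axis=0), cents.max(axis=0)
        center = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo) + margin
        return cls(name=name, residues=tuple(labs), center=center, half_extents=half)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return np.all(
            np.abs(np.asarray(points) - self.center) <= self.half_extents + 1e-9,
            axis=-1,
        )


@dataclass
class DockingConfig:
    """Multi-start docking parameters (defaults follow the protocol)."""

    n_starts: int = 2000
    energy_window: float = 5.0  # kcal/mol above the apparent global minimum
    contact_cutoff: float = 4.0  # A, sensing-residue contact distance
    seed: int = 0
    schedule: MCMSchedule = field(
        default_factory=lambda: MCMSchedule(
            max_steps=2, tolerance=0.05, max_sweeps=2, ls_maxiter=8
        )
    )

    def __post_init__(self) -> None:
        if self.n_starts < 0:
            raise ValueError("n_starts must be >= 0")
        if self.energy_window < 0:
            raise ValueError("energy window must be >= 0")
        if self.contact_cutoff <= 0:
            raise ValueError("contact cutoff must be > 0")


@dataclass
class Pose:
    """One ligand placement: conformation, coordinates and energy."""

    conformation: Conformation
    coords: np.ndarray
    energy: float
    orientation: int = 0  # sign of ester-axis projection on the pore axis
    contact_count: int | None = None


@dataclass
class PoseEnsemble:
    """Poses sorted by interaction energy (ascending)."""

    poses: list[Pose]
    ligand_kind: str = "ligand"

    def __post_init__(self) -> None:
        self.sort()

    def sort(self) -> None:
        self.poses.sort(key=lambda p: p.energy)

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    def __getitem__(self, i) -> Pose:
        return self.poses[i]

    @property
    def energies(self) -> np.ndarray:
        return np.array([p.energy for p in self.poses])


class InteractionEvaluator:
    """Fast ligand-in-pocket energy: cross terms against a frozen receptor
    subset plus the ligand's internal energy.

    Receptor atoms farther than box + margin from the site never see the
    ligand and are dropped once at construction.
    """

    def __init__(
        self,
        receptor: ChannelStructure,
        receptor_topology: Topology,
        ligand: ToyLigand,
        model: EnergyModel,
        site: SiteDefinition,
        margin: float = 12.0,
    ):
        self.model = model
        keep = np.nonzero(
            np.all(
                np.abs(receptor.coords - site.center) <= site.half_extents + margin,
                axis=1,
            )
        )[0]
        self.pocket_indices = keep
        self.rx = receptor.coords[keep]
        table = model.table
        r_eps, r_sig, r_q = (np.empty(len(keep)) for _ in range(3))
        for n, i in enumerate(keep):
            r_eps[n], r_sig[n], r_q[n] = table.lookup(receptor_topology.types[i])
        l_eps, l_sig, l_q = (np.empty(ligand.n_atoms) for _ in range(3))
        for i, t in enumerate(ligand.topology.types):
            l_eps[i], l_sig[i], l_q[i] = table.lookup(t)
        # (n_pocket, n_ligand) parameter matrices
        self.eps = np.sqrt(np.outer(r_eps, l_eps))
        self.sig = 0.5 * (r_sig[:, None] + l_sig[None, :])
        self.qq = np.outer(r_q, l_q)
        # receptor-donor x ligand-acceptor pairs use the 10-12 term
        keep_set = {int(v): n for n, v in enumerate(keep)}
        self.hb_mask = np.zeros(self.eps.shape, dtype=bool)
        for d in receptor_topology.donors:
            if d in keep_set:
                for a in ligand.topology.acceptors:
                    self.hb_mask[keep_set[d], a] = True
        # receptor acceptors for ligand halogen donors
        self.r_acceptors = np.array(
            [keep_set[a] for a in receptor_topology.acceptors if a in keep_set],
            dtype=int,
        )
        self.xb = list(ligand.topology.halogen_donors)
        from .constants import VDW_RADII, XBOND_SLACK

        self.xb_r0 = np.array(
            [
                [
                    VDW_RADII[ligand.topology.elements[x].upper()]
                    + VDW_RADII[receptor.elements[keep[n]].upper()]
                    - XBOND_SLACK
                    for n in self.r_acceptors
                ]
                for c, x in self.xb
            ]
        ).reshape(len(self.xb), -1)
        self.internal = EnergyEvaluator(ligand.topology, model)
        self.cutoff2 = model.cutoff**2

    def cross_terms(self, lig_coords: np.ndarray) -> dict[str, float]:
        diff = self.rx[:, None, :] - lig_coords[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", diff, diff)
        near = r2 < self.cutoff2
        lj = near & ~self.hb_mask
        sr6 = (self.sig[lj] ** 2 / r2[lj]) ** 3
        vdw = float(np.sum(4.0 * self.eps[lj] * (sr6 * sr6 - sr6)))
        r = np.sqrt(r2[lj])
        from .constants import COULOMB_K

        coul = float(
            np.sum(COULOMB_K * self.qq[lj] / self.model.dielectric_factor(r))
        )
        hb = near & self.hb_mask
        hbond = 0.0
        if hb.any():
            x = self.model.hbond_r0 / np.sqrt(r2[hb])
            hbond = float(
                np.sum(self.model.hbond_emin * (5.0 * x**12 - 6.0 * x**10))
            )
        xbond = 0.0
        if self.xb and len(self.r_acceptors):
            acc = self.rx[self.r_acceptors]  # (m, 3)
            for row, (c, x_i) in enumerate(self.xb):
                rv = acc - lig_coords[x_i]
                rr = np.sqrt(np.einsum("ij,ij->i", rv, rv))
                near = (rr > 0.5) & (rr * rr < self.cutoff2)
                if not near.any():
                    continue
                cv = lig_coords[c] - lig_coords[x_i]
                cosang = (rv[near] @ cv) / (np.linalg.norm(cv) * rr[near])
                w = ((1.0 - cosang) / 2.0) ** 2
                t = self.xb_r0[row, near] / rr[near]
                xbond += float(
                    np.sum(
                        self.model.xbond_emin * (5.0 * t**12 - 6.0 * t**10) * w
                    )
                )
        return {"vdw": vdw, "coulomb": coul, "hbond": hbond, "xbond": float(xbond)}

    def energy(self, lig_coords: np.ndarray) -> float:
        cross = self.cross_terms(lig_coords)
        return float(sum(cross.values()) + self.internal.total(lig_coords))


class _ScorerAdapter:
    """Presents InteractionEvaluator under the EnergyEvaluator interface."""

    def __init__(self, scorer: InteractionEvaluator):
        self.scorer = scorer

    def total(self, coords: np.ndarray) -> float:
        return self.scorer.energy(coords)

    def energy(self, coords: np.ndarray) -> dict[str, float]:
        cross = self.scorer.cross_terms(coords)
        out = dict(cross)
        out["internal"] = self.scorer.internal.total(coords)
        out["total"] = float(sum(cross.values()) + out["internal"])
        return out


def ligand_conformation(ligand: ToyLigand) -> Conformation:
    """All-DOF conformation of a ligand: torsions + one rigid body."""
    return Conformation(
        ligand.coords,
        torsion_dofs=list(ligand.torsions),
        rigid_dofs=[RigidBodyDOF(np.arange(ligand.n_atoms))],
    )


def pose_orientation(
    coords: np.ndarray, axis_atoms: tuple[int, int], pore_axis: np.ndarray
) -> int:
    """Sign of the ester-axis projection on the pore axis (+1/-1).

    Distinguishes the two opposite binding orientations multi-start
    docking typically finds; families are reported, never merged.
    """
    v = coords[axis_atoms[1]] - coords[axis_atoms[0]]
    s = float(np.dot(v, pore_axis))
    return 1 if s >= 0 else -1


def random_start_poses(
    ligand: ToyLigand,
    site: SiteDefinition,
    config: DockingConfig,
    scorer: InteractionEvaluator | None = None,
    pore_axis: np.ndarray = (0.0, 0.0, -1.0),
) -> PoseEnsemble:
    """Uniform random starting poses: centroid in the box, uniform
    orientation, uniform torsions; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    if 2 * float(np.min(site.half_extents)) < _ligand_diameter(ligand) / 2:
        import warnings

        warnings.warn("ligand is large relative to the sampling box")
    poses = []
    axis = np.asarray(pore_axis, float)
    for _ in range(config.n_starts):
        conf = ligand_conformation(ligand)
        x = conf.get_dof()
        nt = len(conf.torsion_values)
        x[:nt] = rng.uniform(-180.0, 180.0, size=nt)
        quat = rng.normal(size=4)
        rot = Rotation.from_quat(quat / np.linalg.norm(quat))
        x[nt + 3 : nt + 6] = rot.as_rotvec()
        conf.set_dof(x)
        coords = conf.coords()
        target = site.center + rng.uniform(-1.0, 1.0, size=3) * site.half_extents
        x[nt : nt + 3] = target - coords.mean(axis=0)
        conf.set_dof(x)
        coords = conf.coords()
        e = scorer.energy(coords) if scorer is not None else np.inf
        poses.append(
            Pose(
                conformation=conf,
                coords=coords,
                energy=float(e),
                orientation=pose_orientation(coords, ligand.axis_atoms, axis),
            )
        )
    return PoseEnsemble(poses, ligand_kind=ligand.kind)


def _ligand_diameter(ligand: ToyLigand) -> float:
    d = ligand.coords[:, None, :] - ligand.coords[None, :, :]
    return float(np.sqrt((d * d).sum(-1)).max())


def refine_poses(
    ensemble: PoseEnsemble,
    scorer: InteractionEvaluator,
    schedule: MCMSchedule | None = None,
    ligand: ToyLigand | None = None,
    pore_axis: np.ndarray = (0.0, 0.0, -1.0),
    fine_fraction: float = 0.15,
    min_fine: int = 12,
) -> PoseEnsemble:
    """Refine every pose; energies never increase; re-sorted.

    Refinement is two-phase: a cheap local minimization of every start
    resolves clashes and ranks the ensemble, then full Monte Carlo
    minimization is spent on the best ``max(min_fine, fine_fraction*N)``
    poses, where the low-energy structure actually lives.  Both phases
    are greedy, so no pose's energy ever rises.
    """
    from .energetics import local_minimize, mc_minimize

    schedule = schedule or MCMSchedule(
        max_steps=2, tolerance=0.05, max_sweeps=2, ls_maxiter=8
    )
    adapter = _ScorerAdapter(scorer)
    axis = np.asarray(pore_axis, float)

    def finish(pose: Pose, conf, n: int) -> Pose:
        coords = conf.coords()
        e = scorer.energy(coords)
        if e > pose.energy + 1e-9:  # greedy refinement cannot go uphill
            conf, coords, e = pose.conformation, pose.coords, pose.energy
        return Pose(
            conformation=conf,
            coords=coords,
            energy=float(e),
            orientation=pose_orientation(
                coords, ligand.axis_atoms if ligand else (0, len(coords) - 1),
                axis,
            ),
        )

    coarse: list[Pose] = []
    for n, pose in enumerate(ensemble):
        try:
            conf = local_minimize(
                pose.conformation, adapter,
                tolerance=0.5, max_sweeps=1, ls_maxiter=5,
            )
        except Exception as exc:
            raise DockingError(f"refinement failed for pose {n}: {exc}") from exc
        coarse.append(finish(pose, conf, n))
    coarse.sort(key=lambda p: p.energy)

    n_fine = min(len(coarse), max(min_fine, int(fine_fraction * len(coarse))))
    refined: list[Pose] = []
    for n, pose in enumerate(coarse):
        if n < n_fine:
            sched = replace(schedule, seed=schedule.seed + 7919 * n)
            try:
                best, _ = mc_minimize(pose.conformation, adapter, sched)
            except Exception as exc:
                raise DockingError(
                    f"refinement failed for pose {n}: {exc}"
                ) from exc
            refined.append(finish(pose, best, n))
        else:
            refined.append(pose)
    return PoseEnsemble(refined, ligand_kind=ensemble.ligand_kind)


def filter_window(ensemble: PoseEnsemble, window: float) -> PoseEnsemble:
    """Keep poses with E <= E_min + window (inclusive).

    E_min is the ensemble minimum — the *apparent* global energy minimum,
    i.e. the best energy found by the sampling, not a converged optimum.
    """
    if len(ensemble) == 0:
        return PoseEnsemble([], ligand_kind=ensemble.ligand_kind)
    e_min = ensemble.energies.min()
    kept = [p for p in ensemble if p.energy <= e_min + window]
    return PoseEnsemble(kept, ligand_kind=ensemble.ligand_kind)


def count_sensing_contacts(
    receptor: ChannelStructure,
    pose_coords: np.ndarray,
    sensing: set,
    cutoff: float,
) -> int:
    """Number of sensing residues with a side-chain heavy atom within
    cutoff of any ligand heavy atom (glycine: Calpha)."""
    n = 0
    for lab in sensing:
        ri = receptor.residue_by_label(lab)
        if ri is None:
            continue
        idx = receptor.side_chain_atoms(ri)
        if len(idx) == 0:
            continue
        d = np.linalg.norm(
            receptor.coords[idx][:, None, :] - pose_coords[None, :, :], axis=2
        )
        if d.min() <= cutoff:
            n += 1
    return n


def select_by_sensing_contacts(
    ensemble: PoseEnsemble,
    sensing,
    receptor: ChannelStructure,
    cutoff: float = 4.0,
) -> tuple[Pose, int]:
    """The pose contacting the most sensing residues.

    Ties break by lower interaction energy, then by ensemble order.  An
    empty sensing set degenerates to the lowest-energy pose.
    """
    if len(ensemble) == 0:
        raise DockingError("cannot select from an empty ensemble")
    sensing = {lab.bare() if hasattr(lab, "bare") else lab for lab in sensing}
    best_pose, best_key = None, None
    for order, pose in enumerate(ensemble):
        count = count_sensing_contacts(receptor, pose.coords, sensing, cutoff)
        key = (-count, pose.energy, order)
        if best_key is None or key < best_key:
            best_pose, best_key = replace(pose, contact_count=count), key
    return best_pose, -best_key[0]
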