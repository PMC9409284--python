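"""A reduced molecular-mechanics model and Monte Carlo minimization in
internal coordinates.

The energy model is deliberately small: united-atom Lennard-Jones,
Coulomb with a distance-dependent dielectric eps(r) = 4r (a common
implicit-membrane surrogate), 3-term cosine torsions, a radial 10-12
hydrogen-bond term, an explicitly directional halogen-bond term (so that
Br...S contacts are energetically favorable, not merely geometrically
counted), harmonic angle terms where declared elastic, and harmonic
positional restraints.  Degrees of freedom are torsion angles and
rigid-body placements of mobile units; bond lengths and angles are fixed
unless declared elastic, so every move stays on the manifold of valid
covalent geometry.

Minimization is cyclic coordinate descent with a bounded line search per
degree of freedom — simple and exactly reproducible.  Monte Carlo
minimization (MCM) perturbs random subsets of the degrees of freedom,
re-minimizes, and accepts greedily (or by Metropolis), which is the
standard way to explore rugged torsional landscapes when gradients of the
full system are unaffordable or unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .constants import COULOMB_K, VDW_RADII, XBOND_SLACK

__all__ = [
    "ParameterizationError",
    "AtomTypeTable",
    "Topology",
    "EnergyModel",
    "EnergyEvaluator",
    "TorsionDOF",
    "RigidBodyDOF",
    "Conformation",
    "MCMSchedule",
    "energy",
    "local_minimize",
    "mc_minimize",
    "with_restraints",
]


class ParameterizationError(KeyError):
    """An atom lacks force-field parameters."""


class AtomTypeTable:
    """Per-type Lennard-Jones parameters and partial charges."""

    def __init__(self, rows: dict[str, tuple[float, float, float, str]]):
        self.rows = rows  # type -> (eps, sigma, charge, element)

    @classmethod
    def load(cls, path=None) -> "AtomTypeTable":
        if path is None:
            from importlib.resources import files

            path = files("navpyr.data") / "force_field.tsv"
        rows = {}
        with open(str(path)) as fh:
            next(fh)
            for line in fh:
                t, eps, sigma, q, el = line.split()
                rows[t] = (float(eps), float(sigma), float(q), el)
        return cls(rows)

    def lookup(self, atom_type: str) -> tuple[float, float, float]:
        try:
            eps, sigma, q, _ = self.rows[atom_type]
        except KeyError:
            raise ParameterizationError(
                f"no force-field parameters for atom type {atom_type!r}"
            )
        return eps, sigma, q


@dataclass
class Topology:
    """Connectivity and typing of one molecular system (heavy atoms only)."""

    types: list[str]
    elements: list[str]
    bonds: list[tuple[int, int]]
    names: list[str] = field(default_factory=list)
    donors: list[int] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    halogen_donors: list[tuple[int, int]] = field(default_factory=list)  # (C, X)
    torsion_terms: list[tuple[int, int, int, int, float, int, float]] = field(
        default_factory=list
    )  # i,j,k,l, barrier V (kcal/mol), periodicity n, phase gamma (deg)
    angle_terms: list[tuple[int, int, int, float, float]] = field(
        default_factory=list
    )  # i,j,k, k_theta (kcal/mol/rad^2), theta0 (deg)
    #: additional nonbonded exclusions beyond the bonded-path rules, e.g.
    #: backbone pairs inside an idealized rigid helix
    extra_exclusions: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.types)

    def adjacency(self) -> list[set[int]]:
        adj = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def exclusions(self) -> set[frozenset]:
        """1-2, 1-3 and 1-4 pairs, excluded from all nonbonded terms.

        1-4 interactions are folded into the explicit torsion terms, as
        in united-atom force fields that do not scale them separately.
        """
        adj = self.adjacency()
        excl: set[frozenset] = set()
        for i in range(self.n_atoms):
            frontier = {i}
            seen = {i}
            for _ in range(3):  # bonded paths of length 1..3
                frontier = {
                    nb for cur in frontier for nb in adj[cur] if nb not in seen
                }
                seen |= frontier
                for j in frontier:
                    if i < j:
                        excl.add(frozenset((i, j)))
        for i, j in self.extra_exclusions:
            excl.add(frozenset((int(i), int(j))))
        return excl

    @staticmethod
    def merge(a: "Topology", b: "Topology") -> tuple["Topology", int]:
        """Concatenate two topologies; returns (merged, offset of b)."""
        off = a.n_atoms
        sh = lambda t: tuple(x + off for x in t)
        merged = Topology(
            types=a.types + b.types,
            elements=a.elements + b.elements,
            bonds=a.bonds + [(i + off, j + off) for i, j in b.bonds],
            names=a.names + b.names,
            donors=a.donors + [i + off for i in b.donors],
            acceptors=a.acceptors + [i + off for i in b.acceptors],
            halogen_donors=a.halogen_donors
            + [(c + off, x + off) for c, x in b.halogen_donors],
            torsion_terms=a.torsion_terms
            + [(*sh(t[:4]), *t[4:]) for t in b.torsion_terms],
            angle_terms=a.angle_terms
            + [(*sh(t[:3]), *t[3:]) for t in b.angle_terms],
        )
        return merged, off


@dataclass
class EnergyModel:
    """Parameter tables and global settings for the reduced force field."""

    table: AtomTypeTable
    cutoff: float = 8.0
    dielectric: str = "4r"  # or "constant:<value>"
    hbond_r0: float = 2.9
    hbond_emin: float = 4.0
    xbond_emin: float = 4.0
    #: excluded-volume mode: the vdW term becomes the purely repulsive
    #: WCA form (LJ + eps below its minimum, zero beyond) and the
    #: attractive coulomb/hbond/xbond terms are dropped.  Used for
    #: restraint-driven morphing, where a clash-free structure must feel
    #: no force besides its restraints.
    repulsive_only: bool = False
    restraints: dict[int, tuple[np.ndarray, float]] = field(default_factory=dict)

    def dielectric_factor(self, r: np.ndarray) -> np.ndarray:
        """Returns eps(r) * r, the full Coulomb denominator."""
        if self.dielectric == "4r":
            return 4.0 * r * r
        if self.dielectric.startswith("constant:"):
            return float(self.dielectric.split(":")[1]) * r
        raise ValueError(f"unknown dielectric form {self.dielectric!r}")

    @classmethod
    def default(cls) -> "EnergyModel":
        return cls(table=AtomTypeTable.load())


def with_restraints(
    model: EnergyModel, targets: dict[int, np.ndarray], k: float
) -> EnergyModel:
    """A copy of `model` with harmonic restraints E = k * |x - x0|^2 added.

    `targets` maps atom index -> target position.  k = 0 reproduces the
    unrestrained energy exactly.  Existing restraints are kept; a new
    target for the same atom replaces the old one.
    """
    if k < 0:
        raise ValueError("restraint force constant must be >= 0")
    new = dict(model.restraints)
    for idx, xyz in targets.items():
        new[int(idx)] = (np.asarray(xyz, dtype=float), float(k))
    return replace(model, restraints=new)


class EnergyEvaluator:
    """Precompiled energy function for one topology + model.

    Nonbonded pairs may be culled once against reference coordinates with
    a padded cutoff (useful for large receptors whose atoms move little
    during one relaxation); pass ``pair_reference`` for that.  An optional
    ``frozen`` mask marks atoms whose mutual interactions are constant:
    frozen-frozen pairs are skipped entirely, so the reported totals are
    energies *relative to the frozen-core self-energy*.
    """

    def __init__(
        self,
        topology: Topology,
        model: EnergyModel,
        pair_reference: np.ndarray | None = None,
        pair_padding: float = 3.0,
        frozen: np.ndarray | None = None,
    ):
        self.topology = topology
        self.model = model
        n = topology.n_atoms
        eps = np.empty(n)
        sig = np.empty(n)
        q = np.empty(n)
        for i, t in enumerate(topology.types):
            try:
                eps[i], sig[i], q[i] = model.table.lookup(t)
            except ParameterizationError:
                name = topology.names[i] if topology.names else str(i)
                raise ParameterizationError(
                    f"no force-field parameters for atom {name} (type {t!r})"
                )
        self.eps, self.sig, self.q = eps, sig, q

        if frozen is None:
            frozen = np.zeros(n, dtype=bool)
        self.frozen = np.asarray(frozen, dtype=bool)

        excl = topology.exclusions()
        hb_pairs = {
            frozenset((d, a))
            for d in topology.donors
            for a in topology.acceptors
            if d != a
            and frozenset((d, a)) not in excl
            and not (self.frozen[d] and self.frozen[a])
        }
        self.hb_pairs = np.array(sorted(tuple(sorted(p)) for p in hb_pairs),
                                 dtype=int).reshape(-1, 2)

        # candidate nonbonded pairs
        if pair_reference is not None and n > 200:
            tree = cKDTree(pair_reference)
            cand = tree.query_pairs(model.cutoff + pair_padding, output_type="ndarray")
        else:
            ii, jj = np.triu_indices(n, k=1)
            cand = np.column_stack([ii, jj])
        cand = np.asarray(cand, dtype=np.int64).reshape(-1, 2)
        cand.sort(axis=1)
        codes = cand[:, 0] * n + cand[:, 1]
        drop_codes = [min(p) * n + max(p) for p in map(tuple, excl)]
        drop_codes += [
            int(i) * n + int(j) for i, j in self.hb_pairs
        ]
        mask = ~np.isin(codes, np.asarray(drop_codes, dtype=np.int64))
        mask &= ~(self.frozen[cand[:, 0]] & self.frozen[cand[:, 1]])
        self.pairs = cand[mask]
        pi, pj = self.pairs.T if len(self.pairs) else (np.array([], int),) * 2
        self.pair_eps = np.sqrt(eps[pi] * eps[pj])
        self.pair_sig = 0.5 * (sig[pi] + sig[pj])
        self.pair_qq = q[pi] * q[pj]

        # halogen-bond (C-X, acceptor) triples
        xb = []
        for c, x in topology.halogen_donors:
            for a in topology.acceptors:
                if a in (c, x):
                    continue
                if frozenset((x, a)) in excl:
                    continue
                if self.frozen[x] and self.frozen[a]:
                    continue
                r0 = (
                    VDW_RADII[topology.elements[x].upper()]
                    + VDW_RADII[topology.elements[a].upper()]
                    - XBOND_SLACK
                )
                xb.append((c, x, a, r0))
        self.xb_triples = xb

        self.torsions = topology.torsion_terms
        self.angles = topology.angle_terms
        if self.torsions:
            t = np.array([term[:4] for term in self.torsions], dtype=int)
            self._tors_idx = t
            self._tors_V = np.array([term[4] for term in self.torsions])
            self._tors_n = np.array([term[5] for term in self.torsions])
            self._tors_g = np.array([term[6] for term in self.torsions])
        else:
            self._tors_idx = None

        if model.restraints:
            idx = sorted(model.restraints)
            self._restr_idx = np.asarray(idx, dtype=int)
            self._restr_x0 = np.array([model.restraints[i][0] for i in idx])
            self._restr_k = np.array([model.restraints[i][1] for i in idx])
        else:
            self._restr_idx = None

    # -- terms ---------------------------------------------------------

    def _nonbonded(self, coords: np.ndarray) -> tuple[float, float]:
        if len(self.pairs) == 0:
            return 0.0, 0.0
        d = coords[self.pairs[:, 0]] - coords[self.pairs[:, 1]]
        r2 = np.einsum("ij,ij->i", d, d)
        if self.model.repulsive_only:
            # WCA with a reduced core (82% sigma): only genuine overlaps
            # repel; ordinary packing contacts feel nothing
            rmin2 = 2.0 ** (1.0 / 3.0) * (0.82 * self.pair_sig) ** 2
            mask = r2 < rmin2
            if not mask.any():
                return 0.0, 0.0
            sr6 = ((0.82 * self.pair_sig[mask]) ** 2 / r2[mask]) ** 3
            eps = self.pair_eps[mask]
            vdw = float(np.sum(4.0 * eps * (sr6 * sr6 - sr6) + eps))
            return vdw, 0.0
        mask = r2 < self.model.cutoff**2
        if not mask.any():
            return 0.0, 0.0
        r2 = r2[mask]
        sr6 = (self.pair_sig[mask] ** 2 / r2) ** 3
        vdw = float(np.sum(4.0 * self.pair_eps[mask] * (sr6 * sr6 - sr6)))
        r = np.sqrt(r2)
        coul = float(
            np.sum(COULOMB_K * self.pair_qq[mask] / self.model.dielectric_factor(r))
        )
        return vdw, coul

    def _hbond(self, coords: np.ndarray) -> float:
        if len(self.hb_pairs) == 0 or self.model.repulsive_only:
            return 0.0
        d = coords[self.hb_pairs[:, 0]] - coords[self.hb_pairs[:, 1]]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        mask = r < self.model.cutoff
        if not mask.any():
            return 0.0
        x = self.model.hbond_r0 / r[mask]
        return float(np.sum(self.model.hbond_emin * (5.0 * x**12 - 6.0 * x**10)))

    def _xbond(self, coords: np.ndarray) -> float:
        if self.model.repulsive_only:
            return 0.0
        e = 0.0
        for c, x, a, r0 in self.xb_triples:
            rv = coords[a] - coords[x]
            r = np.linalg.norm(rv)
            if r >= self.model.cutoff or r < 0.5:
                continue
            cv = coords[c] - coords[x]
            cosang = np.dot(cv, rv) / (np.linalg.norm(cv) * r)
            # sigma-hole directionality: full strength at C-X...A = 180 deg,
            # smoothly vanishing toward 0 deg so alignment has a gradient
            w = ((1.0 - cosang) / 2.0) ** 2
            t = r0 / r
            e += self.model.xbond_emin * (5.0 * t**12 - 6.0 * t**10) * w
        return float(e)

    def _torsion(self, coords: np.ndarray) -> float:
        if self._tors_idx is None:
            return 0.0
        phi = dihedrals(coords, self._tors_idx)
        return float(
            np.sum(
                0.5 * self._tors_V
                * (1.0 + np.cos(np.radians(self._tors_n * phi - self._tors_g)))
            )
        )

    def _angle(self, coords: np.ndarray) -> float:
        e = 0.0
        for i, j, k, kt, theta0 in self.angles:
            v1 = coords[i] - coords[j]
            v2 = coords[k] - coords[j]
            c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            theta = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
            e += kt * np.radians(theta - theta0) ** 2
        return float(e)

    def _restraint(self, coords: np.ndarray) -> float:
        if self._restr_idx is None:
            return 0.0
        d = coords[self._restr_idx] - self._restr_x0
        return float(np.sum(self._restr_k * np.einsum("ij,ij->i", d, d)))

    def energy(self, coords: np.ndarray) -> dict[str, float]:
        """Full decomposition in kcal/mol; ``total`` is the component sum."""
        vdw, coul = self._nonbonded(coords)
        parts = {
            "vdw": vdw,
            "coulomb": coul,
            "torsion": self._torsion(coords),
            "hbond": self._hbond(coords),
            "xbond": self._xbond(coords),
            "angle": self._angle(coords),
            "restraint": self._restraint(coords),
        }
        parts["total"] = float(sum(parts.values()))
        return parts

    def total(self, coords: np.ndarray) -> float:
        return self.energy(coords)["total"]


def dihedrals(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Signed dihedral angles (deg) for an (m, 4) index array, vectorized."""
    p = coords[idx]
    b0 = p[:, 0] - p[:, 1]
    b1 = p[:, 2] - p[:, 1]
    b2 = p[:, 3] - p[:, 2]
    b1n = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    v = b0 - np.einsum("ij,ij->i", b0, b1n)[:, None] * b1n
    w = b2 - np.einsum("ij,ij->i", b2, b1n)[:, None] * b1n
    x = np.einsum("ij,ij->i", v, w)
    y = np.einsum("ij,ij->i", np.cross(b1n, v), w)
    return np.degrees(np.arctan2(y, x))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


@dataclass
class TorsionDOF:
    """A rotatable dihedral i-j-k-l; `moving` atoms rotate about j-k."""

    atoms: tuple[int, int, int, int]
    moving: np.ndarray
    step: float = 30.0  # line-search half-bracket, degrees


@dataclass
class RigidBodyDOF:
    """Six rigid-body parameters (translation + rotation vector) of a unit."""

    atoms: np.ndarray
    step_trans: float = 1.0  # A
    step_rot: float = 0.3  # rad


class Conformation:
    """Degrees of freedom over fixed covalent geometry.

    ``base_coords`` is the Cartesian reference; the DOF vector is
    [absolute torsion angles (deg), then per-unit (tx,ty,tz, rx,ry,rz)].
    The rebuild is deterministic: torsions are applied in their listed
    (root-to-leaf) order, rigid units afterwards.
    """

    def __init__(
        self,
        base_coords: np.ndarray,
        torsion_dofs: list[TorsionDOF] | None = None,
        rigid_dofs: list[RigidBodyDOF] | None = None,
    ):
        self.base_coords = np.asarray(base_coords, dtype=float).copy()
        self.torsion_dofs = torsion_dofs or []
        self.rigid_dofs = rigid_dofs or []
        self.torsion_values = np.array(
            [
                dihedral(*(self.base_coords[a] for a in t.atoms))
                for t in self.torsion_dofs
            ]
        )
        self.rigid_values = np.zeros(6 * len(self.rigid_dofs))
        self.min_info: dict = {}

    # -- DOF vector ----------------------------------------------------

    @property
    def n_dof(self) -> int:
        return len(self.torsion_values) + len(self.rigid_values)

    def get_dof(self) -> np.ndarray:
        return np.concatenate([self.torsion_values, self.rigid_values])

    def set_dof(self, x: np.ndarray) -> None:
        nt = len(self.torsion_values)
        self.torsion_values = np.asarray(x[:nt], dtype=float).copy()
        self.rigid_values = np.asarray(x[nt:], dtype=float).copy()

    def dof_steps(self) -> np.ndarray:
        steps = [t.step for t in self.torsion_dofs]
        for u in self.rigid_dofs:
            steps += [u.step_trans] * 3 + [u.step_rot] * 3
        return np.array(steps)

    def copy(self) -> "Conformation":
        c = Conformation(self.base_coords, self.torsion_dofs, self.rigid_dofs)
        c.torsion_values = self.torsion_values.copy()
        c.rigid_values = self.rigid_values.copy()
        return c

    # -- Cartesian rebuild --------------------------------------------

    def coords(self) -> np.ndarray:
        x = self.base_coords.copy()
        for t, target in zip(self.torsion_dofs, self.torsion_values):
            i, j, k, l = t.atoms
            current = dihedral(x[i], x[j], x[k], x[l])
            delta = np.radians(target - current)
            if abs(delta) > 1e-12:
                R = rotation_about_axis(x[k] - x[j], delta)
                x[t.moving] = (x[t.moving] - x[k]) @ R.T + x[k]
        off = 0
        for u in self.rigid_dofs:
            v = self.rigid_values[off : off + 6]
            off += 6
            centroid = x[u.atoms].mean(axis=0)
            ang = np.linalg.norm(v[3:])
            if ang > 1e-12:
                R = rotation_about_axis(v[3:] / ang, ang)
                x[u.atoms] = (x[u.atoms] - centroid) @ R.T + centroid
            x[u.atoms] = x[u.atoms] + v[:3]
        return x


@dataclass
class MCMSchedule:
    """Monte Carlo minimization schedule.

    ``n_trajectories`` sequential chains each continue from the best
    conformation found so far; each chain runs up to ``max_steps``
    perturbation + re-minimization cycles.
    """

    n_trajectories: int = 1
    max_steps: int = 10
    torsion_move: float = 60.0  # deg
    translation_move: float = 1.0  # A
    rotation_move: float = 0.5  # rad
    acceptance: str = "greedy"  # or "metropolis"
    temperature: float = 0.6  # kcal/mol, Metropolis only
    tolerance: float = 0.01  # kcal/mol, local-minimizer energy tolerance
    max_sweeps: int = 8
    ls_maxiter: int = 10
    seed: int = 0
    perturb_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_trajectories < 0 or self.max_steps < 0:
            raise ValueError("counts must be >= 0")
        if min(self.torsion_move, self.translation_move, self.rotation_move) <= 0:
            raise ValueError("move magnitudes must be > 0")
        if self.acceptance not in ("greedy", "metropolis"):
            raise ValueError(f"unknown acceptance rule {self.acceptance!r}")


def energy(conformation: Conformation, evaluator: EnergyEvaluator) -> dict[str, float]:
    """Energy decomposition of a conformation under an evaluator."""
    return evaluator.energy(conformation.coords())


def local_minimize(
    conformation: Conformation,
    evaluator: EnergyEvaluator,
    tolerance: float = 1e-4,
    max_sweeps: int = 50,
    ls_maxiter: int = 30,
    grad_check: bool = False,
) -> Conformation:
    """Cyclic coordinate descent over the DOF vector.

    Each sweep line-searches every degree of freedom within its step
    bracket (bounded Brent); sweeps stop when the energy improves by less
    than `tolerance`.  The returned conformation carries convergence
    diagnostics in ``min_info`` (final energy, sweeps, a finite-difference
    gradient norm).
    """
    conf = conformation.copy()
    if not np.all(np.isfinite(conf.base_coords)):
        raise ValueError("non-finite starting coordinates")
    x = conf.get_dof()
    steps = conf.dof_steps()
    if conf.n_dof == 0:
        e = evaluator.total(conf.coords())
        if not np.isfinite(e):
            raise ValueError("non-finite starting energy")
        conf.min_info = {"energy": e, "sweeps": 0, "grad_norm": 0.0}
        return conf

    def f(xv: np.ndarray) -> float:
        conf.set_dof(xv)
        return evaluator.total(conf.coords())

    e = f(x)
    if not np.isfinite(e):
        raise ValueError("non-finite starting energy")
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        e_before = e
        for d in range(len(x)):
            xd = x[d]

            def f1(v: float) -> float:
                x[d] = v
                return f(x)

            res = minimize_scalar(
                f1,
                bounds=(xd - steps[d], xd + steps[d]),
                method="bounded",
                options={"maxiter": ls_maxiter, "xatol": steps[d] * 1e-4},
            )
            if res.fun < e:
                x[d] = res.x
                e = res.fun
            else:
                x[d] = xd
            f(x)  # leave conf consistent
        if e_before - e < tolerance:
            break
    conf.set_dof(x)
    grad_norm = None
    if grad_check:
        # finite-difference gradient diagnostic (per-DOF scaled)
        g = np.empty(len(x))
        h = 1e-4
        for d in range(len(x)):
            xp = x.copy()
            xp[d] += h * steps[d]
            xm = x.copy()
            xm[d] -= h * steps[d]
            g[d] = (f(xp) - f(xm)) / (2 * h * steps[d])
        grad_norm = float(np.linalg.norm(g))
    f(x)
    conf.min_info = {"energy": e, "sweeps": sweeps, "grad_norm": grad_norm}
    return conf


def mc_minimize(
    conformation: Conformation,
    evaluator: EnergyEvaluator,
    schedule: MCMSchedule,
) -> tuple[Conformation, list[float]]:
    """Monte Carlo energy minimization.

    Returns the best conformation and the list of accepted-minimum
    energies (starting with the minimized input).  Under greedy acceptance
    that sequence is non-increasing; the run is bit-reproducible for a
    given seed.
    """
    rng = np.random.default_rng(schedule.seed)
    mins = dict(
        tolerance=schedule.tolerance,
        max_sweeps=schedule.max_sweeps,
        ls_maxiter=schedule.ls_maxiter,
    )
    current = local_minimize(conformation, evaluator, **mins)
    e_cur = current.min_info["energy"]
    best, e_best = current, e_cur
    accepted = [e_cur]
    nt = len(current.torsion_values)
    for _ in range(max(1, schedule.n_trajectories)):
        current, e_cur = best.copy(), e_best
        for _ in range(schedule.max_steps):
            trial = current.copy()
            x = trial.get_dof()
            pick = rng.random(trial.n_dof) < schedule.perturb_fraction
            if not pick.any() and trial.n_dof:
                pick[rng.integers(trial.n_dof)] = True
            for d in np.nonzero(pick)[0]:
                if d < nt:
                    x[d] += rng.uniform(-schedule.torsion_move, schedule.torsion_move)
                else:
                    r = (d - nt) % 6
                    mag = (
                        schedule.translation_move if r < 3 else schedule.rotation_move
                    )
                    x[d] += rng.uniform(-mag, mag)
            trial.set_dof(x)
            if not np.isfinite(evaluator.total(trial.coords())):
                continue
            trial = local_minimize(trial, evaluator, **mins)
            e_trial = trial.min_info["energy"]
            if schedule.acceptance == "greedy":
                accept = e_trial < e_cur
            else:
                accept = e_trial < e_cur or rng.random() < np.exp(
                    -(e_trial - e_cur) / schedule.temperature
                )
            if accept:
                current, e_cur = trial, e_trial
                accepted.append(e_trial)
                if e_trial < e_best:
                    best, e_best = trial, e_trial
    return best, accepted
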