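"""Reduced force field and Monte Carlo minimization."""

import numpy as np
import pytest

from navpyr.constants import COULOMB_K, VDW_RADII, XBOND_SLACK
from navpyr.energetics import (
    AtomTypeTable,
    Conformation,
    EnergyEvaluator,
    EnergyModel,
    MCMSchedule,
    ParameterizationError,
    RigidBodyDOF,
    Topology,
    TorsionDOF,
    dihedral,
    local_minimize,
    mc_minimize,
    with_restraints,
)


@pytest.fixture(scope="module")
def table():
    return AtomTypeTable.load()


def simple_topology(types, bonds=(), **kw):
    return Topology(
        types=list(types),
        elements=["C"] * len(types),
        bonds=list(bonds),
        names=[f"A{i}" for i in range(len(types))],
        **kw,
    )


def brute_force_energy(topology, model, coords):
    """Straight-line re-implementation: explicit loops over every term."""
    table = model.table
    eps, sig, q = zip(*(table.lookup(t) for t in topology.types))
    excl = topology.exclusions()
    donors, acceptors = set(topology.donors), set(topology.acceptors)
    vdw = coul = hb = 0.0
    n = topology.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((i, j)) in excl:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r >= model.cutoff:
                continue
            is_hb = (i in donors and j in acceptors) or (
                j in donors and i in acceptors
            )
            if is_hb:
                # the 10-12 term subsumes the whole donor-acceptor pair
                x = model.hbond_r0 / r
                hb += model.hbond_emin * (5 * x**12 - 6 * x**10)
            else:
                e = np.sqrt(eps[i] * eps[j])
                s = 0.5 * (sig[i] + sig[j])
                vdw += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
                coul += COULOMB_K * q[i] * q[j] / (4.0 * r * r)
    xb = 0.0
    for c, x_i in topology.halogen_donors:
        for a in acceptors:
            if a in (c, x_i) or frozenset((x_i, a)) in excl:
                continue
            rv = coords[a] - coords[x_i]
            r = float(np.linalg.norm(rv))
            if r >= model.cutoff or r < 0.5:
                continue
            cv = coords[c] - coords[x_i]
            cosang = float(np.dot(cv, rv)) / (np.linalg.norm(cv) * r)
            w = ((1.0 - cosang) / 2.0) ** 2
            r0 = (
                VDW_RADII[topology.elements[x_i].upper()]
                + VDW_RADII[topology.elements[a].upper()]
                - XBOND_SLACK
            )
            xb += model.xbond_emin * (5 * (r0 / r) ** 12 - 6 * (r0 / r) ** 10) * w
    tors = 0.0
    for i, j, k, l, V, per, gamma in topology.torsion_terms:
        phi = dihedral(coords[i], coords[j], coords[k], coords[l])
        tors += 0.5 * V * (1 + np.cos(np.radians(per * phi - gamma)))
    restr = 0.0
    for idx, (x0, kk) in model.restraints.items():
        restr += kk * float(np.sum((coords[idx] - x0) ** 2))
    return vdw + coul + hb + xb + tors + restr


class TestEnergyTerms:
    def test_lj_dimer_closed_form(self, table, model):
        eps, sigma, _ = table.lookup("CH3")
        top = simple_topology(["CH3", "CH3"])
        ev = EnergyEvaluator(top, model)
        r = 2 ** (1 / 6) * sigma
        parts = ev.energy(np.array([[0, 0, 0], [r, 0, 0.0]]))
        assert parts["vdw"] == pytest.approx(-eps, abs=1e-12)
        assert parts["total"] == pytest.approx(parts["vdw"] + parts["coulomb"])

    def test_empty_system(self, model):
        ev = EnergyEvaluator(simple_topology([]), model)
        parts = ev.energy(np.zeros((0, 3)))
        assert all(v == 0.0 for v in parts.values())

    def test_matches_brute_force_oracle(self, model, rng):
        """Random small systems against the loop-based oracle."""
        for _ in range(25):
            n = int(rng.integers(5, 21))
            types = list(rng.choice(["CH3", "CH2", "OH", "S", "N", "BR"], size=n))
            bonds = [(i, i + 1) for i in range(n - 1) if rng.random() < 0.5]
            top = simple_topology(types, bonds)
            top.elements = [
                "BR" if t == "BR" else ("O" if t == "OH" else
                                        "S" if t == "S" else
                                        "N" if t == "N" else "C")
                for t in types
            ]
            top.donors = [i for i, t in enumerate(types) if t == "OH"]
            top.acceptors = [i for i, t in enumerate(types) if t in ("OH", "S", "N")]
            for i, j in bonds:
                if types[j] == "BR":
                    top.halogen_donors.append((i, j))
            coords = rng.uniform(-6, 6, size=(n, 3))
            ev = EnergyEvaluator(top, model)
            got = ev.energy(coords)["total"]
            want = brute_force_energy(top, model, coords)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_rigid_motion_invariance(self, model, rng):
        from scipy.spatial.transform import Rotation

        top = simple_topology(["CH3", "CH2", "OH", "S", "CH3"], [(0, 1), (1, 2)])
        top.elements = ["C", "C", "O", "S", "C"]
        top.donors, top.acceptors = [2], [2, 3]
        coords = rng.uniform(-4, 4, size=(5, 3))
        ev = EnergyEvaluator(top, model)
        e0 = ev.energy(coords)["total"]
        for _ in range(10):
            quat = rng.normal(size=4)
            R = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
            t = rng.normal(scale=20, size=3)
            e1 = ev.energy(coords @ R.T + t)["total"]
            assert abs(e1 - e0) < 1e-6

    def test_unknown_type_names_atom(self, model):
        top = simple_topology(["CH3", "XX"])
        with pytest.raises(ParameterizationError, match="A1"):
            EnergyEvaluator(top, model)


class TestRestraints:
    def test_zero_at_target_and_closed_form(self, model):
        top = simple_topology(["CH3"])
        m = with_restraints(model, {0: np.zeros(3)}, 1.0)
        ev = EnergyEvaluator(top, m)
        assert ev.energy(np.zeros((1, 3)))["restraint"] == 0.0
        # atom 2 A from target, k = 1 -> 4.0 kcal/mol
        assert ev.energy(np.array([[2.0, 0, 0]]))["restraint"] == pytest.approx(4.0)

    def test_zero_k_reproduces_unrestrained(self, model, rng):
        top = simple_topology(["CH3", "CH2"])
        coords = rng.uniform(-3, 3, size=(2, 3))
        e0 = EnergyEvaluator(top, model).energy(coords)["total"]
        m = with_restraints(model, {0: np.array([9.0, 9, 9])}, 0.0)
        e1 = EnergyEvaluator(top, m).energy(coords)["total"]
        assert e1 == pytest.approx(e0)

    def test_restrained_free_atom_minimizes_to_target(self, model):
        top = simple_topology(["CH3"])
        target = np.array([1.0, -2.0, 0.5])
        m = with_restraints(model, {0: target}, 5.0)
        ev = EnergyEvaluator(top, m)
        conf = Conformation(np.zeros((1, 3)), rigid_dofs=[RigidBodyDOF(np.array([0]))])
        out = local_minimize(conf, ev, tolerance=1e-9, max_sweeps=200)
        assert np.linalg.norm(out.coords()[0] - target) <= 1e-3

    def test_negative_k_rejected(self, model):
        with pytest.raises(ValueError):
            with_restraints(model, {0: np.zeros(3)}, -1.0)


class TestLocalMinimize:
    def test_lj_dimer_reaches_sigma_minimum(self, table, model):
        eps, sigma, _ = table.lookup("CH3")
        top = simple_topology(["CH3", "CH3"])
        ev = EnergyEvaluator(top, model)
        conf = Conformation(
            np.array([[0.0, 0, 0], [4.5, 0, 0]]),
            rigid_dofs=[RigidBodyDOF(np.array([1]))],
        )
        out = local_minimize(conf, ev, tolerance=1e-8, max_sweeps=300, ls_maxiter=60)
        sep = np.linalg.norm(out.coords()[1] - out.coords()[0])
        assert sep == pytest.approx(2 ** (1 / 6) * sigma, abs=1e-3)

    def test_fixed_point(self, table, model):
        eps, sigma, _ = table.lookup("CH3")
        r = 2 ** (1 / 6) * sigma
        top = simple_topology(["CH3", "CH3"])
        ev = EnergyEvaluator(top, model)
        conf = Conformation(
            np.array([[0.0, 0, 0], [r, 0, 0]]),
            rigid_dofs=[RigidBodyDOF(np.array([1]))],
        )
        out = local_minimize(conf, ev, tolerance=1e-8, max_sweeps=100, ls_maxiter=60)
        assert np.abs(out.coords() - conf.base_coords).max() < 1e-3

    def test_planted_torsion_minimum(self, model):
        """1-torsion toy converges to the nearest 3-fold minimum (1-deg scan)."""
        base = np.array(
            [[-1.5, 0.8, 0.0], [-0.75, 0, 0], [0.75, 0, 0], [1.5, 0.8, 0.0]]
        )
        top = simple_topology(["CH3", "CH2", "CH2", "CH3"],
                              [(0, 1), (1, 2), (2, 3)])
        top.torsion_terms.append((0, 1, 2, 3, 2.0, 3, 0.0))
        ev = EnergyEvaluator(top, model)
        td = TorsionDOF(atoms=(0, 1, 2, 3), moving=np.array([3]), step=40.0)

        def energy_at(angle):
            conf = Conformation(base, torsion_dofs=[td])
            conf.torsion_values[:] = angle
            return ev.total(conf.coords())

        scan = {a: energy_at(a) for a in range(-180, 180)}
        for start in (-150, -40, 10, 95, 170):
            conf = Conformation(base, torsion_dofs=[td])
            conf.torsion_values[:] = start
            out = local_minimize(conf, ev, tolerance=1e-8, max_sweeps=100,
                                 ls_maxiter=60)
            final = out.torsion_values[0] % 360
            # nearest scan minimum below the converged energy
            e_final = out.min_info["energy"]
            best_near = min(
                v for a, v in scan.items()
                if abs((a - final + 180) % 360 - 180) <= 2
            )
            assert e_final <= best_near + 1e-6

    def test_nonfinite_start_rejected(self, model):
        top = simple_topology(["CH3", "CH3"])
        ev = EnergyEvaluator(top, model)
        conf = Conformation(np.array([[np.nan, 0, 0], [1.0, 0, 0]]),
                            rigid_dofs=[RigidBodyDOF(np.array([0]))])
        with pytest.raises(ValueError):
            local_minimize(conf, ev)


def two_torsion_toy(model):
    """A rugged 2-torsion landscape with competing 2- and 3-fold terms."""
    base = np.array(
        [
            [-2.25, 0.8, 0.3],
            [-1.5, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [2.25, 0.8, -0.3],
        ]
    )
    top = simple_topology(
        ["CH3", "CH2", "CH2", "CH2", "CH3"], [(i, i + 1) for i in range(4)]
    )
    top.torsion_terms.append((0, 1, 2, 3, 2.5, 3, 0.0))
    top.torsion_terms.append((1, 2, 3, 4, 1.8, 2, 60.0))
    ev = EnergyEvaluator(top, model)
    t1 = TorsionDOF(atoms=(0, 1, 2, 3), moving=np.array([3, 4]), step=40.0)
    t2 = TorsionDOF(atoms=(1, 2, 3, 4), moving=np.array([4]), step=40.0)
    conf = Conformation(base, torsion_dofs=[t1, t2])
    return conf, ev


def grid_scan_minimum(conf, ev, step=5):
    best = np.inf
    c = conf.copy()
    for a in range(-180, 180, step):
        for b in range(-180, 180, step):
            c.torsion_values = np.array([float(a), float(b)])
            best = min(best, ev.total(c.coords()))
    return best


class TestMCMinimize:
    def test_zero_steps_is_local_minimize(self, model):
        conf, ev = two_torsion_toy(model)
        sched = MCMSchedule(max_steps=0, seed=3, tolerance=1e-6, max_sweeps=60,
                            ls_maxiter=40)
        best, accepted = mc_minimize(conf, ev, sched)
        direct = local_minimize(conf, ev, tolerance=1e-6, max_sweeps=60,
                                ls_maxiter=40)
        assert best.min_info["energy"] == pytest.approx(
            direct.min_info["energy"], abs=1e-9
        )
        assert len(accepted) == 1

    def test_seed_determinism(self, model):
        conf, ev = two_torsion_toy(model)
        sched = MCMSchedule(max_steps=15, seed=11)
        _, traj1 = mc_minimize(conf, ev, sched)
        _, traj2 = mc_minimize(conf, ev, sched)
        assert traj1 == traj2

    def test_greedy_accepted_energies_non_increasing(self, model):
        conf, ev = two_torsion_toy(model)
        for seed in range(5):
            _, accepted = mc_minimize(conf, ev, MCMSchedule(max_steps=20, seed=seed))
            assert all(a >= b - 1e-9 for a, b in zip(accepted, accepted[1:]))

    def test_best_energy_never_above_start(self, model):
        conf, ev = two_torsion_toy(model)
        e_start = ev.total(conf.coords())
        best, _ = mc_minimize(conf, ev, MCMSchedule(max_steps=10, seed=1))
        assert best.min_info["energy"] <= e_start + 1e-9

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            MCMSchedule(max_steps=-1)
        with pytest.raises(ValueError):
            MCMSchedule(torsion_move=0.0)
        with pytest.raises(ValueError):
            MCMSchedule(acceptance="anneal")


class TestConformation:
    def test_rebuild_preserves_covalent_geometry(self, ligand_type2, rng):
        from navpyr.docking import ligand_conformation

        conf = ligand_conformation(ligand_type2)
        bonds = ligand_type2.topology.bonds

        def lengths(c):
            return np.array([np.linalg.norm(c[i] - c[j]) for i, j in bonds])

        b0 = lengths(conf.coords())
        x = conf.get_dof()
        x[: len(conf.torsion_values)] += rng.uniform(-120, 120,
                                                     len(conf.torsion_values))
        x[len(conf.torsion_values):] += rng.normal(size=6)
        conf.set_dof(x)
        assert np.abs(lengths(conf.coords()) - b0).max() < 1e-9

    def test_rebuild_is_deterministic(self, ligand_type2):
        from navpyr.docking import ligand_conformation

        conf = ligand_conformation(ligand_type2)
        x = conf.get_dof()
        x[:] += 13.0
        conf.set_dof(x)
        assert np.array_equal(conf.coords(), conf.coords())

    def test_torsion_targets_reached(self, ligand_type2):
        from navpyr.docking import ligand_conformation

        conf = ligand_conformation(ligand_type2)
        conf.torsion_values = conf.torsion_values + np.linspace(
            20, 100, len(conf.torsion_values)
        )
        coords = conf.coords()
        for td, target in zip(conf.torsion_dofs, conf.torsion_values):
            got = dihedral(*(coords[a] for a in td.atoms))
            assert abs((got - target + 180) % 360 - 180) < 1e-8
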