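"""Multi-start docking: pose generation, filtering and selection."""

import numpy as np
import pytest

from navpyr.docking import (
    DockingConfig,
    DockingError,
    InteractionEvaluator,
    Pose,
    PoseEnsemble,
    SiteDefinition,
    filter_window,
    ligand_conformation,
    random_start_poses,
    refine_poses,
    select_by_sensing_contacts,
)
from navpyr.energetics import MCMSchedule
from navpyr.proteins import protein_topology
from navpyr.synthetic import sensing_labels


@pytest.fixture(scope="module")
def site(open_channel):
    return SiteDefinition.from_labels(open_channel, sensing_labels())


@pytest.fixture(scope="module")
def scorer(open_channel, receptor_topology, ligand_type2, model, site):
    return InteractionEvaluator(
        open_channel, receptor_topology, ligand_type2, model, site
    )


def _fake_pose(energy, coords=None):
    c = coords if coords is not None else np.zeros((3, 3))
    return Pose(conformation=None, coords=c, energy=energy)


class TestSiteDefinition:
    def test_box_encloses_residue_centroids(self, open_channel, site):
        for lab in site.residues:
            ri = open_channel.residue_by_label(lab)
            cent = open_channel.coords[open_channel.side_chain_atoms(ri)].mean(0)
            assert site.contains(cent)

    def test_missing_residue_rejected(self, open_channel):
        from navpyr.channel_io import UniversalLabel

        with pytest.raises(DockingError):
            SiteDefinition.from_labels(
                open_channel, [UniversalLabel(domain=1, segment="p", index=44)]
            )


class TestRandomStartPoses:
    def test_requested_count(self, ligand_type2, site):
        ens = random_start_poses(ligand_type2, site, DockingConfig(n_starts=25, seed=1))
        assert len(ens) == 25

    def test_zero_starts(self, ligand_type2, site):
        ens = random_start_poses(ligand_type2, site, DockingConfig(n_starts=0))
        assert len(ens) == 0

    def test_centroids_inside_box(self, ligand_type2, site):
        ens = random_start_poses(ligand_type2, site, DockingConfig(n_starts=40, seed=3))
        for pose in ens:
            assert site.contains(pose.coords.mean(axis=0))

    def test_seed_determinism(self, ligand_type2, site):
        a = random_start_poses(ligand_type2, site, DockingConfig(n_starts=10, seed=5))
        b = random_start_poses(ligand_type2, site, DockingConfig(n_starts=10, seed=5))
        c = random_start_poses(ligand_type2, site, DockingConfig(n_starts=10, seed=6))
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.coords, pb.coords)
        assert not all(
            np.allclose(pa.coords, pc.coords) for pa, pc in zip(a, c)
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DockingConfig(n_starts=-1)
        with pytest.raises(ValueError):
            DockingConfig(energy_window=-0.1)
        with pytest.raises(ValueError):
            DockingConfig(contact_cutoff=0.0)


class TestFilterWindow:
    def test_direct_rule(self):
        ens = PoseEnsemble([_fake_pose(e) for e in (-20.0, -16.2, -14.9)])
        kept = filter_window(ens, 5.0)
        assert [p.energy for p in kept] == [-20.0, -16.2]

    def test_zero_window_keeps_ties(self):
        ens = PoseEnsemble([_fake_pose(e) for e in (-20.0, -20.0, -19.9)])
        kept = filter_window(ens, 0.0)
        assert [p.energy for p in kept] == [-20.0, -20.0]

    def test_infinite_window_is_identity(self, rng):
        ens = PoseEnsemble([_fake_pose(e) for e in rng.normal(size=30)])
        assert len(filter_window(ens, np.inf)) == len(ens)

    def test_idempotent(self, rng):
        ens = PoseEnsemble([_fake_pose(e) for e in rng.normal(size=30)])
        once = filter_window(ens, 2.0)
        twice = filter_window(once, 2.0)
        assert [p.energy for p in once] == [p.energy for p in twice]

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            energies = rng.normal(scale=5, size=rng.integers(1, 40))
            window = float(rng.uniform(0, 8))
            ens = PoseEnsemble([_fake_pose(float(e)) for e in energies])
            kept = {p.energy for p in filter_window(ens, window)}
            want = {float(e) for e in energies if e <= energies.min() + window}
            assert kept == want

    def test_empty(self):
        assert len(filter_window(PoseEnsemble([]), 5.0)) == 0


class TestSelectBySensingContacts:
    def test_rule_application(self, open_channel, sensing):
        """Counts 2, 5, 5 with energies -10, -12, -14: the -14 pose wins."""
        ri = open_channel.residue_by_label(sensing[0])
        tip = open_channel.coords[open_channel.side_chain_atoms(ri)].mean(0)
        near_all = np.vstack(
            [
                open_channel.coords[
                    open_channel.side_chain_atoms(
                        open_channel.residue_by_label(lab)
                    )
                ].mean(0)
                for lab in sensing
            ]
        )
        far = np.full((4, 3), 500.0)
        poses = [
            _fake_pose(-10.0, np.vstack([tip, far[:3]])),
            _fake_pose(-12.0, near_all),
            _fake_pose(-14.0, near_all + 0.1),
        ]
        ens = PoseEnsemble(poses)
        best, count = select_by_sensing_contacts(ens, sensing, open_channel)
        assert best.energy == -14.0
        assert count == 4

    def test_empty_sensing_returns_lowest_energy(self, open_channel):
        ens = PoseEnsemble([_fake_pose(-3.0), _fake_pose(-9.0)])
        best, count = select_by_sensing_contacts(ens, set(), open_channel)
        assert best.energy == -9.0 and count == 0

    def test_empty_ensemble_raises(self, open_channel, sensing):
        with pytest.raises(DockingError):
            select_by_sensing_contacts(PoseEnsemble([]), sensing, open_channel)

    def test_matches_enumeration_oracle(self, open_channel, sensing, rng):
        from navpyr.docking import count_sensing_contacts

        sens = {l.bare() for l in sensing}
        for _ in range(10):
            poses = [
                _fake_pose(
                    float(rng.normal()),
                    rng.uniform(-25, 25, size=(6, 3)),
                )
                for _ in range(15)
            ]
            ens = PoseEnsemble(poses)
            best, count = select_by_sensing_contacts(ens, sensing, open_channel)
            # brute force over the ensemble
            scored = [
                (-count_sensing_contacts(open_channel, p.coords, sens, 4.0),
                 p.energy, k)
                for k, p in enumerate(ens)
            ]
            want = min(scored)
            assert count == -want[0]
            assert best.energy == want[1]


class TestRefinePoses:
    def test_energies_never_increase(self, ligand_type2, site, scorer):
        ens = random_start_poses(
            ligand_type2, site, DockingConfig(n_starts=8, seed=2), scorer=scorer
        )
        start = {id(p.conformation): p.energy for p in ens}
        refined = refine_poses(
            ens, scorer,
            schedule=MCMSchedule(max_steps=1, max_sweeps=1, ls_maxiter=5),
            ligand=ligand_type2,
        )
        for p in refined:
            assert p.energy <= max(start.values()) + 1e-9
        assert all(a.energy <= b.energy for a, b in zip(refined, refined[1:]))

    def test_planted_optimum_is_fixed_point(self, truth, ligand_type2, scorer):
        conf = ligand_conformation(ligand_type2)
        conf.base_coords = truth.pose_coords.copy()
        e0 = scorer.energy(truth.pose_coords)
        pose = Pose(conformation=conf, coords=truth.pose_coords, energy=e0)
        refined = refine_poses(
            PoseEnsemble([pose]), scorer,
            schedule=MCMSchedule(max_steps=0, tolerance=1e-4, max_sweeps=10,
                                 ls_maxiter=20),
            ligand=ligand_type2,
        )
        assert refined[0].energy == pytest.approx(e0, abs=0.35)

    def test_empty_ensemble(self, scorer, ligand_type2):
        out = refine_poses(PoseEnsemble([]), scorer, ligand=ligand_type2)
        assert len(out) == 0


class TestOrientationFlag:
    def test_flip_changes_sign(self, ligand_type2):
        from navpyr.docking import pose_orientation

        coords = ligand_type2.coords
        s1 = pose_orientation(coords, ligand_type2.axis_atoms, (0, 0, -1.0))
        s2 = pose_orientation(-coords, ligand_type2.axis_atoms, (0, 0, -1.0))
        assert s1 == -s2
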