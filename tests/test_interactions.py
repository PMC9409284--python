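"""Geometric interaction detectors and contact-difference reports."""

import numpy as np
import pytest

from navpyr.channel_io import ChannelStructure, Residue, UniversalLabel
from navpyr.constants import VDW_RADII
from navpyr.interactions import (
    ContactRecord,
    InteractionInputError,
    InteractionReport,
    contact_diff,
    detect_halogen_bond,
    detect_hbond,
    detect_salt_bridge,
    ligand_contacts,
    residue_environment,
)


def brute_force_contacts(receptor, pose, elements, cutoff, side_chain_only=True):
    """All-pairs loop oracle: one entry per residue with min distance."""
    heavy = [i for i, e in enumerate(elements) if e.upper() != "H"]
    pose = pose[heavy]
    out = {}
    for ri, res in enumerate(receptor.residues):
        idx = (
            receptor.side_chain_atoms(ri)
            if side_chain_only
            else [
                i
                for i in receptor.atoms_of_residue(ri)
                if receptor.elements[i].upper() != "H"
            ]
        )
        best = np.inf
        for i in idx:
            for p in pose:
                best = min(best, float(np.linalg.norm(receptor.coords[i] - p)))
        if best <= cutoff:
            out[res.resnum] = best
    return out


class TestLigandContacts:
    def test_boundary_inclusive(self):
        structure = _two_residue_structure(side_xyz=[3.9, 0, 0])
        recs = ligand_contacts(structure, np.zeros((1, 3)), ["C"], cutoff=4.0)
        assert [r.resnum for r in recs] == [1]
        structure = _two_residue_structure(side_xyz=[4.1, 0, 0])
        assert ligand_contacts(structure, np.zeros((1, 3)), ["C"], cutoff=4.0) == []

    def test_matches_brute_force_oracle(self, open_channel, ligand_type2, rng):
        for _ in range(20):
            pose = rng.uniform(-20, 20, size=(ligand_type2.n_atoms, 3))
            got = {
                r.resnum: r.min_distance
                for r in ligand_contacts(
                    open_channel, pose,
                    pose_elements=ligand_type2.topology.elements,
                )
            }
            want = brute_force_contacts(
                open_channel, pose,
                ligand_type2.topology.elements, 4.0,
            )
            assert set(got) == set(want)
            for k in got:
                assert got[k] == pytest.approx(want[k], abs=1e-9)

    def test_sorted_by_label(self, open_channel, truth, ligand_type2):
        recs = ligand_contacts(
            open_channel, truth.pose_coords,
            pose_elements=ligand_type2.topology.elements,
        )
        keys = [r.sort_key() for r in recs]
        assert keys == sorted(keys)

    def test_empty_ligand(self, open_channel):
        assert ligand_contacts(open_channel, np.zeros((0, 3))) == []

    def test_hydrogens_excluded(self):
        structure = _two_residue_structure(side_xyz=[3.0, 0, 0])
        # hydrogen-only pose: no heavy atoms, no contacts
        recs = ligand_contacts(structure, np.zeros((1, 3)), ["H"], cutoff=4.0)
        assert recs == []


class TestHbond:
    def test_canonical_geometry(self):
        d = np.array([0.0, 0, 0])
        h = np.array([0.95, 0.15, 0])
        a = np.array([2.9, 0, 0])
        assert detect_hbond(d, a, hydrogen=h)

    def test_distance_gate(self):
        assert not detect_hbond([0, 0, 0], [3.6, 0, 0])
        assert detect_hbond([0, 0, 0], [3.5, 0, 0])

    def test_angle_gate(self):
        d = np.array([0.0, 0, 0])
        a = np.array([2.9, 0, 0])
        h_bad = np.array([1.45, 2.0, 0])  # D-H...A near 70 deg
        assert not detect_hbond(d, a, hydrogen=h_bad)

    def test_predicate_grid(self):
        """Direct two-clause predicate over a geometry grid."""
        d = np.zeros(3)
        for dist in np.linspace(2.0, 4.5, 11):
            a = np.array([dist, 0, 0])
            for h_angle in np.linspace(0, np.pi, 13):
                h = d + 1.0 * np.array([np.cos(h_angle), np.sin(h_angle), 0])
                v1, v2 = d - h, a - h
                ang = np.degrees(
                    np.arccos(
                        np.clip(
                            np.dot(v1, v2)
                            / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                            -1, 1,
                        )
                    )
                )
                expected = dist <= 3.5 and ang >= 120.0
                assert detect_hbond(d, a, hydrogen=h) == expected

    def test_coincident_atoms_rejected(self):
        with pytest.raises(InteractionInputError):
            detect_hbond([0, 0, 0], [0, 0, 0])


class TestHalogenBond:
    def test_br_s_within_gates(self):
        # Br...S 3.5 A (vdW sum 3.65), C-Br...S 170 deg -> true
        c = np.array([-1.9, 0.3, 0.0])
        x = np.zeros(3)
        a = np.array([3.5, 0, 0])
        assert detect_halogen_bond(c, x, a, "Br", "S")

    def test_directionality_gate(self):
        # same distance, C-Br...S = 100 deg -> false
        c = 1.9 * np.array([np.cos(np.radians(100)), np.sin(np.radians(100)), 0])
        assert not detect_halogen_bond(c, np.zeros(3), [3.5, 0, 0], "Br", "S")

    def test_predicate_grid(self):
        x = np.zeros(3)
        gate = VDW_RADII["BR"] + VDW_RADII["S"] + 0.2
        for dist in np.linspace(2.5, 4.5, 9):
            a = np.array([dist, 0, 0])
            for ang in np.linspace(0, 180, 13):
                c = 1.9 * np.array(
                    [np.cos(np.radians(ang)), np.sin(np.radians(ang)), 0]
                )
                expected = dist <= gate and ang >= 140.0
                assert detect_halogen_bond(c, x, a, "Br", "S") == expected

    def test_non_halogen_rejected(self):
        with pytest.raises(InteractionInputError):
            detect_halogen_bond([-1.9, 0, 0], [0, 0, 0], [3.5, 0, 0], "C", "S")
        with pytest.raises(InteractionInputError):
            detect_halogen_bond([-1.9, 0, 0], [0, 0, 0], [3.5, 0, 0], "Br", "C")


class TestSaltBridge:
    def test_within_and_beyond_gate(self):
        assert detect_salt_bridge([[0, 0, 0]], [[2.8, 0, 0]]) is True
        assert detect_salt_bridge([[0, 0, 0]], [[4.2, 0, 0]]) is False
        assert detect_salt_bridge([[0, 0, 0]], [[4.0, 0, 0]]) is True

    def test_symmetric(self, rng):
        for _ in range(20):
            o = rng.uniform(-5, 5, size=(2, 3))
            n = rng.uniform(-5, 5, size=(3, 3))
            assert detect_salt_bridge(o, n) == detect_salt_bridge(n, o)

    def test_min_distance_oracle(self, rng):
        for _ in range(30):
            o = rng.uniform(-6, 6, size=(2, 3))
            n = rng.uniform(-6, 6, size=(3, 3))
            want = min(
                np.linalg.norm(oi - ni) for oi in o for ni in n
            ) <= 4.0
            assert detect_salt_bridge(o, n) == want

    def test_missing_atoms_indeterminate(self):
        assert detect_salt_bridge(np.empty((0, 3)), [[0, 0, 0]]) is None

    def test_planted_bridge_in_vsm_fixture(self, vsm_channel):
        """The linker aspartate pairs with the lowest S4 arginine (R1)."""
        open_ch = vsm_channel[0]
        asp = open_ch.residue_by_resnum(3002)
        arg = open_ch.residue_by_resnum(3003)
        o_xyz = open_ch.coords[
            [open_ch.atom_index(asp, n) for n in ("OD1", "OD2")]
        ]
        n_xyz = open_ch.coords[
            [open_ch.atom_index(arg, n) for n in ("NE", "NH1", "NH2")]
        ]
        assert detect_salt_bridge(o_xyz, n_xyz) is True


class TestPiStack:
    def test_distance_gate(self):
        from navpyr.interactions import detect_pi_stack

        assert detect_pi_stack([0, 0, 0], [5.0, 0, 0])
        assert not detect_pi_stack([0, 0, 0], [5.6, 0, 0])
        with pytest.raises(InteractionInputError):
            detect_pi_stack([0, 0, 0], [0, 0, 0])


class TestContactDiff:
    def _report(self, entries, state="open_pm", lig="L"):
        contacts = [
            ContactRecord(
                label=UniversalLabel(domain=d, segment=s, index=i),
                resnum=n, resname="ALA", min_distance=dist,
                residue_atom="CB", partner_atom="L0",
            )
            for (d, s, i, n, dist) in entries
        ]
        return InteractionReport(state, lig, contacts)

    def test_identity_all_retained(self):
        a = self._report([(2, "k", 6, 2026, 3.5), (3, "i", 8, 3088, 3.2)])
        diff = contact_diff(a, a)
        assert diff["lost"] == diff["gained"] == diff["weakened"] == []
        assert len(diff["retained"]) == 2

    def test_lost_and_gained(self):
        a = self._report([(2, "k", 6, 2026, 3.5), (3, "i", 8, 3088, 3.2)])
        b = self._report([(2, "k", 6, 2026, 3.5), (1, "o", 6, 1046, 3.9)])
        diff = contact_diff(a, b)
        assert diff["lost"] == ["3i8"]
        assert diff["gained"] == ["1o6"]

    def test_weakened_threshold(self):
        a = self._report([(2, "k", 6, 2026, 3.0)])
        b = self._report([(2, "k", 6, 2026, 3.6)])
        assert contact_diff(a, b)["weakened"] == ["2k6"]
        b2 = self._report([(2, "k", 6, 2026, 3.4)])
        assert contact_diff(a, b2)["retained"] == ["2k6"]

    def test_mismatched_ligands_rejected(self):
        a = self._report([], lig="L1")
        b = self._report([], lig="L2")
        with pytest.raises(InteractionInputError):
            contact_diff(a, b)

    def test_planted_retreat_between_states(
        self, open_channel, inactivated_channel, truth, ligand_type2
    ):
        """The gate shift pulls the planted aromatic wall off the ligand."""
        elems = ligand_type2.topology.elements
        rep_open = InteractionReport(
            "open_pm", "type2",
            ligand_contacts(open_channel, truth.pose_coords, pose_elements=elems),
        )
        rep_inact = InteractionReport(
            "inactivated_pm", "type2",
            ligand_contacts(
                inactivated_channel, truth.pose_coords, pose_elements=elems
            ),
        )
        diff = contact_diff(rep_open, rep_inact)
        assert "3i8" in diff["lost"] + diff["weakened"]

    def test_report_json_round_trip(self, tmp_path):
        a = self._report([(2, "k", 6, 2026, 3.456)])
        path = tmp_path / "rep.json"
        a.to_json(path)
        back = InteractionReport.from_json(path)
        assert back.ligand_id == a.ligand_id
        assert back.residue_keys().keys() == a.residue_keys().keys()


class TestResidueEnvironment:
    def test_planted_hbond_pair_reported(self, open_channel):
        env = residue_environment(
            open_channel, UniversalLabel(domain=2, segment="p", index=4)
        )
        by_label = {e["label"]: e for e in env}
        assert "2o11" in by_label
        assert "hbond" in by_label["2o11"]["classes"]

    def test_sequential_neighbours_excluded(self, open_channel):
        env = residue_environment(
            open_channel, UniversalLabel(domain=2, segment="o", index=6)
        )
        for e in env:
            if e["label"] and e["label"].startswith("2o"):
                idx = int(e["label"][2:])
                assert abs(idx - 6) > 2

    def test_zero_cutoff_empty(self, open_channel):
        env = residue_environment(
            open_channel, UniversalLabel(domain=2, segment="p", index=4), cutoff=0
        )
        assert env == []

    def test_absent_label_raises(self, open_channel):
        with pytest.raises(KeyError):
            residue_environment(
                open_channel, UniversalLabel(domain=4, segment="p", index=40)
            )

    def test_sorted_by_distance(self, open_channel):
        env = residue_environment(
            open_channel, UniversalLabel(domain=2, segment="k", index=6)
        )
        dists = [e["min_distance"] for e in env]
        assert dists == sorted(dists)


def _two_residue_structure(side_xyz):
    residues = [
        Residue(name="ALA", resnum=1, domain=1, segment="k", seg_index=1),
        Residue(name="ALA", resnum=2, domain=1, segment="k", seg_index=2),
    ]
    coords = np.array(
        [[10.0, 10, 10], side_xyz, [20.0, 20, 20], [25.0, 20, 20]], dtype=float
    )
    return ChannelStructure(
        coords,
        ["CA", "CB", "CA", "CB"],
        ["C", "C", "C", "C"],
        np.array([0, 0, 1, 1]),
        residues,
    )
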