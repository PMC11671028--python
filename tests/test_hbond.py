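import math

import numpy as np
import pytest

from mumiscan import (
    HBondCriterion,
    add_polar_hydrogens,
    count_wt_bonds,
    detect_hbonds,
    dominant_bonds,
    occupancy,
    salt_bridge_distance,
)
from mumiscan.hbond import HBondOccupancy, pair_key
from mumiscan.fixtures import make_helix_peptide, make_jitter_ensemble, make_toy_dimer
from mumiscan.structure_io import Ensemble, Structure

from conftest import brute_force_hbonds, hbond_atom_triples


class TestAddPolarHydrogens:
    def test_amide_hydrogen_geometry(self, helix10):
        p = add_polar_hydrogens(helix10)
        mask = p.residue_mask("A", 2)
        n = p.coords[mask & (p.name == "N")][0]
        h = p.coords[mask & (p.name == "H")][0]
        ca = p.coords[mask & (p.name == "CA")][0]
        c_prev = p.coords[p.residue_mask("A", 1) & (p.name == "C")][0]
        assert np.linalg.norm(h - n) == pytest.approx(1.01, abs=1e-6)
        # coplanar with C_prev, N, CA
        normal = np.cross(c_prev - n, ca - n)
        normal /= np.linalg.norm(normal)
        assert abs(np.dot(h - n, normal)) < 1e-9

    def test_idempotent(self, helix10):
        once = add_polar_hydrogens(helix10)
        twice = add_polar_hydrogens(once)
        assert len(twice) == len(once)
        assert np.array_equal(once.coords, twice.coords)

    def test_serine_hydroxyl_points_to_nearest_acceptor(self):
        """With two candidate acceptors at different distances, the placed
        O–H hydrogen ends up closer to the nearer one; enumerating both
        orientations confirms the choice."""
        dimer, _ = make_toy_dimer([("S", "A", 4.8, 10.0)])
        # add two isolated carbonyl acceptors near the serine OG
        mask = dimer.residue_mask("A", 2)
        og = dimer.coords[mask & (dimer.name == "OG")][0]
        cb = dimer.coords[mask & (dimer.name == "CB")][0]
        axis = (og - cb) / np.linalg.norm(og - cb)
        perp = np.cross(axis, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        near = og + 2.8 * (math.cos(math.radians(109.47)) * axis + math.sin(math.radians(109.47)) * perp)
        far = og + 4.5 * (math.cos(math.radians(109.47)) * axis - math.sin(math.radians(109.47)) * perp)
        probes = Structure(
            serial=[1, 2], name=["O", "O"], element=["O", "O"],
            coords=[near, far], res_id=[50, 51], res_name=["ALA", "ALA"],
            chain_id=["C", "C"],
        )
        combo = Structure(
            serial=np.arange(1, len(dimer) + 2 + 1),
            name=np.concatenate([dimer.name, probes.name]),
            element=np.concatenate([dimer.element, probes.element]),
            coords=np.vstack([dimer.coords, probes.coords]),
            res_id=np.concatenate([dimer.res_id, probes.res_id]),
            res_name=np.concatenate([dimer.res_name, probes.res_name]),
            chain_id=np.concatenate([dimer.chain_id, probes.chain_id]),
        )
        p = add_polar_hydrogens(combo)
        hg = p.coords[p.residue_mask("A", 2) & (p.name == "HG")][0]
        assert np.linalg.norm(hg - near) < np.linalg.norm(hg - far)


class TestDetection:
    def test_constructed_geometries(self):
        inside, _ = make_toy_dimer([("A", "A", 2.9, 0.0)])
        outside, _ = make_toy_dimer([("A", "A", 3.05, 0.0)])
        n_in = len(detect_hbonds(add_polar_hydrogens(inside), between=({"A"}, {"B"})))
        n_out = len(detect_hbonds(add_polar_hydrogens(outside), between=({"A"}, {"B"})))
        assert n_in == 1
        assert n_out == 0

    def test_cutoffs_are_inclusive_at_the_boundary(self):
        dimer, man = make_toy_dimer([("A", "A", 3.0, 20.0)])
        bonds = detect_hbonds(add_polar_hydrogens(dimer), between=({"A"}, {"B"}))
        assert {b.pair for b in bonds} == set(man.pair_keys())

    def test_angle_beyond_cutoff_rejected(self):
        dimer, _ = make_toy_dimer([("A", "A", 2.8, 25.0)])
        assert detect_hbonds(add_polar_hydrogens(dimer), between=({"A"}, {"B"})) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle_on_random_fixtures(self, seed):
        """Exhaustive O(N²) enumeration over all donor/acceptor pairs finds
        exactly the same bond set as the accelerated detector, across
        jittered helices, dimers and randomized cutoffs."""
        rng = np.random.default_rng(seed)
        if seed % 2:
            base, _ = make_toy_dimer(
                [("A", "S", 2.9, 10.0), ("S", "A", 2.8, 15.0), ("A", "A", 3.1, 5.0)]
            )
        else:
            base = make_helix_peptide(8, "ASNQA" + "KDE")
        frame = add_polar_hydrogens(base)
        frame.coords = frame.coords + rng.normal(0, 0.25, size=frame.coords.shape)
        crit = HBondCriterion(
            d_max=float(rng.uniform(2.5, 3.6)),
            theta_max=float(rng.uniform(10.0, 40.0)),
            angle_convention="donor" if seed % 3 else "linearity",
        )
        got = hbond_atom_triples(frame, detect_hbonds(frame, crit))
        assert got == brute_force_hbonds(frame, crit)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        dimer, _ = make_toy_dimer([("A", "A", 2.8, 5.0), ("S", "A", 2.95, 18.0)])
        p = add_polar_hydrogens(dimer)
        before = {(b.pair, round(b.distance, 6), round(b.angle, 6))
                  for b in detect_hbonds(p)}
        rot = Rotation.from_euler("xyz", [31.0, -57.0, 111.0], degrees=True)
        moved = p.copy()
        moved.coords = rot.apply(moved.coords) + np.array([5.0, -3.0, 11.0])
        after = {(b.pair, round(b.distance, 6), round(b.angle, 6))
                 for b in detect_hbonds(moved)}
        assert before == after


class TestOccupancy:
    def test_counting_over_constructed_frames(self):
        bound, man = make_toy_dimer([("A", "A", 2.8, 5.0)])
        broken = bound.copy()
        broken.coords = broken.coords.copy()
        b_mask = broken.chain_id == "B"
        broken.coords[b_mask] += np.array([8.0, 0.0, 0.0])
        frames = [bound.copy() for _ in range(7)] + [broken.copy() for _ in range(3)]
        ens = Ensemble(frames=frames, source="trajectory")
        occ = occupancy(ens, between=({"A"}, {"B"}))
        target = [o for o in occ if o.pair == man.pair_keys()[0]]
        assert len(target) == 1
        assert target[0].occupancy == pytest.approx(0.7)
        assert target[0].frames_present == 7 and target[0].frames_total == 10

    def test_occupancies_are_proper_fractions(self):
        dimer, _ = make_toy_dimer([("A", "A", 2.8, 5.0), ("A", "A", 2.95, 15.0)])
        ens = make_jitter_ensemble(dimer, sigma=0.2, n_frames=40, seed=2)
        for o in occupancy(ens):
            assert 0.0 <= o.occupancy <= 1.0
            assert o.frames_present <= o.frames_total

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            occupancy(Ensemble(frames=[], source="trajectory"))


TABLE_OCCUPANCIES = [0.39, 0.74, 0.43, 0.59, 0.54, 0.23, 0.38, 0.37, 0.44]


def _occ(value, idx):
    return HBondOccupancy(
        pair=pair_key(("A", idx, "side-chain"), ("B", 100 + idx, "side-chain")),
        frames_present=int(round(value * 100)),
        frames_total=100,
    )


class TestDominantBonds:
    def test_twenty_percent_threshold_keeps_nine(self):
        occs = [_occ(v, i) for i, v in enumerate(TABLE_OCCUPANCIES + [0.12])]
        kept = dominant_bonds(occs, threshold=0.20)
        assert len(kept) == 9
        assert kept[0].occupancy == pytest.approx(0.74)
        values = [o.occupancy for o in kept]
        assert values == sorted(values, reverse=True)

    def test_threshold_one_keeps_only_full_occupancy(self):
        occs = [_occ(v, i) for i, v in enumerate([1.0, 0.99, 0.5])]
        kept = dominant_bonds(occs, threshold=1.0)
        assert kept == []  # strictly-above semantics: nothing exceeds 1.0

    def test_threshold_zero_keeps_all(self):
        occs = [_occ(v, i) for i, v in enumerate(TABLE_OCCUPANCIES)]
        assert len(dominant_bonds(occs, threshold=0.0)) == len(occs)


class TestCountWtBonds:
    def test_toy_dimer_full_count(self, dimer3):
        dimer, man = dimer3
        assert count_wt_bonds(dimer, man.pair_keys()) == 3

    def test_zero_when_interface_removed(self, dimer3):
        dimer, man = dimer3
        apart = dimer.copy()
        apart.coords = apart.coords.copy()
        apart.coords[apart.chain_id == "B"] += np.array([50.0, 0.0, 0.0])
        assert count_wt_bonds(apart, man.pair_keys()) == 0

    def test_monotone_under_polar_atom_deletion(self, dimer3):
        dimer, man = dimer3
        keys = man.pair_keys()
        full = count_wt_bonds(dimer, keys)
        # delete one acceptor module's carbonyl oxygen
        drop = ~((dimer.chain_id == "B") & (dimer.res_id == 1) & (dimer.name == "O"))
        reduced = count_wt_bonds(dimer.subset(drop), keys)
        assert reduced <= full
        assert reduced == full - 1


class TestSaltBridge:
    @staticmethod
    def _pair(acid_name, acid_atoms, base_name, base_atoms):
        names = [a for a, _ in acid_atoms] + [a for a, _ in base_atoms]
        xyz = [x for _, x in acid_atoms] + [x for _, x in base_atoms]
        n1 = len(acid_atoms)
        return Structure(
            serial=np.arange(1, len(names) + 1),
            name=names,
            element=[n[0] for n in names],
            coords=np.array(xyz, dtype=float),
            res_id=[1] * n1 + [2] * len(base_atoms),
            res_name=[acid_name] * n1 + [base_name] * len(base_atoms),
            chain_id=["A"] * len(names),
        )

    def test_constructed_glu_lys_distance(self):
        s = self._pair(
            "GLU",
            [("OE1", [0.0, 1.0, 0.0]), ("OE2", [0.0, -1.0, 0.0])],
            "LYS",
            [("NZ", [3.0, 0.0, 0.0])],
        )
        assert salt_bridge_distance(s, ("A", 1), ("A", 2)) == pytest.approx(3.0)

    def test_symmetric_under_oxygen_swap(self):
        a = self._pair(
            "GLU",
            [("OE1", [0.0, 1.0, 0.3]), ("OE2", [0.2, -1.0, 0.0])],
            "LYS", [("NZ", [3.1, 0.4, 0.0])],
        )
        b = self._pair(
            "GLU",
            [("OE1", [0.2, -1.0, 0.0]), ("OE2", [0.0, 1.0, 0.3])],
            "LYS", [("NZ", [3.1, 0.4, 0.0])],
        )
        assert salt_bridge_distance(a, ("A", 1), ("A", 2)) == pytest.approx(
            salt_bridge_distance(b, ("A", 1), ("A", 2))
        )

    def test_arginine_center_of_mass_matches_hand_calculation(self):
        ne, nh1, nh2 = [4.0, 0.0, 0.0], [5.0, 1.0, 0.0], [5.0, -1.0, 0.5]
        s = self._pair(
            "GLU",
            [("OE1", [0.0, 0.6, 0.0]), ("OE2", [0.0, -0.6, 0.0])],
            "ARG",
            [("NE", ne), ("NH1", nh1), ("NH2", nh2)],
        )
        com_o = np.array([0.0, 0.0, 0.0])
        com_n = (np.array(ne) + np.array(nh1) + np.array(nh2)) / 3.0
        assert salt_bridge_distance(s, ("A", 1), ("A", 2)) == pytest.approx(
            float(np.linalg.norm(com_o - com_n))
        )

    def test_wrong_residue_type_rejected(self, helix10):
        with pytest.raises(ValueError, match="not an acidic"):
            salt_bridge_distance(helix10, ("A", 1), ("A", 2))
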