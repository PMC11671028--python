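import numpy as np
import pytest

from mumiscan import (
    SasaSpec,
    compare_stats,
    delta_rsa,
    ensemble_rsa_stats,
    rsa,
    sasa_atoms,
    sasa_total,
    split_complex,
)
from mumiscan.sasa import RSAStats, MAX_ASA_THEORETICAL
from mumiscan.fixtures import (
    _peptide,
    make_helix_peptide,
    make_jitter_ensemble,
    make_sphere_cage,
    make_toy_dimer,
)
from mumiscan.structure_io import Ensemble, Structure


def single_atom(element="C"):
    return Structure(
        serial=[1], name=["C1"], element=[element], coords=[[0.0, 0.0, 0.0]],
        res_id=[1], res_name=["LIG"], chain_id=["A"], hetero=[True],
    )


class TestSasaAtoms:
    def test_isolated_sphere_matches_analytic_area(self):
        a = sasa_atoms(single_atom(), SasaSpec())
        exact = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert a[0] == pytest.approx(exact, rel=0.01)

    def test_distant_atoms_are_additive(self):
        s = Structure(
            serial=[1, 2], name=["C1", "C2"], element=["C", "C"],
            coords=[[0, 0, 0], [100.0, 0, 0]], res_id=[1, 2],
            res_name=["LIG", "LIG"], chain_id=["A", "A"], hetero=[True, True],
        )
        a = sasa_atoms(s)
        iso = sasa_atoms(single_atom())[0]
        assert a[0] == pytest.approx(iso) and a[1] == pytest.approx(iso)

    def test_fully_caged_atom_has_zero_area(self):
        cage = make_sphere_cage(shell_distance=2.0)
        a = sasa_atoms(cage)
        assert a[0] == 0.0

    def test_point_doubling_convergence(self, helix10):
        t1 = sasa_atoms(helix10, SasaSpec(n_sphere_points=960)).sum()
        t2 = sasa_atoms(helix10, SasaSpec(n_sphere_points=1920)).sum()
        assert abs(t2 - t1) / t1 < 0.005

    def test_rotation_translation_invariance(self, helix10):
        from scipy.spatial.transform import Rotation

        t1 = sasa_total(helix10)
        moved = helix10.copy()
        rot = Rotation.from_euler("zyx", [17.0, 121.0, -49.0], degrees=True)
        moved.coords = rot.apply(moved.coords) + np.array([3.0, -7.0, 2.0])
        t2 = sasa_total(moved)
        assert t2 == pytest.approx(t1, rel=1e-3)

    def test_unknown_element_is_reported(self):
        odd = single_atom(element="Xx")
        with pytest.raises(ValueError, match="Xx"):
            sasa_atoms(odd)

    def test_agrees_with_independent_implementation(self, helix10):
        """Cross-check the in-package Shrake–Rupley against an independent
        library implementation on the same radii."""
        import biotite.structure as struc

        from mumiscan.structure_io import _to_atom_array

        ours = sasa_total(helix10)
        theirs = float(np.nansum(struc.sasa(
            _to_atom_array(helix10), probe_radius=1.4, point_number=960,
            vdw_radii="Single",
        )))
        assert ours == pytest.approx(theirs, rel=0.01)


class TestComplexInequality:
    def test_complex_sasa_below_sum_of_parts(self, dimer3):
        dimer, _ = dimer3
        focal, partner = split_complex(dimer, {"A"})
        whole = sasa_total(dimer)
        parts = sasa_total(focal) + sasa_total(partner)
        assert whole < parts

    def test_equality_without_contact(self):
        dimer, _ = make_toy_dimer([("A", "A", 2.8, 5.0)])
        apart = dimer.copy()
        apart.coords = apart.coords.copy()
        apart.coords[apart.chain_id == "B"] += np.array([200.0, 0.0, 0.0])
        focal, partner = split_complex(apart, {"A"})
        assert sasa_total(apart) == pytest.approx(
            sasa_total(focal) + sasa_total(partner), rel=1e-9
        )


class TestRsa:
    def test_extended_tripeptide_central_residue_near_full_exposure(self):
        gxg = _peptide("GAG", phi=-140.0, psi=135.0)
        profile = rsa(gxg)
        ala = profile[("A", 2)]
        # the reference scale is defined on this very construction, so the
        # central alanine should sit near 100 percent
        assert 70.0 < ala < 115.0

    def test_buried_residue_in_dense_globule(self):
        helix = make_helix_peptide(6)
        # bury the middle by surrounding the peptide with an occluding shell
        from mumiscan.sasa import _fibonacci_sphere

        center = helix.coords.mean(axis=0)
        shell = []
        for radius in (7.0, 8.5):
            shell.extend(center + radius * _fibonacci_sphere(900))
        occluders = Structure(
            serial=np.arange(1, len(shell) + 1),
            name=[f"C{i}" for i in range(len(shell))],
            element=["C"] * len(shell), coords=np.array(shell),
            res_id=[999] * len(shell), res_name=["LIG"] * len(shell),
            chain_id=["Z"] * len(shell), hetero=[True] * len(shell),
        )
        combo = Structure(
            serial=np.arange(1, len(helix) + len(occluders) + 1),
            name=np.concatenate([helix.name, occluders.name]),
            element=np.concatenate([helix.element, occluders.element]),
            coords=np.vstack([helix.coords, occluders.coords]),
            res_id=np.concatenate([helix.res_id, occluders.res_id]),
            res_name=np.concatenate([helix.res_name, occluders.res_name]),
            chain_id=np.concatenate([helix.chain_id, occluders.chain_id]),
        )
        buried = rsa(combo)[("A", 3)]
        exposed = rsa(helix)[("A", 3)]
        assert buried < 5.0 < exposed

    def test_delta_rsa_interface_residues_lose_exposure(self, dimer3):
        dimer, man = dimer3
        focal, _ = split_complex(dimer, {"A"})
        unbound = rsa(focal)
        bound_full = rsa(dimer)
        bound = type(unbound)(
            values={k: v for k, v in bound_full.values.items() if k[0] == "A"},
            res_names={k: v for k, v in bound_full.res_names.items() if k[0] == "A"},
        )
        delta = delta_rsa(unbound, bound)
        donor_residues = {("A", b["donor_res"]) for b in man.bonds}
        for key in donor_residues:
            assert delta[key] < 0.0

    def test_delta_rsa_identity_and_mismatch(self, helix10):
        p = rsa(helix10)
        assert all(v == 0.0 for v in delta_rsa(p, p).values())
        q = rsa(make_helix_peptide(9))
        with pytest.raises(ValueError, match="residue sets differ"):
            delta_rsa(p, q)


class TestEnsembleStats:
    def test_identical_frames_have_zero_sigma(self, helix10):
        ens = Ensemble(frames=[helix10.copy() for _ in range(4)],
                       source="trajectory")
        stats = ensemble_rsa_stats(ens)
        assert all(s == 0.0 for s in stats.sigma.values())

    def test_two_frame_hand_calculation(self, helix10):
        jit = make_jitter_ensemble(helix10, sigma=0.4, n_frames=2, seed=9)
        stats = ensemble_rsa_stats(jit)
        p0, p1 = rsa(jit.frames[0]), rsa(jit.frames[1])
        key = ("A", 5)
        assert stats.mean[key] == pytest.approx((p0[key] + p1[key]) / 2.0)
        assert stats.sigma[key] == pytest.approx(abs(p0[key] - p1[key]) / 2.0)

    def test_single_frame_rejected(self, helix10):
        with pytest.raises(ValueError, match="at least 2"):
            ensemble_rsa_stats(Ensemble(frames=[helix10], source="trajectory"))


class TestCompareStats:
    @staticmethod
    def _stats(rng, n=30):
        keys = [("A", i + 1) for i in range(n)]
        return RSAStats(
            mean={k: float(rng.uniform(0, 100)) for k in keys},
            sigma={k: float(rng.uniform(0, 20)) for k in keys},
            n_frames=10,
        )

    def test_self_comparison_is_perfect(self):
        s = self._stats(np.random.default_rng(1))
        _, r2_mean, r2_sigma = compare_stats(s, s)
        assert r2_mean == pytest.approx(1.0)
        assert r2_sigma == pytest.approx(1.0)

    def test_permutation_destroys_pairing(self):
        rng = np.random.default_rng(2)
        a = self._stats(rng, n=120)
        keys = list(a.mean)
        perm = rng.permutation(len(keys))
        b = RSAStats(
            mean={keys[i]: a.mean[keys[int(j)]] for i, j in enumerate(perm)},
            sigma={keys[i]: a.sigma[keys[int(j)]] for i, j in enumerate(perm)},
            n_frames=10,
        )
        _, r2_mean, _ = compare_stats(a, b)
        assert r2_mean < 0.15

    def test_noiseless_linear_relation(self):
        keys = [("A", i) for i in range(1, 6)]
        a = RSAStats(mean={k: float(i) for i, k in enumerate(keys)},
                     sigma={k: 1.0 for k in keys}, n_frames=2)
        b = RSAStats(mean={k: 3.0 * float(i) + 2.0 for i, k in enumerate(keys)},
                     sigma={k: 1.0 for k in keys}, n_frames=2)
        table, r2_mean, _ = compare_stats(a, b, allosteric=(2, 3))
        assert r2_mean == pytest.approx(1.0)
        assert bool(table[table["res_id"] == 2]["allosteric"].item())
        assert not bool(table[table["res_id"] == 4]["allosteric"].item())
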