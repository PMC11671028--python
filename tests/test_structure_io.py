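import numpy as np
import pytest

from mumiscan import (
    Ensemble,
    read_pdb,
    rmsd_heavy,
    split_complex,
    write_pdb,
)
from mumiscan.structure_io import PDBParseError, read_ensemble
from mumiscan.fixtures import _peptide, make_helix_peptide, make_jitter_ensemble


def test_round_trip_is_coordinate_stable(tmp_path, helix10):
    path = tmp_path / "helix.pdb"
    write_pdb(helix10, path)
    back = read_pdb(path)
    assert back.chains == helix10.chains
    assert len(back) == len(helix10)
    assert np.allclose(back.coords, helix10.coords, atol=1e-3)
    # second round trip is exact (fixed-column quantization is idempotent)
    path2 = tmp_path / "helix2.pdb"
    write_pdb(back, path2)
    again = read_pdb(path2)
    assert np.array_equal(again.coords, back.coords)


def test_multi_model_write_and_model_selection(tmp_path, helix10):
    ens = make_jitter_ensemble(helix10, sigma=0.2, n_frames=3, seed=5)
    path = tmp_path / "ens.pdb"
    write_pdb(ens, path)
    back = read_ensemble(path)
    assert len(back) == 3
    second = read_pdb(path, model=2)
    assert np.allclose(second.coords, ens.frames[1].coords, atol=1e-3)
    assert not np.allclose(second.coords, ens.frames[0].coords, atol=1e-3)


ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       1.500   0.100   0.000  0.40  0.00           C
ATOM      4  C   ALA A   1       2.009   1.400   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
END
"""


def test_altloc_resolved_to_highest_occupancy(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    s = read_pdb(path)
    ca = s.coords[s.name == "CA"]
    assert ca.shape == (1, 3)
    # the 0.60-occupancy conformer wins over the 0.40 one
    assert np.allclose(ca[0], [1.458, 0.0, 0.0], atol=1e-3)


INSERTION_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   ALA A   1A      3.300   1.500   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   1A      4.700   1.500   0.000  1.00  0.00           C
ATOM      7  C   ALA A   1A      5.300   2.900   0.000  1.00  0.00           C
ATOM      8  O   ALA A   1A      4.600   3.900   0.000  1.00  0.00           O
END
"""


def test_insertion_codes_are_rejected(tmp_path):
    path = tmp_path / "icode.pdb"
    path.write_text(INSERTION_PDB)
    with pytest.raises(PDBParseError, match="insertion code"):
        read_pdb(path)


class TestSplitComplex:
    def test_partition_conserves_solute_atoms(self, dimer3):
        dimer, _ = dimer3
        focal, partner = split_complex(dimer, {"A"})
        assert len(focal) + len(partner) == int(dimer.solute_mask.sum())
        assert set(focal.chains) == {"A"}
        assert set(partner.chains) == {"B"}

    def test_unknown_chain_lists_available(self, dimer3):
        dimer, _ = dimer3
        with pytest.raises(ValueError, match="available chains"):
            split_complex(dimer, {"Z"})

    def test_all_chains_focal_is_degenerate(self, dimer3):
        dimer, _ = dimer3
        with pytest.raises(ValueError, match="partner is empty"):
            split_complex(dimer, {"A", "B"})

    def test_reference_complex_chain_sizes(self):
        """A 56-residue binder chain and a 206-residue partner chain split
        into structures of exactly those residue counts."""
        a = _peptide("A" * 56, phi=-140.0, psi=135.0, chain_id="A")
        b = _peptide("A" * 206, phi=-140.0, psi=135.0, chain_id="B",
                     offset=np.array([0.0, 40.0, 0.0]))
        combo = _concat(a, b)
        focal, partner = split_complex(combo, {"A"})
        assert len(focal.residue_ids()) == 56
        assert len(partner.residue_ids()) == 206


def _concat(a, b):
    from mumiscan.structure_io import Structure

    return Structure(
        serial=np.arange(1, len(a) + len(b) + 1),
        name=np.concatenate([a.name, b.name]),
        element=np.concatenate([a.element, b.element]),
        coords=np.vstack([a.coords, b.coords]),
        res_id=np.concatenate([a.res_id, b.res_id]),
        res_name=np.concatenate([a.res_name, b.res_name]),
        chain_id=np.concatenate([a.chain_id, b.chain_id]),
    )


class TestRmsd:
    def test_identity_is_zero(self, helix10):
        assert rmsd_heavy(helix10, helix10) == 0.0

    def test_pure_translation(self, helix10):
        b = helix10.copy()
        b.coords = b.coords + np.array([3.0, 0.0, 0.0])
        assert rmsd_heavy(helix10, b) == pytest.approx(3.0, abs=1e-9)
        assert rmsd_heavy(helix10, b, superpose_first=True) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry_and_superposition_bound(self, helix10):
        rng = np.random.default_rng(7)
        b = helix10.copy()
        b.coords = b.coords + rng.normal(0, 0.5, size=b.coords.shape)
        assert rmsd_heavy(helix10, b) == pytest.approx(rmsd_heavy(b, helix10))
        assert rmsd_heavy(helix10, b, superpose_first=True) <= rmsd_heavy(helix10, b) + 1e-12

    def test_superposition_matches_rotation_grid_oracle(self):
        """The closed-form fit reaches (within sampling error) the minimum
        found by brute-force search over random rigid rotations."""
        from scipy.spatial.transform import Rotation

        from mumiscan.structure_io import Structure

        rng = np.random.default_rng(11)
        xa = rng.normal(0, 3, size=(10, 3))
        xb = xa + rng.normal(0, 0.4, size=(10, 3))

        def as_structure(x):
            n = len(x)
            return Structure(
                serial=np.arange(1, n + 1), name=[f"C{i}" for i in range(n)],
                element=["C"] * n, coords=x, res_id=[1] * n,
                res_name=["LIG"] * n, chain_id=["A"] * n, hetero=[True] * n,
            )

        a, b = as_structure(xa), as_structure(xb)
        fitted = rmsd_heavy(a, b, superpose_first=True)
        # brute force: coarse random rotation sampling refined around the
        # incumbent with shrinking perturbations (no closed form involved)
        cb = xb - xb.mean(axis=0)
        ca = xa - xa.mean(axis=0)

        def score(rot):
            d = ca - rot.apply(cb)
            return float(np.sqrt((d ** 2).sum(axis=1).mean()))

        rng2 = np.random.default_rng(3)
        best_rot = min(Rotation.random(500, rng=rng2), key=score)
        best = score(best_rot)
        scale = 0.5
        for _ in range(12):
            for vec in rng2.normal(0, scale, size=(200, 3)):
                cand = Rotation.from_rotvec(vec) * best_rot
                s = score(cand)
                if s < best:
                    best, best_rot = s, cand
            scale *= 0.5
        assert fitted <= best + 1e-9
        assert fitted == pytest.approx(best, abs=0.01)

    def test_atom_mismatch_names_offender(self, helix10):
        b = make_helix_peptide(10, "A" * 9 + "G")
        with pytest.raises(ValueError, match="unpaired|mismatch"):
            rmsd_heavy(helix10, b)


def test_mutant_collection_ensemble_allows_varying_atom_counts(helix10):
    other = make_helix_peptide(10, "A" * 9 + "W")
    ens = Ensemble(frames=[helix10, other], source="mutant-collection")
    assert len(ens) == 2
    with pytest.raises(ValueError):
        Ensemble(frames=[helix10, other], source="trajectory")
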