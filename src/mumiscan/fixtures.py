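"""Deterministic synthetic structures and ensembles with known ground truth.

Every analysis stage of the pipeline is testable without downloading any
crystal structure: ideal α-helical peptides exercise backbone geometry
and i→i+4 hydrogen bonding, two-chain toy dimers realize prescribed
donor–acceptor distances and angles across an interface, and jittered
ensembles (i.i.d. Gaussian coordinate noise, seeded) give occupancy and
contact frequencies with generator-side bookkeeping.  Jitter is not
physical dynamics — it is uncorrelated noise, sufficient to exercise the
counting statistics, and nothing more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mutator import MODAL_CHI1, SideChainTemplate, _graft_coords
from .structure_io import ONE_TO_THREE, Ensemble, Structure

__all__ = [
    "make_helix_peptide",
    "make_toy_dimer",
    "make_jitter_ensemble",
    "make_sphere_cage",
    "synthetic_experiment_table",
    "ToyDimerManifest",
]

# ideal backbone geometry (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
# N-CA-C at the tight end of the helical range so the i→i+4 amide
# geometry closes under the 3.0 Å donor–acceptor criterion
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 110.0, 116.2, 121.7, 120.5
HELIX_PHI, HELIX_PSI, OMEGA = -57.0, -47.0, 180.0


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d given a–b–c using internal coordinates."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_backbone(
    n_residues: int, phi: float, psi: float
) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O coordinates per residue for a (φ, ψ) repeat."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    ang = math.radians(A_N_CA_C)
    c0 = ca0 + B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_residues):
        prev = res[-1]
        n = _nerf(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi)
        ca = _nerf(prev["CA"], prev["C"], n, B_N_CA, A_C_N_CA, OMEGA)
        c = _nerf(prev["C"], n, ca, B_CA_C, A_N_CA_C, phi)
        res.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: anti to the next amide nitrogen, in the peptide plane
    for i, r in enumerate(res):
        if i + 1 < len(res):
            r["O"] = _nerf(res[i + 1]["N"], r["CA"], r["C"],
                           B_C_O, A_CA_C_O, 180.0)
        else:
            r["O"] = _nerf(r["N"], r["CA"], r["C"], B_C_O, A_CA_C_O, psi + 180.0)
    return res


def _assemble(residue_atoms, chain_id: str, res_names, start_id: int = 1,
              offset: np.ndarray | None = None) -> Structure:
    names, elements, xyz, rids, rnames, cids = [], [], [], [], [], []
    for i, atoms in enumerate(residue_atoms):
        for name, coord in atoms:
            names.append(name)
            elements.append("S" if name.startswith("S")
                            else "O" if name.startswith("O")
                            else "N" if name.startswith("N") else "C")
            xyz.append(coord if offset is None else coord + offset)
            rids.append(start_id + i)
            rnames.append(res_names[i])
            cids.append(chain_id)
    return Structure(
        serial=np.arange(1, len(names) + 1),
        name=names, element=elements, coords=np.array(xyz),
        res_id=rids, res_name=rnames, chain_id=cids,
    )


def _peptide(sequence: str, phi: float, psi: float, chain_id: str = "A",
             start_id: int = 1, offset: np.ndarray | None = None) -> Structure:
    bb = _build_backbone(len(sequence), phi, psi)
    residue_atoms = []
    res_names = []
    for i, aa in enumerate(sequence):
        rname = ONE_TO_THREE[aa]
        res_names.append(rname)
        atoms = [("N", bb[i]["N"]), ("CA", bb[i]["CA"]),
                 ("C", bb[i]["C"]), ("O", bb[i]["O"])]
        if rname != "GLY":
            template = SideChainTemplate.load(rname)
            sc_names, sc_xyz = _graft_coords(
                template, bb[i]["N"], bb[i]["CA"], bb[i]["C"],
                MODAL_CHI1.get(rname),
            )
            atoms += list(zip(sc_names, sc_xyz))
        residue_atoms.append(atoms)
    return _assemble(residue_atoms, chain_id, res_names, start_id, offset)


def make_helix_peptide(n_residues: int, sequence: str | None = None) -> Structure:
    """Ideal α-helical peptide (φ = −57°, ψ = −47°, standard bond geometry).

    Defaults to poly-alanine.  For n ≥ 5 the i→i+4 backbone hydrogen
    bonds satisfy the 3.0 Å / 20° criterion once amide hydrogens are
    added.  Fully deterministic.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length does not match n_residues")
    return _peptide(sequence, HELIX_PHI, HELIX_PSI, chain_id="A")


@dataclass
class ToyDimerManifest:
    """Intended interface bonds of a toy dimer: one entry per prescription."""

    bonds: list[dict]

    def pair_keys(self):
        from .hbond import pair_key

        return [
            pair_key(
                (b["donor_chain"], b["donor_res"],
                 b.get("donor_moiety", "backbone")),
                (b["acceptor_chain"], b["acceptor_res"],
                 b.get("acceptor_moiety", "backbone")),
            )
            for b in self.bonds
        ]


def make_toy_dimer(
    hbond_specs: list[tuple[str, str, float, float]],
    spacing: float = 12.0,
) -> tuple[Structure, ToyDimerManifest]:
    """Two-chain complex realizing prescribed backbone hydrogen-bond geometry.

    Each spec ``(donor_res_type, acceptor_res_type, distance, angle)``
    places one single-residue "acceptor module" on chain B so that its
    carbonyl oxygen sits exactly at the given donor–acceptor distance
    and donor-vertex angle from an amide N–H of chain A.  Chain A is an
    extended strand with one interior donor residue per spec, separated
    so the prescriptions do not interfere.  Returns the structure and a
    manifest of intended bonds.
    """
    from .hbond import NH_BOND, _bisector_h, _unit

    if not hbond_specs:
        raise ValueError("need at least one hydrogen-bond spec")
    for k, (_, _, d, theta) in enumerate(hbond_specs):
        if d <= 0 or not 0 <= theta < 90:
            raise ValueError(f"infeasible spec {k}: distance {d}, angle {theta}")

    # chain A: extended strand, donors at interior residues 2..n+1
    seq_a = "G" + "".join(s[0] for s in hbond_specs) + "G"
    chain_a = _peptide(seq_a, phi=-140.0, psi=135.0, chain_id="A")

    b_modules = []
    b_names = []
    manifest = []
    for k, (donor_aa, acceptor_aa, dist, theta) in enumerate(hbond_specs):
        donor_res = k + 2  # interior residue of chain A
        mask = chain_a.residue_mask("A", donor_res)
        get = lambda nm: chain_a.coords[mask & (chain_a.name == nm)][0]
        n_xyz, ca_xyz = get("N"), get("CA")
        prev_mask = chain_a.residue_mask("A", donor_res - 1)
        c_prev = chain_a.coords[prev_mask & (chain_a.name == "C")][0]
        h_dir = _unit(_bisector_h(n_xyz, c_prev, ca_xyz, bond=1.0) - n_xyz)
        # rotate the D→H direction by theta within a deterministic plane
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, h_dir)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        perp = _unit(np.cross(h_dir, ref))
        a_dir = (
            math.cos(math.radians(theta)) * h_dir
            + math.sin(math.radians(theta)) * perp
        )
        o_target = n_xyz + dist * a_dir

        # acceptor module: ideal residue posed so its O sits at the target
        # with its C=O pointing back along the approach direction
        rname = ONE_TO_THREE[acceptor_aa]
        import biotite.structure.info as info

        arr = info.residue(rname)
        heavy = arr[arr.element != "H"]
        t_names = [str(x) for x in heavy.atom_name]
        t_xyz = np.asarray(heavy.coord, dtype=float)
        i_o, i_c = t_names.index("O"), t_names.index("C")
        from scipy.spatial.transform import Rotation

        oc = _unit(t_xyz[i_c] - t_xyz[i_o])
        rot, _ = Rotation.align_vectors(a_dir[None, :], oc[None, :])
        posed = rot.apply(t_xyz - t_xyz[i_o]) + o_target
        b_modules.append(list(zip(t_names, posed)))
        b_names.append(rname)
        manifest.append({
            "donor_chain": "A", "donor_res": donor_res,
            "donor_aa": donor_aa,
            "acceptor_chain": "B", "acceptor_res": k + 1,
            "acceptor_aa": acceptor_aa,
            "distance": dist, "angle": theta,
        })

    chain_b = _assemble(b_modules, "B", b_names, start_id=1)
    combined = Structure(
        serial=np.arange(1, len(chain_a) + len(chain_b) + 1),
        name=np.concatenate([chain_a.name, chain_b.name]),
        element=np.concatenate([chain_a.element, chain_b.element]),
        coords=np.vstack([chain_a.coords, chain_b.coords]),
        res_id=np.concatenate([chain_a.res_id, chain_b.res_id]),
        res_name=np.concatenate([chain_a.res_name, chain_b.res_name]),
        chain_id=np.concatenate([chain_a.chain_id, chain_b.chain_id]),
    )
    return combined, ToyDimerManifest(bonds=manifest)


# GB1 (56-residue C2 fragment of Streptococcal protein G), unbound form;
# the flagship system for full-scale runs and enumeration bookkeeping
GB1_SEQUENCE = "MTYKLILNGKTLKGETTTEAVDAATAEKVFKQYANDNGVDGEWTYDDATKTFTVTE"

# GB1 positions in close proximity to the IgG-Fc binding interface; the
# candidate set for the dynamic extension of selected mutants
GB1_BINDING_PROXIMAL_POSITIONS = (
    25, 27, 28, 29, 31, 32, 33, 35, 36, 40, 41, 42, 43, 54
)


def make_patterned_interface(
    two_bond_positions: tuple[int, ...] = (27, 28),
    one_bond_positions: tuple[int, ...] = (35, 39, 40, 42, 43),
    length: int = 56,
    distance: float = 2.8,
) -> tuple[Structure, ToyDimerManifest]:
    """Synthetic two-chain complex with a prescribed interface bond pattern.

    A purely synthetic stand-in for a real bound complex: chain A is an
    extended peptide of ``length`` residues (serine at the two-bond
    positions, alanine elsewhere) and chain B carries one single-residue
    acceptor module per prescribed bond, placed collinearly with the
    corresponding donor hydrogen at the given donor–acceptor distance.
    Positions in ``two_bond_positions`` receive both a backbone and a
    side-chain hydrogen bond; ``one_bond_positions`` receive a backbone
    bond.  Returns the complex and the manifest of designed bonds (with
    moieties recorded per bond).
    """
    from .hbond import add_polar_hydrogens, _unit

    seq = "".join(
        "S" if (i + 1) in two_bond_positions else "A" for i in range(length)
    )
    chain_a = _peptide(seq, phi=-140.0, psi=135.0, chain_id="A")
    protonated = add_polar_hydrogens(chain_a)

    def donor_direction(rid: int, heavy: str, hydrogen: str):
        mask = protonated.residue_mask("A", rid)
        x = protonated.coords[mask & (protonated.name == heavy)][0]
        h = protonated.coords[mask & (protonated.name == hydrogen)][0]
        return x, _unit(h - x)

    import biotite.structure.info as info

    arr = info.residue("ALA")
    heavy_arr = arr[arr.element != "H"]
    t_names = [str(x) for x in heavy_arr.atom_name]
    t_xyz = np.asarray(heavy_arr.coord, dtype=float)
    i_o, i_c = t_names.index("O"), t_names.index("C")
    from scipy.spatial.transform import Rotation

    oc = _unit(t_xyz[i_c] - t_xyz[i_o])

    modules, names, manifest = [], [], []

    def add_module(rid: int, heavy: str, hydrogen: str, moiety: str):
        x, d = donor_direction(rid, heavy, hydrogen)
        target = x + distance * d
        rot, _ = Rotation.align_vectors(d[None, :], oc[None, :])
        posed = rot.apply(t_xyz - t_xyz[i_o]) + target
        modules.append(list(zip(t_names, posed)))
        names.append("ALA")
        manifest.append({
            "donor_chain": "A", "donor_res": rid, "donor_aa": seq[rid - 1],
            "donor_moiety": moiety,
            "acceptor_chain": "B", "acceptor_res": len(modules),
            "acceptor_aa": "A", "acceptor_moiety": "backbone",
            "distance": distance, "angle": 0.0,
        })

    for rid in sorted(set(one_bond_positions) | set(two_bond_positions)):
        add_module(rid, "N", "H", "backbone")
    for rid in sorted(two_bond_positions):
        add_module(rid, "OG", "HG", "side-chain")

    chain_b = _assemble(modules, "B", names, start_id=1)
    combined = Structure(
        serial=np.arange(1, len(chain_a) + len(chain_b) + 1),
        name=np.concatenate([chain_a.name, chain_b.name]),
        element=np.concatenate([chain_a.element, chain_b.element]),
        coords=np.vstack([chain_a.coords, chain_b.coords]),
        res_id=np.concatenate([chain_a.res_id, chain_b.res_id]),
        res_name=np.concatenate([chain_a.res_name, chain_b.res_name]),
        chain_id=np.concatenate([chain_a.chain_id, chain_b.chain_id]),
    )
    bonds = [
        {**b} for b in manifest
    ]
    man = ToyDimerManifest(bonds=bonds)
    return combined, man


def make_jitter_ensemble(
    base: Structure, sigma: float, n_frames: int, seed: int = 0
) -> Ensemble:
    """Ensemble of seeded i.i.d. Gaussian-displaced copies of a structure."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        f = base.copy()
        f.coords = f.coords + rng.normal(0.0, sigma, size=f.coords.shape)
        frames.append(f)
    return Ensemble(frames=frames, source="trajectory")


def make_sphere_cage(
    center_element: str = "C", shell_distance: float = 2.0
) -> Structure:
    """One atom fully enclosed by a 26-neighbour cubic shell (SASA → 0)."""
    coords = [[0.0, 0.0, 0.0]]
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                v = np.array([dx, dy, dz], dtype=float)
                coords.append(list(shell_distance * v / np.linalg.norm(v)))
    n = len(coords)
    return Structure(
        serial=np.arange(1, n + 1),
        name=[f"C{i}" for i in range(n)],
        element=[center_element] * n,
        coords=np.array(coords),
        res_id=[1] * n,
        res_name=["LIG"] * n,
        chain_id=["A"] * n,
        hetero=[True] * n,
    )


def synthetic_experiment_table(
    matrix, noise_sigma: float = 0.0, seed: int = 0, cap: float = 9.0
):
    """Synthetic stand-in for an experimental ΔΔG table.

    Maps each mutant's maintained-bond count monotonically onto a
    destabilization energy — fewer maintained bonds, larger ΔΔG — and
    adds Gaussian noise of the given σ.  This is a synthetic construct
    for exercising the correlation machinery, not experimental data.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    long = matrix.long_form()
    n_max = max(matrix.n_wt_bonds, 1)
    ddg = (1.0 - long["n_hb"] / n_max) * cap
    ddg = ddg + rng.normal(0.0, noise_sigma, size=len(ddg))
    return pd.DataFrame({
        "position": long["position"],
        "wt": long["wt"],
        "mut": long["mut"],
        "ddg": ddg,
    })
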