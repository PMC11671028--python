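"""Single-point mutant enumeration and construction.

Mutants are built by backbone-preserving template side-chain replacement:
the mutated residue keeps its backbone atoms (N, CA, C, O and OXT if
present) at byte-identical coordinates, the old side chain is removed,
and an ideal side chain for the target amino acid is grafted into the
local frame defined by N/CA/C.  A single template conformer per residue
type is used, with the first side-chain torsion set to the modal rotamer
of standard rotamer surveys; strain left by the graft is relieved by the
subsequent minimization stage, and — when the graft itself produces hard
clashes — by a deterministic coarse sweep of the first two side-chain
torsions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import ClassVar, Iterable, Sequence

import numpy as np

from .structure_io import (
    ONE_TO_THREE,
    THREE_TO_ONE,
    Structure,
)

__all__ = [
    "MutationSpec",
    "SideChainTemplate",
    "enumerate_mutations",
    "apply_mutation",
    "detect_clashes",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

BACKBONE_SET = {"N", "CA", "C", "O", "OXT"}

# first/second side-chain torsion atom quadruples (heavy atoms)
CHI1_ATOMS = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "SER": "OG", "THR": "OG1", "TRP": "CG",
    "TYR": "CG", "VAL": "CG1",
}
CHI2_ATOMS = {
    "ARG": "CD", "GLN": "CD", "GLU": "CD", "ILE": "CD1", "LEU": "CD1",
    "LYS": "CD", "MET": "SD", "PHE": "CD1", "TRP": "CD1", "TYR": "CD1",
    "HIS": "ND1", "ASN": "OD1", "ASP": "OD1",
}

# modal chi1 (degrees) from standard rotamer surveys; gauche(-) dominates
MODAL_CHI1 = {
    "ARG": -67.0, "ASN": -65.0, "ASP": -70.0, "CYS": -65.0, "GLN": -65.0,
    "GLU": -67.0, "HIS": -63.0, "ILE": -61.0, "LEU": -65.0, "LYS": -67.0,
    "MET": -65.0, "PHE": -65.0, "SER": 64.0, "THR": 62.0, "TRP": -65.0,
    "TYR": -65.0, "VAL": 175.0,
}

CLASH_HARD_CUTOFF = 1.5  # Å; below this the graft is swept for relief


@dataclass(frozen=True)
class MutationSpec:
    """One substitution: 1-based position, WT and mutant 1-letter codes."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self):
        for aa, role in ((self.wt_aa, "wt"), (self.mut_aa, "mutant")):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"non-canonical {role} amino acid {aa!r}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"identity substitution {self.label}")

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @classmethod
    def from_label(cls, label: str) -> "MutationSpec":
        return cls(position=int(label[1:-1]), wt_aa=label[0], mut_aa=label[-1])


def enumerate_mutations(
    sequence: str, positions: Iterable[int] | None = None
) -> list[MutationSpec]:
    """All 19 non-identity substitutions at each (selected) position.

    ``positions`` are 1-based; default is every position of the sequence.
    The result is ordered by position, then alphabetically by mutant
    letter, and has exactly ``19 × n_positions`` entries.
    """
    if not sequence:
        raise ValueError("empty sequence")
    for i, aa in enumerate(sequence, start=1):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"non-canonical letter {aa!r} at position {i}")
    if positions is None:
        positions = range(1, len(sequence) + 1)
    specs = []
    for pos in positions:
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"position {pos} outside sequence of length {len(sequence)}")
        wt = sequence[pos - 1]
        for mut in AMINO_ACIDS:
            if mut != wt:
                specs.append(MutationSpec(position=pos, wt_aa=wt, mut_aa=mut))
    return specs


# ---------------------------------------------------------------------------
# Side-chain templates
# ---------------------------------------------------------------------------

@dataclass
class SideChainTemplate:
    """Ideal heavy-atom geometry for one residue type.

    Coordinates come from the bundled chemical component dictionary; the
    template is expressed in an arbitrary frame and re-posed onto a target
    backbone through a rigid fit on N/CA/C.  ``neighbors`` holds the
    heavy-atom bond graph used for torsion sweeps.
    """

    residue_name: str
    atom_names: list[str]
    coords: np.ndarray
    neighbors: dict[str, set[str]]

    _cache: ClassVar[dict] = {}

    @classmethod
    def load(cls, residue_name: str) -> "SideChainTemplate":
        if residue_name in cls._cache:
            return cls._cache[residue_name]
        import biotite.structure.info as info

        arr = info.residue(residue_name)
        heavy = arr.element != "H"
        arr = arr[heavy]
        names = [str(n) for n in arr.atom_name]
        neighbors: dict[str, set[str]] = {n: set() for n in names}
        bonds, _ = arr.bonds.get_all_bonds()
        for i, name in enumerate(names):
            for j in bonds[i]:
                if j >= 0:
                    neighbors[name].add(names[j])
        tmpl = cls(
            residue_name=residue_name,
            atom_names=names,
            coords=np.asarray(arr.coord, dtype=float),
            neighbors=neighbors,
        )
        cls._cache[residue_name] = tmpl
        return tmpl

    def index(self, name: str) -> int:
        return self.atom_names.index(name)

    def sidechain_names(self) -> list[str]:
        return [n for n in self.atom_names if n not in BACKBONE_SET]

    def atoms_beyond(self, proximal: str, distal: str) -> list[str]:
        """Heavy atoms on the far side of the proximal→distal bond."""
        seen = {proximal, distal}
        stack = [distal]
        out = []
        while stack:
            cur = stack.pop()
            for nb in sorted(self.neighbors[cur]):
                if nb not in seen:
                    seen.add(nb)
                    out.append(nb)
                    stack.append(nb)
        return out


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _rotate_about_axis(
    coords: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float
) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    return rot.apply(coords - origin) + origin


def _fit_template(template: SideChainTemplate, n, ca, c) -> np.ndarray:
    """Template coordinates posed so its N/CA/C matches the target frame."""
    from scipy.spatial.transform import Rotation

    src = np.array(
        [template.coords[template.index(a)] for a in ("N", "CA", "C")]
    )
    dst = np.array([n, ca, c])
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - mu_d, src - mu_s)
    return rot.apply(template.coords - mu_s) + mu_d


def _set_chi(
    names: list[str],
    coords: np.ndarray,
    template: SideChainTemplate,
    quad: tuple[str, str, str, str],
    moving: list[str],
    target_deg: float,
) -> np.ndarray:
    idx = {n: i for i, n in enumerate(names)}
    p = [coords[idx[a]] for a in quad]
    current = _dihedral(*p)
    delta = target_deg - current
    move_idx = [idx[m] for m in moving if m in idx]
    out = coords.copy()
    out[move_idx] = _rotate_about_axis(
        coords[move_idx], origin=p[2], axis=p[2] - p[1], angle_deg=delta
    )
    return out


def _graft_coords(
    template: SideChainTemplate, n, ca, c, chi1: float | None
) -> tuple[list[str], np.ndarray]:
    """Posed side-chain heavy atoms (names beyond the backbone) for a graft."""
    posed = _fit_template(template, n, ca, c)
    names = template.atom_names
    sc_names = template.sidechain_names()
    coords = posed.copy()
    res = template.residue_name
    if chi1 is not None and res in CHI1_ATOMS and res != "PRO":
        quad = ("N", "CA", "CB", CHI1_ATOMS[res])
        moving = template.atoms_beyond("CA", "CB")
        coords = _set_chi(names, coords, template, quad, moving, chi1)
    sc_idx = [names.index(s) for s in sc_names]
    return sc_names, coords[sc_idx]


def apply_mutation(
    structure: Structure,
    spec: MutationSpec,
    chain: str,
    relieve_clashes: bool = True,
) -> Structure:
    """Replace one residue's side chain, leaving every other atom untouched.

    The residue must currently be ``spec.wt_aa``; its backbone coordinates
    are preserved exactly and only its side chain is rebuilt.  Hydrogens
    of the mutated residue are dropped (re-protonation is a downstream
    concern).  Atom serial numbers are renumbered consecutively.

    When the grafted rotamer leaves heavy-atom contacts shorter than
    1.5 Å, χ1 (then χ2) is swept in 30° steps and the clash-minimal
    conformer kept, ties broken by the smallest torsion change.
    """
    res_mask = structure.residue_mask(chain, spec.position)
    if not res_mask.any():
        raise ValueError(f"no residue {spec.position} on chain {chain!r}")
    found_name = str(structure.res_name[res_mask][0])
    expected = ONE_TO_THREE[spec.wt_aa]
    if found_name != expected:
        raise ValueError(
            f"wild-type mismatch at {chain}:{spec.position}: "
            f"found {found_name}, expected {expected} ({spec.label})"
        )
    names_here = {str(n) for n in structure.name[res_mask]}
    missing = {"N", "CA", "C", "O"} - names_here
    if missing:
        raise ValueError(
            f"residue {chain}:{spec.position} missing backbone atoms {sorted(missing)}"
        )

    idx_res = np.where(res_mask)[0]
    keep_backbone = [
        i for i in idx_res
        if str(structure.name[i]) in BACKBONE_SET
    ]
    bb = {str(structure.name[i]): structure.coords[i] for i in keep_backbone}

    new_resname = ONE_TO_THREE[spec.mut_aa]
    template = SideChainTemplate.load(new_resname)
    chi1 = MODAL_CHI1.get(new_resname)
    sc_names, sc_coords = _graft_coords(
        template, bb["N"], bb["CA"], bb["C"], chi1
    )

    if relieve_clashes and sc_names:
        sc_coords = _relieve_graft_clashes(
            structure, res_mask, template, bb, sc_names, sc_coords, chi1
        )

    # assemble: all atoms before the residue, backbone (original order),
    # grafted side chain, all atoms after the residue
    first = int(idx_res[0])
    last = int(idx_res[-1])
    before = np.arange(len(structure)) < first
    after = np.arange(len(structure)) > last

    def cols(mask_or_idx):
        return (
            structure.name[mask_or_idx], structure.element[mask_or_idx],
            structure.coords[mask_or_idx], structure.res_id[mask_or_idx],
            structure.res_name[mask_or_idx], structure.chain_id[mask_or_idx],
            structure.hetero[mask_or_idx],
        )

    parts_name, parts_elem, parts_xyz = [], [], []
    parts_rid, parts_rname, parts_cid, parts_het = [], [], [], []

    for mask in (before,):
        nm, el, xy, ri, rn, ci, he = cols(mask)
        parts_name.append(nm); parts_elem.append(el); parts_xyz.append(xy)
        parts_rid.append(ri); parts_rname.append(rn); parts_cid.append(ci)
        parts_het.append(he)

    bb_names = [str(structure.name[i]) for i in keep_backbone]
    bb_xyz = np.array([structure.coords[i] for i in keep_backbone])
    res_names_col = bb_names + sc_names
    res_elem = [("S" if n.startswith("S") else "O" if n.startswith("O")
                 else "N" if n.startswith("N") else "C") for n in res_names_col]
    res_xyz = (
        np.vstack([bb_xyz, sc_coords]) if len(sc_names) else bb_xyz
    )
    n_res_atoms = len(res_names_col)
    parts_name.append(np.array(res_names_col, dtype="U6"))
    parts_elem.append(np.array(res_elem, dtype="U2"))
    parts_xyz.append(res_xyz)
    parts_rid.append(np.full(n_res_atoms, spec.position, dtype=np.int64))
    parts_rname.append(np.full(n_res_atoms, new_resname, dtype="U5"))
    parts_cid.append(np.full(n_res_atoms, chain, dtype="U4"))
    parts_het.append(np.zeros(n_res_atoms, dtype=bool))

    nm, el, xy, ri, rn, ci, he = cols(after)
    parts_name.append(nm); parts_elem.append(el); parts_xyz.append(xy)
    parts_rid.append(ri); parts_rname.append(rn); parts_cid.append(ci)
    parts_het.append(he)

    out = Structure(
        serial=np.arange(1, sum(len(p) for p in parts_name) + 1),
        name=np.concatenate(parts_name),
        element=np.concatenate(parts_elem),
        coords=np.vstack(parts_xyz),
        res_id=np.concatenate(parts_rid),
        res_name=np.concatenate(parts_rname),
        chain_id=np.concatenate(parts_cid),
        hetero=np.concatenate(parts_het),
    )
    return out


def _relieve_graft_clashes(
    structure, res_mask, template, bb, sc_names, sc_coords, chi1
):
    """Coarse deterministic χ1/χ2 sweep when the graft clashes hard."""
    from scipy.spatial import cKDTree

    env_mask = (~res_mask) & structure.heavy_mask & structure.solute_mask
    env = structure.coords[env_mask]
    if len(env) == 0:
        return sc_coords
    tree = cKDTree(env)

    def n_clashes(xyz):
        return sum(len(h) for h in tree.query_ball_point(xyz, CLASH_HARD_CUTOFF))

    if n_clashes(sc_coords) == 0:
        return sc_coords

    res = template.residue_name
    names_full = ["N", "CA", "C"] + sc_names
    coords_full = np.vstack([[bb["N"], bb["CA"], bb["C"]], sc_coords])

    def sweep(quad, moving, base_angle):
        nonlocal coords_full
        best = (n_clashes(coords_full[3:]), 0.0, coords_full)
        for delta in range(-180, 180, 30):
            if delta == 0:
                continue
            cand = _set_chi(
                names_full, coords_full, template, quad, moving,
                base_angle + delta,
            )
            score = (n_clashes(cand[3:]), abs(delta), cand)
            if score[0] < best[0] or (score[0] == best[0] and score[1] < best[1]):
                best = score
        coords_full = best[2]
        return best[0]

    if res in CHI1_ATOMS and res != "PRO":
        quad1 = ("N", "CA", "CB", CHI1_ATOMS[res])
        moving1 = template.atoms_beyond("CA", "CB")
        idx = {n: i for i, n in enumerate(names_full)}
        base1 = _dihedral(*[coords_full[idx[a]] for a in quad1])
        remaining = sweep(quad1, moving1, base1)
        if remaining > 0 and res in CHI2_ATOMS:
            quad2 = ("CA", "CB", CHI1_ATOMS[res], CHI2_ATOMS[res])
            moving2 = template.atoms_beyond("CB", CHI1_ATOMS[res])
            base2 = _dihedral(*[coords_full[idx[a]] for a in quad2])
            sweep(quad2, moving2, base2)
    return coords_full[3:]


# ---------------------------------------------------------------------------
# Clash detection
# ---------------------------------------------------------------------------

def _bond_graph(structure: Structure) -> list[set[int]]:
    """Heavy-atom bond adjacency from residue connectivity templates."""
    import biotite.structure as struc

    from .structure_io import _to_atom_array

    arr = _to_atom_array(structure)
    bond_list = struc.connect_via_residue_names(arr)
    adj: list[set[int]] = [set() for _ in range(len(structure))]
    for i, j, _ in bond_list.as_array():
        i, j = int(i), int(j)
        same_res = (
            structure.res_id[i] == structure.res_id[j]
            and structure.chain_id[i] == structure.chain_id[j]
        )
        # inter-residue (peptide) links only count when geometrically real
        if not same_res:
            d = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
            if d > 2.0:
                continue
        adj[i].add(j)
        adj[j].add(i)
    return adj


def detect_clashes(
    structure: Structure, threshold: float
) -> list[tuple[int, int, float]]:
    """Heavy-atom pairs closer than ``threshold`` Å, excluding 1-2/1-3 pairs.

    Returns ``(i, j, distance)`` index pairs sorted by distance ascending
    (ties by index), a deterministic ordering.
    """
    from scipy.spatial import cKDTree

    if threshold <= 0:
        return []
    heavy_idx = np.where(structure.heavy_mask & structure.solute_mask)[0]
    coords = structure.coords[heavy_idx]
    if len(coords) < 2:
        return []
    adj = _bond_graph(structure)
    excluded: set[tuple[int, int]] = set()
    for i in range(len(structure)):
        for j in adj[i]:
            excluded.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    excluded.add((min(i, k), max(i, k)))
    tree = cKDTree(coords)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    out = []
    for a, b in pairs:
        i, j = int(heavy_idx[a]), int(heavy_idx[b])
        key = (min(i, j), max(i, j))
        if key in excluded:
            continue
        d = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
        if d < threshold:
            out.append((key[0], key[1], d))
    out.sort(key=lambda t: (t[2], t[0], t[1]))
    return out
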