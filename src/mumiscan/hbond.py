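"""Geometric hydrogen-bond and salt-bridge analysis.

A hydrogen bond is declared when the heavy-atom donor–acceptor distance
is at most ``d_max`` (default 3.0 Å) and the bond angle is at most
``theta_max`` (default 20°).  The default angle convention measures the
angle at the donor between the D→H and D→A vectors; the alternative
``"linearity"`` convention measures the deviation of D–H···A from 180°
at the hydrogen.  Both cutoffs are inclusive.

Crystal structures carry no hydrogens, so :func:`add_polar_hydrogens`
constructs them at ideal geometry before detection.  Ensemble statistics
aggregate bonds at residue–moiety granularity (backbone vs side chain),
the natural resolution for interface occupancy tables: a residue pair
counts as bonded in a frame if at least one atomic hydrogen bond matches
it in that frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .structure_io import Ensemble, Structure, THREE_TO_ONE

__all__ = [
    "HBondCriterion",
    "HBond",
    "HBondOccupancy",
    "add_polar_hydrogens",
    "detect_hbonds",
    "occupancy",
    "dominant_bonds",
    "count_wt_bonds",
    "salt_bridge_distance",
]

# numerical slack so that geometry constructed exactly on a cutoff
# (e.g. 3.0 Å / 20°) is counted as inside it
_EDGE = 1e-9

NH_BOND = 1.01
OH_BOND = 0.96
SH_BOND = 1.34
TETRAHEDRAL = 109.47

# side-chain donor heavy atoms -> hydrogen names; grouped by residue
SIDECHAIN_DONORS: dict[str, dict[str, list[str]]] = {
    "SER": {"OG": ["HG"]},
    "THR": {"OG1": ["HG1"]},
    "TYR": {"OH": ["HH"]},
    "CYS": {"SG": ["HG"]},
    "LYS": {"NZ": ["HZ1", "HZ2", "HZ3"]},
    "ARG": {"NE": ["HE"], "NH1": ["HH11", "HH12"], "NH2": ["HH21", "HH22"]},
    "ASN": {"ND2": ["HD21", "HD22"]},
    "GLN": {"NE2": ["HE21", "HE22"]},
    "TRP": {"NE1": ["HE1"]},
    # histidine: neutral, ND1-protonated tautomer by default
    "HIS": {"ND1": ["HD1"]},
}

SIDECHAIN_ACCEPTORS: dict[str, list[str]] = {
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "ASN": ["OD1"],
    "GLN": ["OE1"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "HIS": ["NE2"],  # the unprotonated imidazole nitrogen of the default tautomer
}

ACIDIC_SC_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_SC_NITROGENS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric cutoffs: donor–acceptor distance (Å) and angle (degrees)."""

    d_max: float = 3.0
    theta_max: float = 20.0
    angle_convention: str = "donor"  # or "linearity"

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.theta_max < 90:
            raise ValueError("theta_max must be in (0, 90) degrees")
        if self.angle_convention not in ("donor", "linearity"):
            raise ValueError("angle_convention must be 'donor' or 'linearity'")


AtomRef = tuple[str, int, str, str]  # (chain, res_id, res_name, atom_name)


@dataclass(frozen=True)
class HBond:
    donor: AtomRef
    hydrogen: AtomRef
    acceptor: AtomRef
    distance: float
    angle: float
    donor_moiety: str
    acceptor_moiety: str

    @property
    def pair(self) -> "PairKey":
        return pair_key(
            (self.donor[0], self.donor[1], self.donor_moiety),
            (self.acceptor[0], self.acceptor[1], self.acceptor_moiety),
        )


# a residue-moiety pair, order-normalized: ((chain, res_id, moiety), ...)
PairKey = tuple[tuple[str, int, str], tuple[str, int, str]]


def pair_key(a: tuple[str, int, str], b: tuple[str, int, str]) -> PairKey:
    return (a, b) if a <= b else (b, a)


@dataclass
class HBondOccupancy:
    pair: PairKey
    frames_present: int
    frames_total: int

    @property
    def occupancy(self) -> float:
        return self.frames_present / self.frames_total


# ---------------------------------------------------------------------------
# Polar hydrogen construction
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _bisector_h(n: np.ndarray, a: np.ndarray, b: np.ndarray,
                bond: float = NH_BOND) -> np.ndarray:
    """H on atom ``n`` along the external bisector of its bonds to a and b."""
    return n + bond * _unit(_unit(n - a) + _unit(n - b))


def _sp2_nh2(n: np.ndarray, c: np.ndarray, ref: np.ndarray) -> list[np.ndarray]:
    """Two H on an sp2 nitrogen ``n`` bonded to ``c``, in the c/ref plane."""
    to_c = _unit(c - n)
    normal = _unit(np.cross(ref - c, n - c))
    in_plane = _unit(np.cross(normal, to_c))
    out = []
    for sign in (1.0, -1.0):
        d = to_c * math.cos(math.radians(120.0)) + sign * in_plane * math.sin(
            math.radians(120.0)
        )
        out.append(n + NH_BOND * d)
    return out


def _cone_h_toward(
    x: np.ndarray, anchor: np.ndarray, target: np.ndarray | None,
    bond: float, cone_angle: float = TETRAHEDRAL, n_h: int = 1,
) -> list[np.ndarray]:
    """H atoms on a cone around the x→anchor axis, azimuth toward target.

    Models rotatable O–H / S–H / N–H3+ groups: the X–H direction makes
    ``cone_angle`` with the X→anchor bond; the azimuth is chosen
    analytically so one hydrogen points as closely as possible toward the
    target acceptor (azimuth 0 along an arbitrary fixed frame if no
    target exists).  For ``n_h`` = 3 the remaining hydrogens sit at
    ±120° azimuth.
    """
    axis = _unit(anchor - x)
    # orthonormal frame around the axis, deterministic
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, axis)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = _unit(seed - np.dot(seed, axis) * axis)
    e2 = np.cross(axis, e1)
    if target is not None:
        t = target - x
        u, v = np.dot(t, e1), np.dot(t, e2)
        phi0 = math.atan2(v, u) if (abs(u) > 1e-12 or abs(v) > 1e-12) else 0.0
    else:
        phi0 = 0.0
    ca, sa = math.cos(math.radians(cone_angle)), math.sin(math.radians(cone_angle))
    out = []
    for k in range(n_h):
        phi = phi0 + 2.0 * math.pi * k / 3.0 if n_h == 3 else phi0
        d = ca * axis + sa * (math.cos(phi) * e1 + math.sin(phi) * e2)
        out.append(x + bond * d)
    return out


def _acceptor_atoms(structure: Structure) -> list[int]:
    idx = []
    for i in range(len(structure)):
        rn = str(structure.res_name[i])
        an = str(structure.name[i])
        if rn not in THREE_TO_ONE:
            continue
        if an in ("O", "OXT") or an in SIDECHAIN_ACCEPTORS.get(rn, ()):
            idx.append(i)
    return idx


def add_polar_hydrogens(structure: Structure) -> Structure:
    """Return a copy with hydrogens on all polar donor groups.

    Amide and ring N–H hydrogens are placed at ideal in-plane geometry;
    rotatable hydroxyl, thiol and ammonium hydrogens are oriented toward
    the nearest acceptor heavy atom (ties broken by lowest residue index,
    then atom name).  Existing hydrogens are preserved, so the operation
    is idempotent.  Nonstandard residues are skipped with a warning.
    """
    import warnings

    from scipy.spatial import cKDTree

    acc_idx = _acceptor_atoms(structure)
    acc_coords = structure.coords[acc_idx] if acc_idx else np.zeros((0, 3))
    acc_tree = cKDTree(acc_coords) if len(acc_coords) else None

    def nearest_acceptor(x: np.ndarray, own_residue: tuple[str, int]):
        if acc_tree is None:
            return None
        dists, order = acc_tree.query(x, k=min(8, len(acc_idx)))
        dists = np.atleast_1d(dists)
        order = np.atleast_1d(order)
        ranked = sorted(
            zip(dists, order),
            key=lambda t: (
                round(float(t[0]), 9),
                structure.res_id[acc_idx[int(t[1])]],
                str(structure.name[acc_idx[int(t[1])]]),
            ),
        )
        for d, o in ranked:
            i = acc_idx[int(o)]
            key = (str(structure.chain_id[i]), int(structure.res_id[i]))
            if key != own_residue:
                return structure.coords[i]
        return None

    # positions of new hydrogens per residue key
    new_h: dict[tuple[str, int], list[tuple[str, np.ndarray]]] = {}

    residues = structure.residue_ids()
    res_atom_names: dict[tuple[str, int], set[str]] = {}
    for key in residues:
        mask = structure.residue_mask(*key)
        res_atom_names[key] = {str(n) for n in structure.name[mask]}

    def coord(key, name):
        mask = structure.residue_mask(*key) & (structure.name == name)
        if not mask.any():
            return None
        return structure.coords[np.argmax(mask)]

    for key in residues:
        chain, rid = key
        rname = structure.residue_name_of(chain, rid)
        if rname not in THREE_TO_ONE:
            if rname not in ("HOH", "WAT"):
                warnings.warn(f"skipping nonstandard residue {rname} {chain}:{rid}",
                              stacklevel=2)
            continue
        names = res_atom_names[key]
        added: list[tuple[str, np.ndarray]] = []
        n_xyz, ca_xyz = coord(key, "N"), coord(key, "CA")

        # backbone amide / N-terminal ammonium
        if n_xyz is not None and ca_xyz is not None and rname != "PRO":
            prev_key = (chain, rid - 1)
            c_prev = coord(prev_key, "C") if prev_key in res_atom_names else None
            if c_prev is not None and np.linalg.norm(c_prev - n_xyz) < 1.8:
                if "H" not in names and "HN" not in names:
                    added.append(("H", _bisector_h(n_xyz, c_prev, ca_xyz)))
            else:
                if not {"H1", "H2", "H3"} & names and "H" not in names:
                    tgt = nearest_acceptor(n_xyz, key)
                    hs = _cone_h_toward(n_xyz, ca_xyz, tgt, NH_BOND, n_h=3)
                    added.extend(zip(("H1", "H2", "H3"), hs))

        # side-chain donors
        for heavy, h_names in SIDECHAIN_DONORS.get(rname, {}).items():
            if heavy not in names or all(h in names for h in h_names):
                continue
            x = coord(key, heavy)
            if x is None:
                continue
            if rname == "SER" and heavy == "OG":
                added += _rotatable(x, coord(key, "CB"), OH_BOND, h_names, key, nearest_acceptor)
            elif rname == "THR" and heavy == "OG1":
                added += _rotatable(x, coord(key, "CB"), OH_BOND, h_names, key, nearest_acceptor)
            elif rname == "TYR" and heavy == "OH":
                added += _rotatable(x, coord(key, "CZ"), OH_BOND, h_names, key, nearest_acceptor)
            elif rname == "CYS" and heavy == "SG":
                added += _rotatable(x, coord(key, "CB"), SH_BOND, h_names, key, nearest_acceptor)
            elif rname == "LYS" and heavy == "NZ":
                tgt = nearest_acceptor(x, key)
                hs = _cone_h_toward(x, coord(key, "CE"), tgt, NH_BOND, n_h=3)
                added.extend(zip(h_names, hs))
            elif rname == "ARG" and heavy == "NE":
                added.append((h_names[0], _bisector_h(x, coord(key, "CD"), coord(key, "CZ"))))
            elif rname == "ARG" and heavy in ("NH1", "NH2"):
                hs = _sp2_nh2(x, coord(key, "CZ"), coord(key, "NE"))
                added.extend(zip(h_names, hs))
            elif rname == "ASN" and heavy == "ND2":
                hs = _sp2_nh2(x, coord(key, "CG"), coord(key, "OD1"))
                added.extend(zip(h_names, hs))
            elif rname == "GLN" and heavy == "NE2":
                hs = _sp2_nh2(x, coord(key, "CD"), coord(key, "OE1"))
                added.extend(zip(h_names, hs))
            elif rname == "TRP" and heavy == "NE1":
                added.append((h_names[0], _bisector_h(x, coord(key, "CD1"), coord(key, "CE2"))))
            elif rname == "HIS" and heavy == "ND1":
                added.append((h_names[0], _bisector_h(x, coord(key, "CG"), coord(key, "CE1"))))
        if added:
            new_h[key] = added

    if not new_h:
        return structure.copy()

    # rebuild keeping residue blocks contiguous
    cols = {k: [] for k in ("name", "element", "xyz", "rid", "rname", "cid", "het")}

    def push(name, element, xyz, rid, rname, cid, het):
        cols["name"].append(name); cols["element"].append(element)
        cols["xyz"].append(xyz); cols["rid"].append(rid)
        cols["rname"].append(rname); cols["cid"].append(cid); cols["het"].append(het)

    i = 0
    n = len(structure)
    while i < n:
        key = (str(structure.chain_id[i]), int(structure.res_id[i]))
        j = i
        while j < n and (str(structure.chain_id[j]), int(structure.res_id[j])) == key:
            a = structure[j]
            push(a.name, a.element, a.coords, a.residue_index, a.residue_name,
                 a.chain_id, a.hetero)
            j += 1
        rname = str(structure.res_name[i])
        het = bool(structure.hetero[i])
        for h_name, h_xyz in new_h.pop(key, []):
            push(h_name, "H", h_xyz, key[1], rname, key[0], het)
        i = j

    return Structure(
        serial=np.arange(1, len(cols["name"]) + 1),
        name=cols["name"], element=cols["element"],
        coords=np.vstack(cols["xyz"]), res_id=cols["rid"],
        res_name=cols["rname"], chain_id=cols["cid"], hetero=cols["het"],
    )


def _rotatable(x, anchor, bond, h_names, key, nearest_acceptor):
    tgt = nearest_acceptor(x, key)
    hs = _cone_h_toward(x, anchor, tgt, bond, n_h=1)
    return list(zip(h_names, hs))


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _donor_triples(structure: Structure) -> list[tuple[int, int, str]]:
    """(donor_idx, hydrogen_idx, moiety) for every present D–H pair."""
    triples = []
    for key in structure.residue_ids():
        chain, rid = key
        rname = structure.residue_name_of(chain, rid)
        if rname not in THREE_TO_ONE:
            continue
        mask = structure.residue_mask(chain, rid)
        idx_of = {str(structure.name[i]): i for i in np.where(mask)[0]}
        # backbone
        if "N" in idx_of:
            for h in ("H", "HN", "H1", "H2", "H3"):
                if h in idx_of:
                    triples.append((idx_of["N"], idx_of[h], "backbone"))
        for heavy, h_names in SIDECHAIN_DONORS.get(rname, {}).items():
            if heavy not in idx_of:
                continue
            for h in h_names:
                if h in idx_of:
                    triples.append((idx_of[heavy], idx_of[h], "side-chain"))
    return triples


def _acceptor_entries(structure: Structure) -> list[tuple[int, str]]:
    entries = []
    for i in _acceptor_atoms(structure):
        name = str(structure.name[i])
        moiety = "backbone" if name in ("O", "OXT") else "side-chain"
        entries.append((i, moiety))
    return entries


def detect_hbonds(
    structure: Structure,
    criterion: HBondCriterion = HBondCriterion(),
    between: tuple[Iterable[str], Iterable[str]] | None = None,
) -> list[HBond]:
    """All hydrogen bonds satisfying the geometric criterion.

    ``between`` restricts the result to bonds whose donor and acceptor
    lie in different chain sets (either direction).  Bonds are sorted by
    (donor residue, acceptor residue, atom names).  Polar hydrogens must
    be present (see :func:`add_polar_hydrogens`).
    """
    from scipy.spatial import cKDTree

    donors = _donor_triples(structure)
    acceptors = _acceptor_entries(structure)
    if not donors or not acceptors:
        return []
    acc_idx = np.array([a for a, _ in acceptors])
    acc_moiety = [m for _, m in acceptors]
    tree = cKDTree(structure.coords[acc_idx])

    set_a = set(between[0]) if between else None
    set_b = set(between[1]) if between else None

    def ref(i: int) -> AtomRef:
        return (
            str(structure.chain_id[i]), int(structure.res_id[i]),
            str(structure.res_name[i]), str(structure.name[i]),
        )

    bonds = []
    for d_i, h_i, d_moiety in donors:
        d_xyz = structure.coords[d_i]
        for local in tree.query_ball_point(d_xyz, criterion.d_max + _EDGE):
            a_i = int(acc_idx[local])
            if a_i == d_i:
                continue
            same_res = (
                structure.chain_id[a_i] == structure.chain_id[d_i]
                and structure.res_id[a_i] == structure.res_id[d_i]
            )
            a_moiety = acc_moiety[local]
            if same_res and a_moiety == d_moiety:
                continue
            if between is not None:
                cd, ca_ = str(structure.chain_id[d_i]), str(structure.chain_id[a_i])
                if not ((cd in set_a and ca_ in set_b) or (cd in set_b and ca_ in set_a)):
                    continue
            a_xyz = structure.coords[a_i]
            dist = float(np.linalg.norm(a_xyz - d_xyz))
            if dist > criterion.d_max + _EDGE:
                continue
            h_xyz = structure.coords[h_i]
            if criterion.angle_convention == "donor":
                v1, v2 = h_xyz - d_xyz, a_xyz - d_xyz
            else:  # deviation of D–H···A from linearity, measured at H
                v1, v2 = d_xyz - h_xyz, h_xyz - a_xyz
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang > criterion.theta_max + _EDGE:
                continue
            bonds.append(
                HBond(
                    donor=ref(d_i), hydrogen=ref(h_i), acceptor=ref(a_i),
                    distance=dist, angle=ang,
                    donor_moiety=d_moiety, acceptor_moiety=a_moiety,
                )
            )
    bonds.sort(key=lambda b: (b.donor[:2], b.acceptor[:2], b.donor[3], b.acceptor[3]))
    return bonds


# ---------------------------------------------------------------------------
# Ensemble statistics
# ---------------------------------------------------------------------------

def occupancy(
    ensemble: Ensemble,
    criterion: HBondCriterion = HBondCriterion(),
    between: tuple[Iterable[str], Iterable[str]] | None = None,
    protonate: bool = True,
) -> list[HBondOccupancy]:
    """Residue–moiety pair occupancies over an ensemble.

    A pair is present in a frame if at least one atomic hydrogen bond
    matches it there.  Frames without hydrogens are protonated on the fly
    when ``protonate`` is set.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    counts: dict[PairKey, int] = {}
    for frame in ensemble:
        if protonate and not (frame.element == "H").any():
            frame = add_polar_hydrogens(frame)
        seen = {b.pair for b in detect_hbonds(frame, criterion, between)}
        for p in seen:
            counts[p] = counts.get(p, 0) + 1
    total = len(ensemble)
    out = [
        HBondOccupancy(pair=p, frames_present=c, frames_total=total)
        for p, c in counts.items()
    ]
    out.sort(key=lambda o: (-o.occupancy, o.pair))
    return out


def dominant_bonds(
    occupancies: Sequence[HBondOccupancy], threshold: float = 0.20
) -> list[HBondOccupancy]:
    """Pairs with occupancy strictly above ``threshold``, sorted descending."""
    kept = [o for o in occupancies if o.occupancy > threshold]
    kept.sort(key=lambda o: (-o.occupancy, o.pair))
    return kept


def count_wt_bonds(
    structure: Structure,
    wt_bonds: Sequence[PairKey | HBondOccupancy],
    criterion: HBondCriterion = HBondCriterion(),
    protonate: bool = True,
) -> int:
    """How many of the reference (wild-type) pairs are satisfied here.

    ``wt_bonds`` is typically the output of :func:`dominant_bonds` on the
    wild-type reference ensemble (or the pair keys directly).  The count
    is bounded by ``len(wt_bonds)``.
    """
    keys = {o.pair if isinstance(o, HBondOccupancy) else o for o in wt_bonds}
    if protonate and not (structure.element == "H").any():
        structure = add_polar_hydrogens(structure)
    present = {b.pair for b in detect_hbonds(structure, criterion)}
    return len(keys & present)


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

def salt_bridge_distance(
    structure: Structure,
    acidic: tuple[str, int],
    basic: tuple[str, int],
) -> float:
    """Distance between charged-group mass centers, in Å.

    The acidic side is the center of mass of the side-chain carboxylate
    oxygens (ASP OD1/OD2 or GLU OE1/OE2); the basic side is the center of
    mass of the side-chain nitrogens (LYS NZ; ARG NE/NH1/NH2; HIS
    ND1/NE2).
    """
    a_name = structure.residue_name_of(*acidic)
    b_name = structure.residue_name_of(*basic)
    if a_name not in ACIDIC_SC_OXYGENS:
        raise ValueError(f"{a_name} {acidic} is not an acidic residue (ASP/GLU)")
    if b_name not in BASIC_SC_NITROGENS:
        raise ValueError(f"{b_name} {basic} is not a basic residue (LYS/ARG/HIS)")

    def com(key, names):
        mask = structure.residue_mask(*key) & np.isin(structure.name, names)
        if not mask.any():
            raise ValueError(f"residue {key} missing side-chain atoms {names}")
        return structure.coords[mask].mean(axis=0)

    return float(
        np.linalg.norm(
            com(acidic, list(ACIDIC_SC_OXYGENS[a_name]))
            - com(basic, list(BASIC_SC_NITROGENS[b_name]))
        )
    )
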