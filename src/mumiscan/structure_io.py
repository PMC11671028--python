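"""Structure data model and PDB input/output.

The :class:`Structure` is the universal unit passed between pipeline
stages: an ordered, numpy-backed table of atoms (serial, name, element,
coordinates, residue index/name, chain id, hetero flag).  Coordinates are
in Ångström throughout.  Residue numbering follows the author numbering
of the source PDB file; all residue references in downstream analyses
resolve through author numbering, not sequential index.

PDB parsing and writing are delegated to biotite; this module adds the
conventions the pipeline relies on: alternate locations resolved to the
highest-occupancy conformer, insertion codes rejected, waters and hetero
groups retained but flagged, and bit-stable fixed-column output so that a
read → write → read round trip is coordinate-stable to 1e-3 Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Ensemble",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "split_complex",
    "rmsd_heavy",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

WATER_NAMES = {"HOH", "WAT", "TIP", "TIP3", "SPC", "DOD"}
ION_NAMES = {"K", "CL", "NA", "MG", "CA", "ZN", "MN", "FE", "CU", "IOD", "BR"}


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a :class:`Structure` (a read-only view)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue_index: int
    residue_name: str
    chain_id: str
    hetero: bool = False

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


class Structure:
    """Ordered collection of atoms grouped into chains and residues.

    Internally column-oriented (parallel numpy arrays) for vectorised
    geometry; :meth:`atoms` yields :class:`AtomRecord` views for
    record-oriented access.
    """

    def __init__(
        self,
        serial: Sequence[int],
        name: Sequence[str],
        element: Sequence[str],
        coords: np.ndarray,
        res_id: Sequence[int],
        res_name: Sequence[str],
        chain_id: Sequence[str],
        hetero: Sequence[bool] | None = None,
    ):
        n = len(serial)
        self.serial = np.asarray(serial, dtype=np.int64)
        self.name = np.asarray(name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.coords = np.array(coords, dtype=np.float64).reshape(n, 3)
        self.res_id = np.asarray(res_id, dtype=np.int64)
        self.res_name = np.asarray(res_name, dtype="U5")
        self.chain_id = np.asarray(chain_id, dtype="U4")
        if hetero is None:
            hetero = np.zeros(n, dtype=bool)
        self.hetero = np.asarray(hetero, dtype=bool)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    # -- basic container protocol -------------------------------------
    def __len__(self) -> int:
        return len(self.serial)

    def __getitem__(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]),
            name=str(self.name[i]),
            element=str(self.element[i]),
            coords=self.coords[i].copy(),
            residue_index=int(self.res_id[i]),
            residue_name=str(self.res_name[i]),
            chain_id=str(self.chain_id[i]),
            hetero=bool(self.hetero[i]),
        )

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield self[i]

    def copy(self) -> "Structure":
        return Structure(
            self.serial.copy(), self.name.copy(), self.element.copy(),
            self.coords.copy(), self.res_id.copy(), self.res_name.copy(),
            self.chain_id.copy(), self.hetero.copy(),
        )

    def subset(self, mask: np.ndarray) -> "Structure":
        """New Structure containing the atoms selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        return Structure(
            self.serial[mask], self.name[mask], self.element[mask],
            self.coords[mask], self.res_id[mask], self.res_name[mask],
            self.chain_id[mask], self.hetero[mask],
        )

    # -- selections ----------------------------------------------------
    @property
    def chains(self) -> list[str]:
        """Distinct chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.res_name, sorted(WATER_NAMES))

    @property
    def is_ion(self) -> np.ndarray:
        return self.hetero & np.isin(self.res_name, sorted(ION_NAMES))

    @property
    def solute_mask(self) -> np.ndarray:
        return ~(self.is_water | self.is_ion)

    def chain(self, chain_id: str) -> "Structure":
        return self.subset(self.chain_id == chain_id)

    def residue_ids(self, chain: str | None = None) -> list[tuple[str, int]]:
        """Ordered (chain, residue_index) keys of non-water residues."""
        keys: dict[tuple[str, int], None] = {}
        mask = self.solute_mask
        for c, r in zip(self.chain_id[mask], self.res_id[mask]):
            if chain is None or str(c) == chain:
                keys.setdefault((str(c), int(r)))
        return list(keys)

    def residue_mask(self, chain: str, res_id: int) -> np.ndarray:
        return (self.chain_id == chain) & (self.res_id == res_id)

    def residue_name_of(self, chain: str, res_id: int) -> str:
        mask = self.residue_mask(chain, res_id)
        if not mask.any():
            raise KeyError(f"no residue {res_id} on chain {chain!r}")
        return str(self.res_name[mask][0])

    def sequence(self, chain: str) -> str:
        """1-letter sequence of a chain's standard amino-acid residues."""
        out = []
        for c, r in self.residue_ids(chain):
            name = self.residue_name_of(c, r)
            if name in THREE_TO_ONE:
                out.append(THREE_TO_ONE[name])
        return "".join(out)

    def renumber_serials(self) -> None:
        self.serial = np.arange(1, len(self) + 1, dtype=np.int64)

    def validate_backbone(self) -> list[tuple[str, int]]:
        """Return residues missing any of N/CA/C/O (standard residues only)."""
        flagged = []
        for c, r in self.residue_ids():
            mask = self.residue_mask(c, r)
            if str(self.res_name[mask][0]) not in THREE_TO_ONE:
                continue
            names = set(self.name[mask])
            if not set(BACKBONE_ATOMS) <= names:
                flagged.append((c, r))
        return flagged


@dataclass
class Ensemble:
    """Ordered list of structures sharing one topology (or one chain layout).

    ``source`` distinguishes fixed-topology ensembles (multi-model PDB,
    trajectory export) from mutant collections, where only the residue
    count per chain is guaranteed identical.
    """

    frames: list[Structure]
    source: str = "multi-model-pdb"
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.source in ("multi-model-pdb", "trajectory") and self.frames:
            n0 = len(self.frames[0])
            for i, f in enumerate(self.frames):
                if len(f) != n0:
                    raise ValueError(
                        f"frame {i} has {len(f)} atoms, expected {n0}"
                    )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def _from_atom_array(arr) -> Structure:
    import biotite.structure as struc

    n = arr.array_length()
    serial = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    return Structure(
        serial=serial,
        name=arr.atom_name,
        element=np.char.capitalize(arr.element),
        coords=arr.coord,
        res_id=arr.res_id,
        res_name=arr.res_name,
        chain_id=arr.chain_id,
        hetero=arr.hetero,
    )


def _to_atom_array(structure: Structure):
    import biotite.structure as struc

    arr = struc.AtomArray(len(structure))
    arr.coord = structure.coords.astype(np.float32)
    arr.atom_name = structure.name
    arr.element = np.char.upper(structure.element)
    arr.res_id = structure.res_id
    arr.res_name = structure.res_name
    arr.chain_id = structure.chain_id
    arr.hetero = structure.hetero
    arr.set_annotation("atom_id", structure.serial.astype(int))
    return arr


def read_pdb(path: str | Path, model: int | None = None) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by the first listed).  Waters and hetero groups are kept
    and flagged through the ``hetero`` column.  Residues with insertion
    codes are rejected.  Residues missing backbone atoms produce a
    warning, not an error.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(
            model=model if model is not None else 1,
            altloc="occupancy",
            extra_fields=["atom_id"],
        )
    except Exception as exc:  # biotite reports offending content itself
        raise PDBParseError(f"{path}: {exc}") from exc

    # insertion codes live in column 27 of ATOM/HETATM records; the
    # pairing logic downstream assumes plain author numbering, so reject
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) > 26:
            if line[26] not in (" ", ""):
                raise PDBParseError(
                    f"{path}:{lineno}: insertion code {line[26]!r} on "
                    f"residue {line[17:27].strip()}; insertion codes are "
                    "not supported"
                )

    structure = _from_atom_array(arr)
    flagged = structure.validate_backbone()
    if flagged:
        warnings.warn(
            f"{path.name}: {len(flagged)} residue(s) missing backbone atoms: "
            + ", ".join(f"{c}:{r}" for c, r in flagged[:5]),
            stacklevel=2,
        )
    return structure


def read_ensemble(path: str | Path) -> Ensemble:
    """Read all MODELs of a multi-model PDB file as an :class:`Ensemble`."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    frames = [read_pdb(path, model=m) for m in range(1, n_models + 1)]
    return Ensemble(frames=frames, source="multi-model-pdb")


def write_pdb(obj: Structure | Ensemble, path: str | Path) -> Path:
    """Write a structure (or a multi-model ensemble) as fixed-column PDB.

    Coordinates are written with 3 decimals, so a round trip reproduces
    them to 1e-3 Å.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if isinstance(obj, Ensemble):
        frames = obj.frames
    else:
        frames = [obj]
    for f in frames:
        if len(f) > 99999:
            raise ValueError(
                f"{len(f)} atoms exceed the 99999-atom PDB format limit"
            )
    pdb = PDBFile()
    if len(frames) == 1:
        pdb.set_structure(_to_atom_array(frames[0]))
    else:
        import biotite.structure as struc

        stack = struc.stack([_to_atom_array(f) for f in frames])
        pdb.set_structure(stack)
    pdb.write(str(path))
    return path


# ---------------------------------------------------------------------------
# Complex handling and RMSD
# ---------------------------------------------------------------------------

def split_complex(
    complex_structure: Structure, focal_chains: set[str] | Sequence[str]
) -> tuple[Structure, Structure]:
    """Partition a complex into (focal, partner) solute structures.

    Waters and ions are excluded from both halves; the union of the two
    halves is exactly the solute atom set.
    """
    focal_chains = set(focal_chains)
    if not focal_chains:
        raise ValueError("focal_chains is empty")
    available = set(complex_structure.chains)
    unknown = focal_chains - available
    if unknown:
        raise ValueError(
            f"unknown chain id(s) {sorted(unknown)}; "
            f"available chains: {sorted(available)}"
        )
    solute = complex_structure.subset(complex_structure.solute_mask)
    in_focal = np.isin(solute.chain_id, sorted(focal_chains))
    focal = solute.subset(in_focal)
    partner = solute.subset(~in_focal)
    if len(partner) == 0:
        raise ValueError("partner is empty: focal_chains covers every chain")
    return focal, partner


def _pair_heavy(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Name-based pairing of heavy atoms; error naming the first mismatch."""
    am, bm = a.heavy_mask, b.heavy_mask
    keys_a = list(zip(a.chain_id[am], a.res_id[am], a.name[am]))
    keys_b = list(zip(b.chain_id[bm], b.res_id[bm], b.name[bm]))
    if len(keys_a) != len(keys_b):
        sa, sb = set(keys_a), set(keys_b)
        odd = sorted(sa ^ sb)
        what = odd[0] if odd else ("?", 0, "?")
        raise ValueError(
            f"heavy-atom count mismatch ({len(keys_a)} vs {len(keys_b)}); "
            f"first unpaired atom: chain {what[0]} res {what[1]} {what[2]}"
        )
    index_b = {k: i for i, k in enumerate(keys_b)}
    order = []
    for k in keys_a:
        if k not in index_b:
            raise ValueError(
                f"atom chain {k[0]} res {k[1]} {k[2]} has no counterpart"
            )
        order.append(index_b[k])
    return a.coords[am], b.coords[bm][order]


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit (Kabsch) of ``mobile`` onto ``target``."""
    from scipy.spatial.transform import Rotation

    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - mu_t, mobile - mu_m)
    return rot.apply(mobile - mu_m) + mu_t


def rmsd_heavy(a: Structure, b: Structure, superpose_first: bool = False) -> float:
    """Heavy-atom RMSD between two structures, in Å.

    Atoms are paired by (chain, residue index, atom name).  With
    ``superpose_first`` an optimal rigid-body least-squares fit is applied
    before the deviation is measured; the default leaves both structures
    in their own frames, which is the natural convention for comparing a
    structure before and after minimization.
    """
    xa, xb = _pair_heavy(a, b)
    if superpose_first:
        xb = superpose(xb, xa)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
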