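"""Solvent-accessible surface area and relative solvent accessibility.

SASA is computed with the Shrake–Rupley rolling-probe method: each heavy
atom is covered with a deterministic generalized-spiral (Fibonacci)
point set on its solvent-expanded sphere, and the accessible fraction of
points yields the atomic area.  Hydrogens are excluded, the convention
for crystal-structure input.

RSA expresses a residue's SASA as a percent of the theoretical maximum
accessible area of that amino-acid type in an extended Gly-X-Gly context
(Tien et al. 2013 scale); residues with RSA above 25 are conventionally
classified as surface residues.  Values above 100 can occur for extended
conformations and are permitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structure_io import Ensemble, Structure, THREE_TO_ONE

__all__ = [
    "SasaSpec",
    "RSAProfile",
    "RSAStats",
    "sasa_atoms",
    "sasa_total",
    "rsa",
    "delta_rsa",
    "ensemble_rsa_stats",
    "compare_stats",
    "MAX_ASA_THEORETICAL",
    "MAX_ASA_EMPIRICAL",
]

# van der Waals radii (Å) per element, classic protein set
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "P": 1.80, "Se": 1.90, "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "Ar": 1.88,
}

# theoretical maximum ASA (Å²), Tien et al. 2013
MAX_ASA_THEORETICAL = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
# empirical maxima from the same survey
MAX_ASA_EMPIRICAL = {
    "ALA": 121.0, "ARG": 265.0, "ASN": 187.0, "ASP": 187.0, "CYS": 148.0,
    "GLN": 214.0, "GLU": 214.0, "GLY": 97.0, "HIS": 216.0, "ILE": 195.0,
    "LEU": 191.0, "LYS": 230.0, "MET": 203.0, "PHE": 228.0, "PRO": 154.0,
    "SER": 143.0, "THR": 163.0, "TRP": 264.0, "TYR": 255.0, "VAL": 165.0,
}

SURFACE_RSA_THRESHOLD = 25.0


@dataclass(frozen=True)
class SasaSpec:
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_set: str = "default"
    max_asa_scale: str = "theoretical"

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be non-negative")
        if self.n_sphere_points < 32:
            raise ValueError("n_sphere_points must be at least 32")

    def max_asa(self) -> dict[str, float]:
        return (
            MAX_ASA_THEORETICAL
            if self.max_asa_scale == "theoretical"
            else MAX_ASA_EMPIRICAL
        )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere point set (generalized spiral)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + 5.0 ** 0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa_atoms(structure: Structure, spec: SasaSpec = SasaSpec()) -> np.ndarray:
    """Per-atom accessible areas in Å² (zeros for hydrogens).

    Deterministic for a given spec: the sphere point set is fixed, and
    occlusion is evaluated exactly against all neighbours within reach.
    """
    from scipy.spatial import cKDTree

    heavy = np.where(structure.heavy_mask)[0]
    areas = np.zeros(len(structure))
    if len(heavy) == 0:
        return areas
    radii = np.empty(len(heavy))
    for k, i in enumerate(heavy):
        el = str(structure.element[i])
        if el not in VDW_RADII:
            raise ValueError(f"no van der Waals radius for element {el!r}")
        radii[k] = VDW_RADII[el]
    expanded = radii + spec.probe_radius
    coords = structure.coords[heavy]
    pts = _fibonacci_sphere(spec.n_sphere_points)
    tree = cKDTree(coords)
    neighbor_lists: list[list[int]] = [[] for _ in range(len(heavy))]
    for a, b in tree.query_pairs(2.0 * expanded.max(), output_type="ndarray"):
        d = float(np.linalg.norm(coords[a] - coords[b]))
        if d < expanded[a] + expanded[b]:
            neighbor_lists[a].append(b)
            neighbor_lists[b].append(a)
    for k in range(len(heavy)):
        sphere = coords[k] + expanded[k] * pts
        neighbors = neighbor_lists[k]
        if neighbors:
            nb_xyz = coords[neighbors]
            nb_r = expanded[neighbors]
            d2 = ((sphere[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r ** 2)[None, :]).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = spec.n_sphere_points
        areas[heavy[k]] = (
            4.0 * np.pi * expanded[k] ** 2 * accessible / spec.n_sphere_points
        )
    return areas


def sasa_total(structure: Structure, spec: SasaSpec = SasaSpec()) -> float:
    return float(sasa_atoms(structure, spec).sum())


@dataclass
class RSAProfile:
    """Per-residue relative solvent accessibility, in percent."""

    values: dict[tuple[str, int], float]
    res_names: dict[tuple[str, int], str]
    structure_label: str = ""

    def __getitem__(self, key: tuple[str, int]) -> float:
        return self.values[key]

    def residues(self) -> list[tuple[str, int]]:
        return list(self.values)

    def surface_residues(self, threshold: float = SURFACE_RSA_THRESHOLD):
        return [k for k, v in self.values.items() if v > threshold]

    def overextended(self) -> list[tuple[str, int]]:
        """Residues with RSA above 100 (extended conformations); flagged, kept."""
        return [k for k, v in self.values.items() if v > 100.0]


def rsa(structure: Structure, spec: SasaSpec = SasaSpec(),
        label: str = "") -> RSAProfile:
    """Residue SASA normalized by the reference maximum, in percent.

    Nonstandard residues (and waters/ions) are excluded.
    """
    areas = sasa_atoms(structure.subset(structure.solute_mask), spec)
    solute = structure.subset(structure.solute_mask)
    max_asa = spec.max_asa()
    values: dict[tuple[str, int], float] = {}
    names: dict[tuple[str, int], str] = {}
    for key in solute.residue_ids():
        rname = solute.residue_name_of(*key)
        if rname not in max_asa:
            continue
        mask = solute.residue_mask(*key)
        values[key] = float(areas[mask].sum()) / max_asa[rname] * 100.0
        names[key] = rname
    return RSAProfile(values=values, res_names=names, structure_label=label)


def delta_rsa(unbound: RSAProfile, bound: RSAProfile) -> dict[tuple[str, int], float]:
    """Signed per-residue RSA change on binding: bound − unbound."""
    if set(unbound.values) != set(bound.values):
        only_u = set(unbound.values) - set(bound.values)
        only_b = set(bound.values) - set(unbound.values)
        raise ValueError(
            f"residue sets differ (only unbound: {sorted(only_u)[:4]}, "
            f"only bound: {sorted(only_b)[:4]})"
        )
    return {k: bound[k] - unbound[k] for k in unbound.values}


@dataclass
class RSAStats:
    """Per-residue ensemble mean ⟨RSA⟩ and population σ."""

    mean: dict[tuple[str, int], float]
    sigma: dict[tuple[str, int], float]
    n_frames: int = 0

    def residues(self) -> list[tuple[str, int]]:
        return list(self.mean)


def ensemble_rsa_stats(
    ensemble: Ensemble, spec: SasaSpec = SasaSpec()
) -> RSAStats:
    """⟨RSA⟩ and σ per residue over an ensemble.

    For mutant-collection ensembles the statistics at each position run
    over the mutants, so a residue's spread reflects the 19 substitutions
    (and every mutant contributes to every position).
    """
    if len(ensemble) < 2:
        raise ValueError("ensemble statistics require at least 2 frames")
    profiles = [rsa(f, spec) for f in ensemble]
    keys = [k for k in profiles[0].values if all(k in p.values for p in profiles)]
    mean, sigma = {}, {}
    for k in keys:
        v = np.array([p[k] for p in profiles])
        mean[k] = float(v.mean())
        sigma[k] = float(v.std())  # population σ
    return RSAStats(mean=mean, sigma=sigma, n_frames=len(ensemble))


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import linregress

    if len(x) < 2 or np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return 1.0 if np.allclose(x - x.mean(), y - y.mean()) else 0.0
    return float(linregress(x, y).rvalue ** 2)


def compare_stats(
    a: RSAStats,
    b: RSAStats,
    allosteric: Sequence[int] = (9, 12, 14, 30, 33, 37, 39, 56),
    binding: Sequence[int] = (),
):
    """Paired per-residue table of two RSA ensembles plus least-squares R².

    Returns ``(table, r2_mean, r2_sigma)``; the table annotates residues
    as allosteric or binding for downstream plotting.
    """
    import pandas as pd

    keys = [k for k in a.residues() if k in b.mean]
    if set(a.mean) != set(b.mean):
        raise ValueError("residue sets differ between the two ensembles")
    rows = []
    for chain, rid in keys:
        rows.append({
            "chain": chain, "res_id": rid,
            "mean_a": a.mean[(chain, rid)], "mean_b": b.mean[(chain, rid)],
            "sigma_a": a.sigma[(chain, rid)], "sigma_b": b.sigma[(chain, rid)],
            "allosteric": rid in set(allosteric),
            "binding": rid in set(binding),
        })
    table = pd.DataFrame(rows)
    r2_mean = _r_squared(table["mean_a"].to_numpy(), table["mean_b"].to_numpy())
    r2_sigma = _r_squared(table["sigma_a"].to_numpy(), table["sigma_b"].to_numpy())
    return table, r2_mean, r2_sigma
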