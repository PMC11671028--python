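"""Binding-region membership and per-residue interface probability.

A focal residue belongs to the binding region when at least one of its
heavy (non-hydrogen) atoms lies within the cutoff (default 5.0 Å) of any
heavy atom of the binding partner.  Over an ensemble — a trajectory or a
mutant collection — the per-residue fraction of frames in which this
holds is the probability of being located at the binding region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .structure_io import Ensemble, Structure, split_complex

__all__ = [
    "InterfaceProfile",
    "binding_region",
    "binding_probability",
    "rank_interface_positions",
    "DEFAULT_CONTACT_CUTOFF",
]

DEFAULT_CONTACT_CUTOFF = 5.0


@dataclass
class InterfaceProfile:
    """Per-residue probability of binding-region membership."""

    probabilities: dict[tuple[str, int], float]
    cutoff: float
    n_observations: int

    def __getitem__(self, key: tuple[str, int]) -> float:
        return self.probabilities[key]

    def residues(self) -> list[tuple[str, int]]:
        return list(self.probabilities)


def binding_region(
    focal: Structure,
    partner: Structure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> set[tuple[str, int]]:
    """Focal residues with a heavy atom within ``cutoff`` of the partner."""
    from scipy.spatial import cKDTree

    if len(focal) == 0 or len(partner) == 0:
        raise ValueError("both structures must be nonempty")
    fm = focal.heavy_mask & focal.solute_mask
    pm = partner.heavy_mask & partner.solute_mask
    f_idx = np.where(fm)[0]
    p_xyz = partner.coords[pm]
    if len(f_idx) == 0 or len(p_xyz) == 0:
        return set()
    tree = cKDTree(p_xyz)
    dists, _ = tree.query(focal.coords[f_idx], k=1)
    region = set()
    for i, d in zip(f_idx, dists):
        if d < cutoff:
            region.add((str(focal.chain_id[i]), int(focal.res_id[i])))
    return region


def binding_probability(
    ensemble: Ensemble,
    focal_chains: Iterable[str],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> InterfaceProfile:
    """Fraction of frames (or mutants) in which each residue contacts.

    For a mutant collection the denominator is the number of usable
    mutant structures: each mutant contributes one observation to every
    focal residue, so a residue's probability aggregates over all
    substitutions at every position.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    focal_chains = set(focal_chains)
    counts: dict[tuple[str, int], int] = {}
    universe: dict[tuple[str, int], None] = {}
    for frame in ensemble:
        focal, partner = split_complex(frame, focal_chains)
        for key in focal.residue_ids():
            universe.setdefault(key)
        for key in binding_region(focal, partner, cutoff):
            counts[key] = counts.get(key, 0) + 1
    n = len(ensemble)
    probs = {k: counts.get(k, 0) / n for k in universe}
    return InterfaceProfile(probabilities=probs, cutoff=cutoff, n_observations=n)


def rank_interface_positions(
    profile: InterfaceProfile, reference: InterfaceProfile
) -> list[tuple[tuple[str, int], float]]:
    """Residues with probability above the reference, most probable first.

    Ties are broken deterministically by residue index.  Used to select
    the candidate set of binding-region positions (e.g. those a mutant
    collection visits more often than the wild-type indicator).
    """
    if set(profile.probabilities) != set(reference.probabilities):
        raise ValueError("profiles cover different residue sets")
    above = [
        (k, p)
        for k, p in profile.probabilities.items()
        if p > reference.probabilities[k]
    ]
    above.sort(key=lambda t: (-t[1], t[0][0], t[0][1]))
    return above
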