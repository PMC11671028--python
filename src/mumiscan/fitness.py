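"""Binding-fitness proxy from maintained wild-type hydrogen bonds.

The central quantity is, for every relaxed mutant complex, the number of
wild-type dominant interface hydrogen bonds that remain geometrically
satisfied (N_HB).  Arranged as a position × substitution matrix this is
a deep-mutational-scanning heatmap; compared against experimental
binding destabilization energies (ΔΔG, kcal/mol, conventionally capped
at a ceiling so that fully broken binders share one value) it serves as
a one-feature fitness predictor.  Larger destabilization means worse
binding, so the expected association between N_HB and capped ΔΔG is
negative; the sign is reported, never folded into a score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hbond import HBondCriterion, HBondOccupancy, PairKey, count_wt_bonds
from .mutator import AMINO_ACIDS
from .structure_io import Ensemble

__all__ = [
    "FitnessMatrix",
    "build_matrix",
    "cap_energies",
    "read_experiment_table",
    "correlate",
    "DEFAULT_ENERGY_CAP",
]

DEFAULT_ENERGY_CAP = 9.0  # kcal/mol


@dataclass
class FitnessMatrix:
    """positions × 19 substitutions matrix of maintained-WT-bond counts.

    ``values`` is a DataFrame indexed by position with one column per
    substitution letter; cells are integer counts or NaN for mutants
    that failed relaxation (enumerated in ``missing``).
    """

    values: pd.DataFrame
    wt_sequence: dict[int, str]
    n_wt_bonds: int
    missing: list[str] = field(default_factory=list)

    def cell(self, label: str) -> float:
        pos, mut = int(label[1:-1]), label[-1]
        return float(self.values.at[pos, mut])

    def long_form(self) -> pd.DataFrame:
        rows = []
        for pos in self.values.index:
            wt = self.wt_sequence[pos]
            for mut in self.values.columns:
                v = self.values.at[pos, mut]
                if not np.isnan(v):
                    rows.append(
                        {"label": f"{wt}{pos}{mut}", "position": pos,
                         "wt": wt, "mut": mut, "n_hb": int(v)}
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "wt", [self.wt_sequence[p] for p in out.index])
        out.to_csv(path, index_label="position")


def build_matrix(
    ensemble: Ensemble,
    manifest: pd.DataFrame,
    wt_bonds: Sequence[PairKey | HBondOccupancy],
    criterion: HBondCriterion = HBondCriterion(),
) -> FitnessMatrix:
    """Count maintained WT bonds for every usable mutant structure.

    ``ensemble`` and ``manifest`` come from the mutate-and-minimize
    driver; frames are matched to manifest rows by label.  Failed
    mutants appear as NaN cells and are listed in ``missing``.
    """
    labels = list(ensemble.labels)
    if len(labels) != len(ensemble.frames):
        raise ValueError("ensemble has no per-frame labels")
    known = set(manifest["label"])
    stray = [lab for lab in labels if lab not in known]
    if stray:
        raise ValueError(f"ensemble labels missing from manifest: {stray[:5]}")

    positions = sorted(manifest["position"].unique())
    wt_seq = {
        int(p): manifest[manifest["position"] == p]["wt"].iloc[0]
        for p in positions
    }
    values = pd.DataFrame(
        np.nan, index=positions, columns=list(AMINO_ACIDS), dtype=float
    )
    for lab, frame in zip(labels, ensemble.frames):
        pos, mut = int(lab[1:-1]), lab[-1]
        values.at[pos, mut] = count_wt_bonds(frame, wt_bonds, criterion)
    missing = sorted(set(manifest["label"]) - set(labels))
    return FitnessMatrix(
        values=values,
        wt_sequence=wt_seq,
        n_wt_bonds=len(wt_bonds),
        missing=missing,
    )


def cap_energies(
    table: pd.DataFrame, cap: float = DEFAULT_ENERGY_CAP, column: str = "ddg"
) -> pd.DataFrame:
    """Cap destabilization energies at a ceiling (idempotent).

    Any mutation exceeding the cap is reported through the cap value
    itself; values at or below pass unchanged.
    """
    out = table.copy()
    vals = pd.to_numeric(out[column], errors="coerce")
    bad = vals.isna() & out[column].notna()
    if bad.any():
        raise ValueError(
            f"non-numeric energy in row(s) {list(out.index[bad])[:5]}"
        )
    out[column] = np.minimum(vals, cap)
    return out


def read_experiment_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited experiment table with header position,wt,mut,ddg."""
    table = pd.read_csv(path)
    required = {"position", "wt", "mut", "ddg"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"experiment table missing columns {sorted(missing)}")
    table["label"] = (
        table["wt"].astype(str) + table["position"].astype(str) + table["mut"].astype(str)
    )
    return table


def correlate(
    matrix: FitnessMatrix, experiment: pd.DataFrame, column: str = "ddg"
) -> dict:
    """Join the bond-count matrix with an experiment table and associate.

    Returns paired records plus Pearson and Spearman statistics with the
    pair count; mutants present on only one side are reported, excluded
    pairwise.  Row order of either input does not matter.
    """
    from scipy import stats

    if "label" not in experiment.columns:
        experiment = experiment.copy()
        experiment["label"] = (
            experiment["wt"].astype(str)
            + experiment["position"].astype(str)
            + experiment["mut"].astype(str)
        )
    long = matrix.long_form()
    merged = long.merge(experiment[["label", column]], on="label", how="inner")
    if merged.empty:
        raise ValueError("no overlapping mutation labels between inputs")
    x = merged["n_hb"].to_numpy(dtype=float)
    y = merged[column].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        pearson_r, pearson_p = np.nan, np.nan
        spearman_r, spearman_p = np.nan, np.nan
    else:
        pearson_r, pearson_p = stats.pearsonr(x, y)
        spearman_r, spearman_p = stats.spearmanr(x, y)
    return {
        "records": merged,
        "n": len(merged),
        "pearson_r": float(pearson_r),
        "pearson_p": float(pearson_p),
        "spearman_rho": float(spearman_r),
        "spearman_p": float(spearman_p),
        "only_in_matrix": sorted(set(long["label"]) - set(experiment["label"])),
        "only_in_experiment": sorted(set(experiment["label"]) - set(long["label"])),
    }
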