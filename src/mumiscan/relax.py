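"""Solvation and energy minimization of (mutant) structures.

Two backends stand behind one contract:

* ``"engine"`` delegates solvation and minimization to an external
  molecular-dynamics engine (registered through :func:`register_engine`);
  this is the route for production runs with a full force field in
  explicit water.
* ``"fallback"`` is an internal steepest-descent minimizer on a reduced
  vacuum potential — harmonic bonds and angles restrained at ideal
  template values, Lennard-Jones, and distance-capped Coulomb on charged
  groups.  It exists so that the whole pipeline is runnable and testable
  without an engine; its energies are in kcal/mol-like reduced units and
  are comparable only within one run.

:func:`build_box` prepares the solvated system description (cubic box
with a minimum solute–wall distance, pre-equilibrated water lattice
pruned around the solute, and isotonic KCl placed by seeded substitution
of waters) for the engine hand-off and for ion bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .mutator import MutationSpec, apply_mutation, detect_clashes
from .structure_io import Ensemble, Structure

__all__ = [
    "SolvationSpec",
    "MinimizationSpec",
    "RelaxResult",
    "SolvatedSystem",
    "EngineUnavailableError",
    "register_engine",
    "build_box",
    "minimize",
    "run_mumi",
    "exclude_failures",
    "MUMI_DYN_FAILED_LABELS",
]

AVOGADRO = 6.02214076e23
WATER_SPACING = 3.1035  # Å; one three-site water per site at 0.997 g/cm³
SOLUTE_WATER_MIN_DIST = 2.4  # Å heavy-atom overlap pruning
COULOMB_CONST = 332.0636  # kcal·Å/(mol·e²)
COULOMB_CAP = 2.0  # Å; Coulomb distance floor of the reduced potential

# GB1 mutants whose solvated systems showed runaway energies after side-chain
# insertion in the full-scale study conditions; shipped for bookkeeping.
MUMI_DYN_FAILED_LABELS = ("D40L", "E42H", "E42M", "E42F", "E42Y")

RESIDUE_FORMAL_CHARGE = {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1}

# reduced-potential Lennard-Jones parameters per element
LJ_SIGMA = {"C": 3.40, "N": 3.25, "O": 3.00, "S": 3.60, "H": 0.90, "Ar": 3.40,
            "P": 3.70, "Se": 3.70}
LJ_EPS = {"C": 0.086, "N": 0.17, "O": 0.21, "S": 0.25, "H": 0.010, "Ar": 0.238,
          "P": 0.20, "Se": 0.25}

# charged-group partial charges (reduced): carboxylates, ammonium, guanidinium
PARTIAL_CHARGES = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
}

# united-atom charges for polar heavy atoms (implicit hydrogens), so that
# hydrogen-bonded donor/acceptor contacts are energetically stable in the
# hydrogen-free reduced potential instead of being pushed apart by LJ
NAME_CHARGES = {
    "N": 0.20, "O": -0.40, "C": 0.25, "OXT": -0.40,
    "OG": -0.20, "OG1": -0.20, "OH": -0.20,
    "ND2": 0.20, "NE2": 0.20, "NE1": 0.20, "ND1": 0.20, "NE": 0.20,
    "OD1": -0.40, "OE1": -0.40,
}

PEPTIDE_BOND_LENGTH = 1.329
PEPTIDE_ANGLES = {
    ("CA", "C", "N"): 116.2,
    ("O", "C", "N"): 123.2,
    ("C", "N", "CA"): 121.7,
}
K_BOND = 300.0  # kcal/mol/Å²
K_ANGLE = 50.0  # kcal/mol/rad²


class EngineUnavailableError(RuntimeError):
    pass


_ENGINE: Callable | None = None


def register_engine(fn: Callable | None) -> None:
    """Register an external engine adapter: fn(system, spec) -> RelaxResult."""
    global _ENGINE
    _ENGINE = fn


@dataclass(frozen=True)
class SolvationSpec:
    padding: float = 10.0  # Å minimum solute–wall distance
    salt_concentration: float = 0.15  # mol/L KCl
    salt_species: tuple[str, str] = ("K", "CL")
    water_model: str = "tip3p"
    neutralize: bool = True

    def __post_init__(self):
        if self.padding <= 0:
            raise ValueError("padding must be positive")
        if self.salt_concentration < 0:
            raise ValueError("salt concentration must be non-negative")


@dataclass(frozen=True)
class MinimizationSpec:
    steps: int = 10000
    backend: str = "fallback"  # or "engine"
    energy_report_interval: int = 100
    energy_threshold: float | None = None  # flag "excess energy" above this

    def __post_init__(self):
        if self.steps <= 0:
            raise ValueError("steps must be positive")
        if self.backend not in ("engine", "fallback"):
            raise ValueError("backend must be 'engine' or 'fallback'")


@dataclass
class RelaxResult:
    structure: Structure  # solute only; waters/ions stripped
    initial_energy: float
    final_energy: float
    converged: bool
    failure_reason: str | None = None
    energy_trace: list[float] = field(default_factory=list)


@dataclass
class SolvatedSystem:
    solute: Structure
    water_oxygens: np.ndarray  # (n_water, 3)
    water_hydrogens: np.ndarray  # (n_water, 2, 3)
    ion_positions: dict[str, np.ndarray]
    box_edge: float
    spec: SolvationSpec
    seed: int

    @property
    def n_waters(self) -> int:
        return len(self.water_oxygens)


# ---------------------------------------------------------------------------
# Solvation
# ---------------------------------------------------------------------------

def solute_formal_charge(structure: Structure) -> int:
    q = 0
    for key in structure.residue_ids():
        rname = structure.residue_name_of(*key)
        q += RESIDUE_FORMAL_CHARGE.get(rname, 0)
    return q


def salt_pair_count(box_edge: float, concentration: float) -> int:
    """Ion pairs for a cubic box: round(c · V · N_A)."""
    volume_liters = (box_edge ** 3) * 1e-27
    return int(round(concentration * volume_liters * AVOGADRO))


def build_box(
    structure: Structure, spec: SolvationSpec = SolvationSpec(), seed: int = 0
) -> SolvatedSystem:
    """Cubic solvent box around the solute.

    The edge is the largest solute extent plus twice the padding, so
    periodic images stay separated by at least ``2 × padding``.  Waters
    sit on a density-matched lattice with seeded random orientations,
    pruned where a water oxygen would come within 2.4 Å of a solute
    heavy atom.  Salt ions (plus neutralizing counterions) replace
    randomly chosen waters, deterministically for a given seed.
    """
    rng = np.random.default_rng(seed)
    heavy = structure.coords[structure.heavy_mask]
    lo, hi = heavy.min(axis=0), heavy.max(axis=0)
    extent = float((hi - lo).max())
    edge = extent + 2.0 * spec.padding
    center = (lo + hi) / 2.0

    n_side = int(math.floor(edge / WATER_SPACING))
    offsets = (np.arange(n_side) - (n_side - 1) / 2.0) * WATER_SPACING
    gx, gy, gz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + center

    from scipy.spatial import cKDTree

    tree = cKDTree(heavy)
    d, _ = tree.query(sites, k=1)
    sites = sites[d >= SOLUTE_WATER_MIN_DIST]

    # seeded random orientations for the two hydrogens (0.9572 Å, 104.52°)
    n_w = len(sites)
    h = np.empty((n_w, 2, 3))
    half = math.radians(104.52 / 2.0)
    axes = rng.normal(size=(n_w, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    ref = rng.normal(size=(n_w, 3))
    perp = np.cross(axes, ref)
    perp /= np.linalg.norm(perp, axis=1, keepdims=True)
    d1 = math.cos(half) * axes + math.sin(half) * perp
    d2 = math.cos(half) * axes - math.sin(half) * perp
    h[:, 0, :] = sites + 0.9572 * d1
    h[:, 1, :] = sites + 0.9572 * d2

    n_pairs = salt_pair_count(edge, spec.salt_concentration)
    cation, anion = spec.salt_species
    n_cat, n_an = n_pairs, n_pairs
    if spec.neutralize:
        q = solute_formal_charge(structure)
        if q > 0:
            n_an += q
        elif q < 0:
            n_cat += -q
    n_ions = n_cat + n_an
    ion_positions: dict[str, np.ndarray] = {
        cation: np.zeros((0, 3)), anion: np.zeros((0, 3))
    }
    if n_ions > 0:
        if n_ions > n_w:
            raise ValueError("box too small to place requested ions")
        chosen = rng.choice(n_w, size=n_ions, replace=False)
        ion_positions[cation] = sites[chosen[:n_cat]].copy()
        ion_positions[anion] = sites[chosen[n_cat:]].copy()
        keep = np.ones(n_w, dtype=bool)
        keep[chosen] = False
        sites, h = sites[keep], h[keep]

    return SolvatedSystem(
        solute=structure.copy(),
        water_oxygens=sites,
        water_hydrogens=h,
        ion_positions=ion_positions,
        box_edge=edge,
        spec=spec,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Reduced vacuum potential (fallback backend)
# ---------------------------------------------------------------------------

class _ReducedPotential:
    """Harmonic bonds/angles + LJ + capped Coulomb on a fixed topology."""

    def __init__(self, structure: Structure):
        from .mutator import SideChainTemplate, _bond_graph

        self.n = len(structure)
        self.names = [str(x) for x in structure.name]
        self.resnames = [str(x) for x in structure.res_name]
        elements = [str(x) for x in structure.element]
        self.sigma = np.array([LJ_SIGMA.get(e, 3.4) for e in elements])
        self.eps = np.array([LJ_EPS.get(e, 0.1) for e in elements])
        from .structure_io import THREE_TO_ONE

        self.charge = np.array([
            PARTIAL_CHARGES.get(
                (rn, nm),
                NAME_CHARGES.get(nm, 0.0) if rn in THREE_TO_ONE else 0.0,
            )
            for rn, nm in zip(self.resnames, self.names)
        ])

        adj = _bond_graph(structure)
        # hydrogens the residue-template connectivity does not know
        # (e.g. terminal ammonium H1/H3) are bonded to the nearest heavy atom
        heavy_idx = [i for i, e in enumerate(elements) if e != "H"]
        for i, e in enumerate(elements):
            if e == "H" and not adj[i]:
                j = min(
                    heavy_idx,
                    key=lambda k: np.linalg.norm(
                        structure.coords[i] - structure.coords[k]
                    ),
                )
                adj[i].add(j)
                adj[j].add(i)
        # transfer united-atom charge onto explicit polar hydrogens so a
        # donor H sits between its heavy atom and the acceptor
        for i, e in enumerate(elements):
            if e == "H":
                self.charge[i] = 0.20
                for j in adj[i]:
                    self.charge[j] -= 0.20
        bonds = sorted(
            {(i, j) for i in range(self.n) for j in adj[i] if i < j}
        )
        same_res = lambda i, j: (
            structure.res_id[i] == structure.res_id[j]
            and structure.chain_id[i] == structure.chain_id[j]
        )

        tmpl_dist = {}

        def template_distance(rname, a, b):
            key = (rname, a, b)
            if key not in tmpl_dist:
                try:
                    t = SideChainTemplate.load(rname)
                    tmpl_dist[key] = float(np.linalg.norm(
                        t.coords[t.index(a)] - t.coords[t.index(b)]
                    ))
                except Exception:
                    tmpl_dist[key] = None
            return tmpl_dist[key]

        x0 = structure.coords
        self.bond_idx = np.array(bonds, dtype=int).reshape(-1, 2)
        r0 = []
        for i, j in bonds:
            if same_res(i, j):
                d = template_distance(self.resnames[i], self.names[i], self.names[j])
            elif {self.names[i], self.names[j]} == {"C", "N"}:
                d = PEPTIDE_BOND_LENGTH
            else:
                d = None
            if d is None:
                d = float(np.linalg.norm(x0[i] - x0[j]))
            r0.append(d)
        self.bond_r0 = np.array(r0)

        # connected triples i-j-k (vertex j)
        triples = []
        theta0 = []
        for j in range(self.n):
            nbrs = sorted(adj[j])
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    i, k = nbrs[a], nbrs[b]
                    triples.append((i, j, k))
                    if same_res(i, j) and same_res(j, k):
                        t0 = self._template_angle(
                            structure, template_distance, i, j, k
                        )
                    else:
                        key = (self.names[i], self.names[j], self.names[k])
                        t0 = PEPTIDE_ANGLES.get(key) or PEPTIDE_ANGLES.get(key[::-1])
                    if t0 is None:
                        u, v = x0[i] - x0[j], x0[k] - x0[j]
                        cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                        t0 = math.degrees(math.acos(max(-1.0, min(1.0, cos))))
                    theta0.append(math.radians(t0))
        self.angle_idx = np.array(triples, dtype=int).reshape(-1, 3)
        self.angle_t0 = np.array(theta0)

        # nonbonded exclusions: 1-2 and 1-3
        excl = {tuple(b) for b in bonds}
        for i, j, k in triples:
            excl.add((min(i, k), max(i, k)))
        pairs = [
            (i, j)
            for i in range(self.n)
            for j in range(i + 1, self.n)
            if (i, j) not in excl
        ]
        self.nb_idx = np.array(pairs, dtype=int).reshape(-1, 2)

    @staticmethod
    def _template_angle(structure, template_distance, i, j, k):
        from .mutator import SideChainTemplate

        rname = str(structure.res_name[j])
        names = (str(structure.name[i]), str(structure.name[j]),
                 str(structure.name[k]))
        try:
            t = SideChainTemplate.load(rname)
            p = [t.coords[t.index(nm)] for nm in names]
        except Exception:
            return None
        u, v = p[0] - p[1], p[2] - p[1]
        cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return math.degrees(math.acos(max(-1.0, min(1.0, cos))))

    def energy_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        e = 0.0
        g = np.zeros_like(x)

        if len(self.bond_idx):
            i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
            d = x[i] - x[j]
            r = np.linalg.norm(d, axis=1)
            dr = r - self.bond_r0
            e += float(np.sum(K_BOND * dr ** 2))
            f = (2.0 * K_BOND * dr / r)[:, None] * d
            np.add.at(g, i, f)
            np.add.at(g, j, -f)

        if len(self.angle_idx):
            ia, ij, ik = (self.angle_idx[:, c] for c in range(3))
            u = x[ia] - x[ij]
            v = x[ik] - x[ij]
            ru = np.linalg.norm(u, axis=1)
            rv = np.linalg.norm(v, axis=1)
            uh = u / ru[:, None]
            vh = v / rv[:, None]
            cos = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
            theta = np.arccos(cos)
            sin = np.sqrt(np.maximum(1e-12, 1.0 - cos ** 2))
            dt = theta - self.angle_t0
            e += float(np.sum(K_ANGLE * dt ** 2))
            coef = 2.0 * K_ANGLE * dt
            ga = (coef / (ru * sin))[:, None] * (cos[:, None] * uh - vh)
            gc = (coef / (rv * sin))[:, None] * (cos[:, None] * vh - uh)
            np.add.at(g, ia, ga)
            np.add.at(g, ik, gc)
            np.add.at(g, ij, -(ga + gc))

        if len(self.nb_idx):
            i, j = self.nb_idx[:, 0], self.nb_idx[:, 1]
            d = x[i] - x[j]
            r = np.linalg.norm(d, axis=1)
            r = np.maximum(r, 1e-6)
            sig = 0.5 * (self.sigma[i] + self.sigma[j])
            eps = np.sqrt(self.eps[i] * self.eps[j])
            sr6 = (sig / r) ** 6
            e += float(np.sum(4.0 * eps * (sr6 ** 2 - sr6)))
            dEdr = 4.0 * eps * (-12.0 * sr6 ** 2 + 6.0 * sr6) / r
            qq = self.charge[i] * self.charge[j]
            has_q = qq != 0.0
            if has_q.any():
                rc = np.maximum(r, COULOMB_CAP)
                e += float(np.sum(COULOMB_CONST * qq / rc))
                dEdr_c = np.where(
                    r > COULOMB_CAP, -COULOMB_CONST * qq / rc ** 2, 0.0
                )
                dEdr = dEdr + dEdr_c
            f = (dEdr / r)[:, None] * d
            np.add.at(g, i, f)
            np.add.at(g, j, -f)

        return e, g


def _descend(
    potential: _ReducedPotential,
    x0: np.ndarray,
    spec: MinimizationSpec,
) -> tuple[np.ndarray, list[float], bool, str | None]:
    """Monotone first-order minimization (nonlinear conjugate gradient).

    Polak–Ribière directions with automatic restart and a backtracking
    line search that only ever accepts energy-non-increasing steps, so
    the reported energy sequence is monotone by construction.
    """
    x = x0.copy()
    e, g = potential.energy_grad(x)
    trace = [e]
    d = -g
    alpha = 1e-3
    max_disp = 0.5  # Å per step
    g_prev = g
    for step in range(1, spec.steps + 1):
        gmax = float(np.abs(g).max()) if g.size else 0.0
        if not math.isfinite(e) or not math.isfinite(gmax):
            return x, trace, False, "non-finite energy"
        if gmax < 1e-8:
            break
        if float((d * g).sum()) >= 0.0:
            d = -g  # restart: direction no longer a descent direction
        accepted = False
        for _ in range(50):
            delta = alpha * d
            norm = np.abs(delta).max()
            if norm > max_disp:
                delta = delta * (max_disp / norm)
            e_new, g_new = potential.energy_grad(x + delta)
            if math.isfinite(e_new) and e_new <= e:
                x = x + delta
                g_prev, g = g, g_new
                e = e_new
                beta = max(
                    0.0,
                    float((g * (g - g_prev)).sum())
                    / max(float((g_prev * g_prev).sum()), 1e-30),
                )
                d = -g + beta * d
                alpha = min(alpha * 1.6, 10.0)
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            if (d + g).any():  # was a CG direction: retry along -g
                d = -g
                alpha = 1e-3
                continue
            break  # at a numerical fixed point even along -g
        if step % spec.energy_report_interval == 0:
            trace.append(e)
    trace.append(e)
    return x, trace, True, None


def minimize(
    system: SolvatedSystem | Structure,
    spec: MinimizationSpec = MinimizationSpec(),
) -> RelaxResult:
    """Minimize a system; return the relaxed solute and energy bookkeeping.

    The engine backend requires a registered external adapter and raises
    :class:`EngineUnavailableError` otherwise, instructing use of the
    fallback.  The fallback backend minimizes the solute in vacuum on the
    reduced potential; waters and ions of a solvated system are not part
    of its degrees of freedom.
    """
    if spec.backend == "engine":
        if _ENGINE is None:
            raise EngineUnavailableError(
                "no molecular-dynamics engine adapter is registered; "
                "register one with relax.register_engine(...) or use "
                "MinimizationSpec(backend='fallback')"
            )
        return _ENGINE(system, spec)

    structure = system.solute if isinstance(system, SolvatedSystem) else system
    solute = structure.subset(structure.solute_mask)
    potential = _ReducedPotential(solute)
    x_final, trace, ok, reason = _descend(potential, solute.coords, spec)
    final = solute.copy()
    final.coords = x_final
    initial_e, final_e = trace[0], trace[-1]
    converged = ok and math.isfinite(final_e) and final_e <= initial_e + 1e-9
    if converged and spec.energy_threshold is not None and final_e > spec.energy_threshold:
        converged = False
        reason = (
            f"excess energy: final energy {final_e:.3g} above threshold "
            f"{spec.energy_threshold:.3g}"
        )
    return RelaxResult(
        structure=final,
        initial_energy=initial_e,
        final_energy=final_e,
        converged=converged,
        failure_reason=reason,
        energy_trace=trace,
    )


# ---------------------------------------------------------------------------
# MuMi driver
# ---------------------------------------------------------------------------

def exclude_failures(
    specs: Sequence[MutationSpec], failed_labels: Sequence[str]
) -> list[MutationSpec]:
    """Usable specs after removing the listed failed mutants."""
    failed = set(failed_labels)
    return [s for s in specs if s.label not in failed]


def run_mumi(
    wt: Structure,
    specs: Sequence[MutationSpec],
    chain: str,
    solvation: SolvationSpec = SolvationSpec(),
    minimization: MinimizationSpec = MinimizationSpec(),
    outlier_sigma: float = 5.0,
    clash_threshold: float = 2.0,
):
    """Mutate and minimize every spec; collect usable mutants and a manifest.

    Each mutant is processed in isolation: construction or minimization
    problems are recorded in the manifest, never fatal.  After the cohort
    completes, mutants whose final energy is non-finite or exceeds the
    converged cohort mean by ``outlier_sigma`` standard deviations are
    flagged as excess-energy failures.  Returns ``(ensemble, manifest)``
    where the ensemble (source ``"mutant-collection"``) holds the usable
    relaxed structures and the manifest is a tidy per-mutant table.
    """
    import pandas as pd

    records = []
    results: dict[str, RelaxResult] = {}
    for s in specs:
        row = {
            "label": s.label, "position": s.position,
            "wt": s.wt_aa, "mut": s.mut_aa,
            "converged": False, "initial_energy": np.nan,
            "final_energy": np.nan, "clash_count": np.nan,
            "failure_reason": None,
        }
        try:
            mutant = apply_mutation(wt, s, chain=chain)
            row["clash_count"] = len(detect_clashes(mutant, clash_threshold))
            if minimization.backend == "fallback":
                # the reduced potential is hydrogen-aware: protonate first
                from .hbond import add_polar_hydrogens

                mutant = add_polar_hydrogens(mutant)
            res = minimize(mutant, minimization)
            results[s.label] = res
            row["converged"] = res.converged
            row["initial_energy"] = res.initial_energy
            row["final_energy"] = res.final_energy
            row["failure_reason"] = res.failure_reason
        except Exception as exc:
            row["failure_reason"] = str(exc)
        records.append(row)

    manifest = pd.DataFrame(
        records,
        columns=["label", "position", "wt", "mut", "converged",
                 "initial_energy", "final_energy", "clash_count",
                 "failure_reason"],
    )
    if manifest.empty:
        return Ensemble(frames=[], source="mutant-collection", labels=[]), manifest
    finite = manifest["converged"] & np.isfinite(manifest["final_energy"])
    if finite.sum() >= 3:
        cohort = manifest.loc[finite, "final_energy"]
        cutoff = cohort.mean() + outlier_sigma * cohort.std(ddof=0)
        outliers = finite & (manifest["final_energy"] > cutoff)
        manifest.loc[outliers, "converged"] = False
        manifest.loc[outliers, "failure_reason"] = (
            f"excess energy: above cohort mean + {outlier_sigma}σ"
        )
    usable = manifest[manifest["converged"]]["label"].tolist()
    frames = [results[lab].structure for lab in usable]
    ensemble = Ensemble(frames=frames, source="mutant-collection", labels=usable)
    return ensemble, manifest
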