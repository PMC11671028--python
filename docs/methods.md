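# Methods

## Scope and model

The package implements a structure-based proxy for a binding deep
mutational scan. The model assumption is that a single side-chain
replacement followed by energy minimization — no further dynamics —
captures enough of the conformational shift to predict whether the
mutant still makes the wild-type interface interactions. The fitness
proxy is therefore a plain count: of the wild-type *dominant* interface
hydrogen bonds (occupancy > 20% in the wild-type bound-state ensemble),
how many remain geometrically satisfied in the relaxed mutant.

## Structure model and PDB conventions

Structures are column-oriented atom tables (serial, name, element,
coordinates in Å, author residue number, residue name, chain, hetero
flag). Author numbering is authoritative: every residue reference
(E27, K28, W43, …) resolves through the numbering of the source PDB
file, never through a sequential index. Parsing and writing go through
biotite; on top of it the package resolves alternate locations to the
highest-occupancy conformer (ties: first listed), retains but flags
waters and hetero groups, and rejects insertion codes outright — the
GB1 system has none, and refusing them keeps all residue-pairing logic
one-to-one. Round trips are coordinate-stable to 10⁻³ Å (the PDB
fixed-column precision). Heavy-atom RMSD defaults to *no*
superposition: minimization does not move the frame, so the raw
deviation is the quantity of interest; an optimal least-squares fit is
available behind a flag.

## Mutant construction

Side chains are replaced, never repacked: the mutated residue keeps N,
CA, C, O (and OXT) exactly, all other residues are untouched, and the
new side chain comes from the ideal-coordinate residue templates of the
chemical component dictionary bundled with biotite, posed by a rigid
fit of the template's N/CA/C onto the target backbone. One template
conformer per residue type is used, with χ1 set to the modal rotamer of
standard rotamer surveys (gauche⁻ for most types; *trans* for valine,
gauche⁺ for serine/threonine). There is no rotamer optimization — the
scheme deliberately relies on the subsequent minimization to relieve
strain. Only when the graft leaves heavy-atom contacts shorter than
1.5 Å is a deterministic coarse sweep applied: χ1 (then χ2) in 30°
steps, keeping the clash-minimal conformer, ties broken by the smallest
torsion change. Proline is introduced without ring-closure refinement;
histidine is built as the neutral ND1-protonated tautomer
(configurable). Clash detection for reporting excludes bonded and 1–3
pairs, with residue-template connectivity; peptide links are only
accepted when the C–N distance is geometrically real (≤ 2.0 Å), so
fixtures with spatially separated residues on one chain do not acquire
phantom bonds.

## Solvation and minimization

`build_box` follows the study conditions: a cubic box whose edge is the
largest solute extent plus twice the padding (default 10 Å, so
periodic images stay ≥ 20 Å apart), a density-matched water lattice
(3.1035 Å spacing ≈ 0.997 g/cm³ for a three-site model) with seeded
random orientations, pruned where a water oxygen would come within
2.4 Å of a solute heavy atom, and KCl at 0.15 M — ion pairs =
round(c·V·N_A) — plus neutralizing counterions, placed by seeded random
substitution of waters. Identical seeds give byte-identical boxes.
Temperature/pressure (310 K, 1 atm) are recorded in the solvation spec
only for engine hand-off; no dynamics are integrated here.

Minimization has two backends behind one contract. The **engine**
backend delegates to an external MD engine registered via
`relax.register_engine` (production route: full force field, explicit
water, 10,000 steps); without a registered adapter it raises a clear
error instructing use of the fallback. The **fallback** backend is an
internal minimizer on a reduced vacuum potential: harmonic bonds and
angles restrained at ideal template values (peptide C–N 1.329 Å;
unknown terms restrained at their initial values), Lennard-Jones with
per-element parameters, and distance-capped Coulomb (floor 2.0 Å) on
charged groups plus small united-atom charges on polar heavy atoms.
The potential is hydrogen-aware: polar hydrogens (placed before
minimization in the mutate-and-minimize driver) carry +0.2 e drawn from
their heavy atom and a small LJ radius, which makes ideal
donor–H–acceptor geometry an actual minimum instead of letting bare
heavy-atom LJ push donor–acceptor pairs past the 3.0 Å criterion.
Energies are in reduced kcal/mol-like units, comparable only within a
run. The descent is nonlinear conjugate gradient (Polak–Ribière with
restart) with a backtracking line search that accepts only
non-increasing energies, so the reported energy trace is monotone by
construction; plain steepest descent proved too slow near minima to
honor the re-minimization fixed-point contract, and conjugate gradient
is also the default minimizer of the engines this pipeline targets.
Failure handling mirrors the study's "excess energy" flag: a mutant is
unusable when its energy goes non-finite, exceeds a configured
threshold, or lies more than 5σ above the converged cohort mean. The
five labels known to fail at full scale (D40L, E42H, E42M, E42F, E42Y)
ship as a bookkeeping constant.

## Hydrogen bonds

The geometric criterion is donor–acceptor distance ≤ 3.0 Å and angle
≤ 20°, both inclusive (a 10⁻⁹ slack absorbs floating-point error at
exactly-constructed boundaries). The angle is measured by default at
the donor between the D→H and D→A vectors; the alternative
"linearity" convention (deviation of D–H···A from 180°) is available
because the literature does not always state which is meant. Donor and
acceptor chemistry follows canonical residue rules (backbone N–H
donors except proline, backbone O/OXT acceptors; S/T/Y hydroxyls in
both roles; charged groups included; histidine per tautomer; sulfur
acceptors excluded). Crystal inputs carry no hydrogens, so
`add_polar_hydrogens` constructs them at ideal geometry: in-plane
placement for amide and ring N–H, analytic cone placement for
rotatable O–H/S–H/N–H₃⁺ groups with the azimuth chosen toward the
nearest acceptor (ties: lowest residue index, then atom name) —
deterministic and idempotent.

Ensemble occupancy is aggregated at residue–moiety (backbone vs
side-chain) granularity, the resolution of published interface
occupancy tables: a pair is present in a frame if at least one atomic
bond matches it. `dominant_bonds` keeps pairs strictly above the
threshold (default 20%). Salt bridges are reported as the distance
between the centroid of the acidic side-chain carboxylate oxygens and
the centroid of the basic side-chain nitrogens; a ≤ 4.0 Å convention
is suggested for "formed" summaries but never imposed.

## SASA and RSA

SASA is in-package Shrake–Rupley with a deterministic Fibonacci-spiral
point set (default 960 points, probe 1.4 Å), per-element radii
(C 1.70, N 1.55, O 1.52, S 1.80 Å), hydrogens excluded. The
implementation is cross-checked in the tests against an independent
library implementation; the two agree within 1% and the isolated-sphere
case is exact to the point-set resolution. RSA divides residue SASA by
the theoretical maximum of the Tien et al. (2013) scale (empirical
scale available) and is reported in percent because the surface
threshold of the method ("RSA > 25") is a percent. Values above 100
(extended conformations) are permitted and flagged. Ensemble statistics
report per-residue mean and population σ; for mutant collections the
statistics run over mutants, so every usable mutant contributes one
observation at every position.

## Interface statistics

A focal residue is in the binding region when any of its heavy atoms is
strictly within the cutoff (default 5.0 Å) of any partner heavy atom;
waters, ions and hydrogens are excluded. Over an ensemble the
per-residue contact fraction estimates the binding-region probability;
for mutant collections the denominator is the number of usable mutants,
i.e. a residue's probability aggregates over all substitutions at all
positions. Candidate positions for the dynamic extension are those
whose probability exceeds the wild-type indicator, ranked by
probability with residue-index tie-breaks; the package derives this set
from its own ranking rather than hard-coding it, and records the chosen
set in the run manifest. The binding-proximal position list shipped for
GB1 bookkeeping (25, 27, 28, 29, 31, 32, 33, 35, 36, 40, 41, 42, 43,
54, giving 14 × 19 = 266 mutants and 261 usable systems after the five
known failures) is exactly that: bookkeeping for the full-scale study
conditions, not an input to any algorithm.

## Fitness matrix and comparison to experiment

`build_matrix` counts maintained wild-type dominant bonds per usable
mutant; failed mutants appear as missing cells, enumerated in the
matrix metadata and excluded pairwise from correlations.
Destabilization energies are capped at 9 kcal/mol (idempotent); any
mutation exceeding that destabilization is reported through the cap.
The package reports Pearson and Spearman statistics with *n* and the
direction convention (association with the bond count is expected
negative) but never folds the sign into a score. The experiment table
is user-supplied; a synthetic stand-in generator (monotone map of the
bond count plus Gaussian noise of configurable σ) ships with the
fixtures for exercising the machinery and is labelled synthetic
throughout.

## Synthetic fixtures: what they emulate, and what they do not

The generators provide known ground truth with no downloads: ideal
α-helical peptides (φ = −57°, ψ = −47°; the N–CA–C angle is set to
110.0°, the tight end of the helical range, so the i→i+4 amide
geometry closes under the 3.0 Å criterion), toy dimers realizing
prescribed donor–acceptor distances/angles exactly, a synthetic
bound-complex mimic carrying the wild-type nine-bond interface pattern
(two bonds each at positions 27 and 28, one each at 35/39/40/42/43),
and jitter ensembles: i.i.d. Gaussian coordinate noise, seeded. Jitter
is *not* physical dynamics — it has no correlations, no solvent and no
energy model — it exists solely to exercise occupancy/probability
counting statistics. Tests passing on these fixtures demonstrate the
correctness of the geometry, counting and bookkeeping machinery, not
the physical fidelity of any relaxed structure; physical fidelity at
full scale depends on the MD-engine backend and the real crystal
structures, which the optional reproduction script
(`examples/full_reproduction.py`) addresses.

## Numerical choices and problem sizes

Boundary comparisons are inclusive with 10⁻⁹ slack; spatial searches
use k-d trees and are verified against exhaustive O(N²) oracles in the
tests; sphere integration uses 960 points (doubling changes totals by
< 0.5%). The test suite and the acceptance script run everything at
desk scale — toy dimers of a few residues, 57-mutant scans at 150
minimization steps, 200-frame ensembles — sizes chosen so the whole
suite completes in a few minutes while still exercising every stage;
the full-scale study conditions (1064 mutants, 10,000 steps, solvated
boxes, microsecond trajectories) are reached by turning the same knobs
up with an engine registered.

## Known limitations

No rotamer optimization or neighbor repacking; no multi-point mutants
or epistasis; no water-mediated or π-interactions; no energetic
hydrogen-bond scoring; the fallback potential is a reduced model whose
energies are not comparable to force-field energies; mmCIF and
compressed trajectory formats are out of scope (multi-model PDB is the
ensemble interchange format); crystallographic symmetry is not
expanded.
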