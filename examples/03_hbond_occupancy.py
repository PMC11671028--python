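"""Detect interface hydrogen bonds and their ensemble occupancy.

A hydrogen bond is a donor-acceptor pair within 3.0 Å whose donor-vertex
angle is at most 20 degrees. Over an ensemble, the occupancy of a
residue pair is the fraction of frames in which the bond is present;
pairs above 20% occupancy are the dominant bonds that maintain binding.
"""

from mumiscan import add_polar_hydrogens, detect_hbonds, dominant_bonds, occupancy
from mumiscan.fixtures import make_jitter_ensemble, make_toy_dimer

dimer, manifest = make_toy_dimer(
    [("A", "A", 2.8, 5.0), ("S", "A", 2.7, 8.0), ("A", "G", 2.9, 5.0)]
)
protonated = add_polar_hydrogens(dimer)
for b in detect_hbonds(protonated, between=({"A"}, {"B"})):
    print(f"donor {b.donor[0]}:{b.donor[1]} -> acceptor "
          f"{b.acceptor[0]}:{b.acceptor[1]}  d={b.distance:.2f} A, "
          f"angle={b.angle:.1f} deg")

ensemble = make_jitter_ensemble(protonated, sigma=0.25, n_frames=100, seed=7)
occ = occupancy(ensemble, between=({"A"}, {"B"}))
print("\noccupancies over 100 jittered frames (thermal-noise stand-in):")
for o in dominant_bonds(occ, threshold=0.20):
    print(f"  {o.pair[0]} -- {o.pair[1]}: {o.occupancy:.0%}")
# Bonds built closer to the 3.0 Å limit lose occupancy fastest under
# coordinate noise — the same ranking logic used on MD trajectories.
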