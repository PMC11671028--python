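import math

import numpy as np
import pytest

from mumiscan.fixtures import make_helix_peptide, make_toy_dimer


@pytest.fixture(scope="session")
def helix10():
    return make_helix_peptide(10)


@pytest.fixture(scope="session")
def dimer3():
    """Toy dimer with three designed interface bonds, all inside cutoffs."""
    return make_toy_dimer(
        [("A", "A", 2.8, 5.0), ("S", "A", 2.7, 8.0), ("A", "G", 2.9, 5.0)]
    )


# ---------------------------------------------------------------------------
# Independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_hbonds(structure, criterion):
    """Exhaustive O(N²) hydrogen-bond detection over all donor/acceptor pairs.

    Pure-python double loop with scalar math; shares only the chemistry
    tables with the production detector, not its spatial search or its
    vector path.
    """
    from mumiscan.hbond import _acceptor_entries, _donor_triples

    found = set()
    acceptors = _acceptor_entries(structure)
    for d_i, h_i, d_moiety in _donor_triples(structure):
        for a_i, a_moiety in acceptors:
            if a_i == d_i:
                continue
            if (
                structure.chain_id[a_i] == structure.chain_id[d_i]
                and structure.res_id[a_i] == structure.res_id[d_i]
                and a_moiety == d_moiety
            ):
                continue
            d = structure.coords[d_i]
            h = structure.coords[h_i]
            a = structure.coords[a_i]
            dist = math.dist(list(d), list(a))
            if dist > criterion.d_max + 1e-9:
                continue
            if criterion.angle_convention == "donor":
                v1 = h - d
                v2 = a - d
            else:
                v1 = d - h
                v2 = h - a
            cos = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cos))))
            if ang > criterion.theta_max + 1e-9:
                continue
            found.add((d_i, h_i, a_i))
    return found


def hbond_atom_triples(structure, bonds):
    """Map detector output to (donor, hydrogen, acceptor) index triples."""
    index = {}
    for i in range(len(structure)):
        key = (
            str(structure.chain_id[i]), int(structure.res_id[i]),
            str(structure.res_name[i]), str(structure.name[i]),
        )
        index[key] = i
    return {(index[b.donor], index[b.hydrogen], index[b.acceptor]) for b in bonds}
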