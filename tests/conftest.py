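"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from interactor import DEFAULT_CONFIG, make_ideal_helix, make_toy_core
from interactor.fixtures import _structure_from_atoms

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def helix10():
    return make_ideal_helix(10)


@pytest.fixture(scope="session")
def toy_core():
    return make_toy_core()


def build_structure(atom_specs, **kwargs):
    """Construct a structure through the PDB round-trip path."""
    return _structure_from_atoms(atom_specs, **kwargs)


def brute_force_contact_counts(structure, config=DEFAULT_CONFIG):
    """Independent O(n^2) oracle for the four contact counts.

    Re-derives covalent adjacency from the distance rule, covalent path
    lengths with networkx BFS, and band membership with explicit double
    loops over the full distance matrix.  Returns
    (repulsive, vdw, london, hydrophobic_total).
    """
    import networkx as nx
    from scipy.spatial.distance import squareform, pdist

    atoms = [a for a in structure.atoms if a.element != "H"]
    ids = [i for i, a in enumerate(structure.atoms) if a.element != "H"]
    coords = np.array([a.coords for a in atoms])
    n = len(atoms)
    dmat = squareform(pdist(coords))

    cov = np.array([config.covalent_radii.get(a.element, 0.77)
                    for a in atoms])
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if dmat[i, j] <= cov[i] + cov[j] + config.covalent_tolerance:
                g.add_edge(i, j)
    cap = config.contacts.min_bonded_path
    path = {i: nx.single_source_shortest_path_length(g, i, cutoff=cap - 1)
            for i in range(n)}

    vdw = np.array([config.vdw_radii.get(a.element,
                                         config.default_vdw_radius)
                    for a in atoms])
    apolar = []
    for i, a in enumerate(atoms):
        if not a.is_sidechain:
            apolar.append(False)
        elif a.element in ("S", "SE"):
            apolar.append(True)
        elif a.element == "C":
            apolar.append(not any(atoms[j].element in ("N", "O")
                                  for j in g.neighbors(i)))
        else:
            apolar.append(False)

    c = config.contacts
    n_rep = n_vdw = n_lon = n_hyd = 0
    for i in range(n):
        for j in range(i + 1, n):
            if path[i].get(j, cap) < cap:
                continue
            d = dmat[i, j]
            rsum = vdw[i] + vdw[j]
            if d < rsum:
                n_rep += 1
            elif d <= rsum + c.vdw_band:
                n_vdw += 1
            elif d <= rsum + c.london_band:
                n_lon += 1
            if (d <= c.hydrophobic_cutoff and apolar[i] and apolar[j]
                    and atoms[i].residue_index != atoms[j].residue_index):
                n_hyd += 1
    return n_rep, n_vdw, n_lon, n_hyd


def package_contact_counts(structure, config=DEFAULT_CONFIG):
    """The package's own four contact counts for oracle comparison."""
    from interactor import assign_vdw_radii, neighbor_pairs
    from interactor.interactions import (hydrophobic_contacts,
                                         london_contacts, pair_cutoff,
                                         repulsive_contacts, vdw_contacts)

    assign_vdw_radii(structure, config)
    pairs = neighbor_pairs(structure, pair_cutoff(config), config)
    n_hyd = hydrophobic_contacts(structure, pairs, None, config)[0]
    return (repulsive_contacts(structure, pairs, config),
            vdw_contacts(structure, pairs, config),
            london_contacts(structure, pairs, config),
            n_hyd)
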