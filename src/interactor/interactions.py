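"""The 11 per-protein structural features built on interatomic interactions.

Non-bonded heavy-atom pairs are partitioned into three contiguous distance
bands keyed to the vdW radius sum R = r_i + r_j:

* repulsive        d <  R            (electron-cloud overlap / clash)
* van der Waals    R <= d <= R+0.7   (contact band)
* London dispersion R+0.7 < d <= R+3.0  (longer-range attraction)

so the three counts are disjoint by construction.  Hydrophobic contacts,
hydrogen-bond scores, the rotatable-bond flexibility proxy ("deformation
effect"), surface-tension sums and total ASA complete the 11 features.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import _chem
from .config import DEFAULT_CONFIG, FeatureConfig
from .geometry import (AsaResult, NeighborPair, assign_vdw_radii,
                       compute_asa, detect_hbonds, ensure_bonds,
                       neighbor_pairs)
from .structure_io import ProteinStructure

__all__ = [
    "InteractionVector", "INTERACTION_FEATURE_NAMES",
    "vdw_contacts", "repulsive_contacts", "london_contacts",
    "hydrophobic_contacts", "deformation_effect", "tension_features",
    "interaction_vector", "pair_cutoff",
]

INTERACTION_FEATURE_NAMES = (
    "total_hydrophobic_contacts",
    "total_vdw_interactions",
    "deformation_effect",
    "intramolecular_hbond_score",
    "repulsive_interactions",
    "london_dispersion_forces",
    "total_hydrophobicity",
    "internal_hydrophobicity",
    "total_surface_tension",
    "internal_tension",
    "total_asa",
)


@dataclass(frozen=True)
class InteractionVector:
    """The 11 structural feature values for one protein chain."""

    total_hydrophobic_contacts: float
    total_vdw_interactions: float
    deformation_effect: float
    intramolecular_hbond_score: float
    repulsive_interactions: float
    london_dispersion_forces: float
    total_hydrophobicity: float
    internal_hydrophobicity: float
    total_surface_tension: float
    internal_tension: float
    total_asa: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name)
                for name in INTERACTION_FEATURE_NAMES}


def pair_cutoff(config: FeatureConfig = DEFAULT_CONFIG) -> float:
    """Neighbor-search radius covering every contact band."""
    r_max = max(config.vdw_radii.values())
    return max(2 * r_max + config.contacts.london_band,
               config.contacts.hydrophobic_cutoff,
               config.hbond.d_max)


def _nonbonded(pairs: list[NeighborPair],
               config: FeatureConfig) -> list[NeighborPair]:
    return [p for p in pairs if p.bonded_path >= config.contacts.min_bonded_path]


def _radius_sum(structure: ProteinStructure, p: NeighborPair) -> float:
    return (structure.atoms[p.atom_i].vdw_radius
            + structure.atoms[p.atom_j].vdw_radius)


def vdw_contacts(structure: ProteinStructure, pairs: list[NeighborPair],
                 config: FeatureConfig = DEFAULT_CONFIG) -> int:
    """Pairs in the contact band R <= d <= R + vdw_band."""
    band = config.contacts.vdw_band
    return sum(1 for p in _nonbonded(pairs, config)
               if _radius_sum(structure, p) <= p.d
               <= _radius_sum(structure, p) + band)


def repulsive_contacts(structure: ProteinStructure, pairs: list[NeighborPair],
                       config: FeatureConfig = DEFAULT_CONFIG) -> int:
    """Pairs closer than the vdW radius sum (electron-cloud overlap)."""
    return sum(1 for p in _nonbonded(pairs, config)
               if p.d < _radius_sum(structure, p))


def london_contacts(structure: ProteinStructure, pairs: list[NeighborPair],
                    config: FeatureConfig = DEFAULT_CONFIG) -> int:
    """Pairs in the dispersion band R + vdw_band < d <= R + london_band."""
    c = config.contacts
    count = 0
    for p in _nonbonded(pairs, config):
        r = _radius_sum(structure, p)
        if r + c.vdw_band < p.d <= r + c.london_band:
            count += 1
    return count


def _hydrophobic_atom_ids(structure: ProteinStructure,
                          config: FeatureConfig) -> set[int]:
    """Side-chain apolar atoms: S/Se, and C not bonded to N or O."""
    bonds = ensure_bonds(structure, config)
    out = set()
    for i, atom in enumerate(structure.atoms):
        if not atom.is_sidechain or atom.element == "H":
            continue
        if atom.element in ("S", "SE"):
            out.add(i)
        elif atom.element == "C":
            if not any(structure.atoms[j].element in ("N", "O")
                       for j in bonds.neighbors(i)):
                out.add(i)
    return out


def hydrophobic_contacts(structure: ProteinStructure,
                         pairs: list[NeighborPair],
                         asa: AsaResult | None = None,
                         config: FeatureConfig = DEFAULT_CONFIG
                         ) -> tuple[int, int, float, float]:
    """Hydrophobic contact counts and hydropathy-weighted sums.

    A contact is a pair of side-chain apolar heavy atoms from distinct
    residues within ``hydrophobic_cutoff``.  Weighted sums add the mean
    Kyte-Doolittle value of the two residues per contact; the "internal"
    variants keep only contacts where both residues are buried
    (relative ASA below ``burial_rasa``).
    """
    c = config.contacts
    apolar = _hydrophobic_atom_ids(structure, config)
    buried = None
    if asa is not None:
        buried = asa.per_residue_relative_asa < c.burial_rasa
    n_total = n_internal = 0
    w_total = w_internal = 0.0
    for p in _nonbonded(pairs, config):
        if p.d > c.hydrophobic_cutoff:
            continue
        if p.atom_i not in apolar or p.atom_j not in apolar:
            continue
        ai, aj = structure.atoms[p.atom_i], structure.atoms[p.atom_j]
        if ai.residue_index == aj.residue_index:
            continue
        kd = 0.5 * (config.hydropathy.get(ai.residue_code, 0.0)
                    + config.hydropathy.get(aj.residue_code, 0.0))
        n_total += 1
        w_total += kd
        if buried is not None and buried[ai.residue_index] \
                and buried[aj.residue_index]:
            n_internal += 1
            w_internal += kd
    return n_total, n_internal, w_total, w_internal


def deformation_effect(structure: ProteinStructure,
                       config: FeatureConfig = DEFAULT_CONFIG) -> int:
    """Rotatable-bond count, a static proxy for conformational flexibility.

    Counts acyclic single bonds between heavy atoms that each have at
    least two heavy neighbors, excluding amide bonds and bonds whose both
    endpoints are sp2 (conjugated linkages such as the peptide bond in
    distance-inferred graphs).
    """
    bonds = ensure_bonds(structure, config)
    g = nx.Graph()
    heavy = set(structure.heavy_atom_ids())
    for (i, j), bond_type in bonds.edges.items():
        if i in heavy and j in heavy:
            g.add_edge(i, j, bond_type=bond_type)
    bridges = set(frozenset(e) for e in nx.bridges(g)) if len(g) else set()
    count = 0
    for (i, j), bond_type in bonds.edges.items():
        if i not in heavy or j not in heavy:
            continue
        if bond_type != "single":
            continue
        if frozenset((i, j)) not in bridges:  # in a ring
            continue
        if i in bonds.sp2 and j in bonds.sp2:
            continue
        deg_i = sum(1 for k in bonds.neighbors(i) if k in heavy)
        deg_j = sum(1 for k in bonds.neighbors(j) if k in heavy)
        if deg_i >= 2 and deg_j >= 2:
            count += 1
    return count


def _solvation_class(atom) -> str:
    key = (atom.residue_code, atom.name)
    if key in _chem.CHARGED_O_ATOMS or atom.name == "OXT":
        return "O_charged"
    if key in _chem.CHARGED_N_ATOMS:
        return "N_charged"
    return atom.element


def tension_features(structure: ProteinStructure, asa: AsaResult,
                     config: FeatureConfig = DEFAULT_CONFIG
                     ) -> tuple[float, float]:
    """Surface-tension sums from atomic solvation parameters.

    ``total_surface_tension`` is the ASA-weighted sum of per-atom-class
    solvation parameters over the whole surface (kcal/mol scale);
    ``internal_tension`` sums the absolute hydropathy of buried residues
    (relative ASA below the burial threshold).
    """
    sigma = config.solvation_params
    total = 0.0
    for i, atom in enumerate(structure.atoms):
        a = asa.per_atom_asa[i]
        if a > 0:
            total += sigma.get(_solvation_class(atom), 0.0) * a
    buried = asa.per_residue_relative_asa < config.contacts.burial_rasa
    internal = sum(abs(config.hydropathy.get(code, 0.0))
                   for (code, _), b in zip(structure.residues, buried) if b)
    return float(total), float(internal)


def interaction_vector(structure: ProteinStructure,
                       config: FeatureConfig = DEFAULT_CONFIG,
                       ) -> InteractionVector:
    """Compute all 11 structural features for one chain."""
    assign_vdw_radii(structure, config)
    ensure_bonds(structure, config)
    pairs = neighbor_pairs(structure, pair_cutoff(config), config)
    asa = compute_asa(structure, config=config)
    n_hyd, _n_int, w_total, w_internal = hydrophobic_contacts(
        structure, pairs, asa, config)
    surface_tension, internal_tension = tension_features(
        structure, asa, config)
    hbonds = detect_hbonds(structure, config)
    return InteractionVector(
        total_hydrophobic_contacts=float(n_hyd),
        total_vdw_interactions=float(vdw_contacts(structure, pairs, config)),
        deformation_effect=float(deformation_effect(structure, config)),
        intramolecular_hbond_score=float(sum(h.score for h in hbonds)),
        repulsive_interactions=float(
            repulsive_contacts(structure, pairs, config)),
        london_dispersion_forces=float(
            london_contacts(structure, pairs, config)),
        total_hydrophobicity=float(w_total),
        internal_hydrophobicity=float(w_internal),
        total_surface_tension=surface_tension,
        internal_tension=internal_tension,
        total_asa=asa.total_asa,
    )
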