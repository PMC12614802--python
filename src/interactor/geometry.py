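"""Geometric primitives: neighbor pairs, geometric centers, hydrogen-bond
geometry and accessible surface area.

All routines operate on heavy atoms only; explicit hydrogens, when present
in the input, are ignored so that results do not depend on whether a
crystal structure was deposited with protons.  Angles for hydrogen-bond
geometry are built from heavy atoms and geometric centers: the center of
an atom and its covalent neighbors stands in for the (frequently absent)
hydrogen positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._chem import DEFAULT_VDW_RADIUS
from .config import DEFAULT_CONFIG, FeatureConfig
from .structure_io import BondGraph, ProteinStructure, infer_bonds

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborPair", "HBondRecord", "AsaResult",
    "assign_vdw_radii", "neighbor_pairs", "geometric_center",
    "hbond_angle", "detect_hbonds", "compute_asa", "golden_spiral_points",
    "ensure_bonds",
]


@dataclass(frozen=True)
class NeighborPair:
    """Unordered heavy-atom pair within a distance cutoff.

    ``bonded_path`` is the covalent-graph distance truncated at the
    configured non-bonded threshold: 1 = bonded, 2 = angle (1-3)
    neighbors, and the cap value means "at least that many bonds apart,
    or disconnected".  Contact features only consider pairs at or beyond
    the threshold, so that distances dictated by covalent geometry
    (bond lengths, angles, and the torsion-range 1-4/1-5 separations)
    never register as non-covalent interactions.
    """

    atom_i: int
    atom_j: int
    d: float
    bonded_path: int


@dataclass(frozen=True)
class HBondRecord:
    donor_atom: int
    acceptor_atom: int
    d_DA: float
    alpha: float
    score: float


@dataclass
class AsaResult:
    per_atom_asa: np.ndarray          # A^2, full atom indexing (H rows = 0)
    total_asa: float                  # A^2
    per_residue_asa: np.ndarray       # A^2 per residue
    per_residue_relative_asa: np.ndarray  # fraction of Gly-X-Gly maximum


def ensure_bonds(structure: ProteinStructure,
                 config: FeatureConfig = DEFAULT_CONFIG) -> BondGraph:
    """Return the structure's bond graph, inferring one if absent."""
    if structure.bonds is None:
        structure.bonds = infer_bonds(structure, config)
    return structure.bonds


def assign_vdw_radii(structure: ProteinStructure,
                     config: FeatureConfig = DEFAULT_CONFIG
                     ) -> ProteinStructure:
    """Assign per-element van der Waals radii in place (and return)."""
    for atom in structure.atoms:
        radius = config.vdw_radii.get(atom.element)
        if radius is None:
            logger.warning("no vdW radius for element %r; using default %.2f",
                           atom.element, config.default_vdw_radius)
            radius = config.default_vdw_radius
        atom.vdw_radius = radius
    return structure


def _bonded_path_class(bonds: BondGraph, i: int, j: int) -> int:
    if bonds.has_bond(i, j):
        return 1
    if bonds.neighbors(i) & bonds.neighbors(j):
        return 2
    return 3


def covalent_distances(bonds: BondGraph, atom_ids, cap: int
                       ) -> dict[int, dict[int, int]]:
    """Per-atom covalent graph distances up to ``cap - 1`` bonds (BFS)."""
    out: dict[int, dict[int, int]] = {}
    for start in atom_ids:
        dist = {start: 0}
        frontier = [start]
        for depth in range(1, cap):
            nxt = []
            for node in frontier:
                for nb in bonds.neighbors(node):
                    if nb not in dist:
                        dist[nb] = depth
                        nxt.append(nb)
            frontier = nxt
        out[start] = dist
    return out


def neighbor_pairs(structure: ProteinStructure, cutoff: float,
                   config: FeatureConfig = DEFAULT_CONFIG
                   ) -> list[NeighborPair]:
    """All unordered heavy-atom pairs with distance <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    bonds = ensure_bonds(structure, config)
    heavy = structure.heavy_atom_ids()
    if len(heavy) < 2:
        return []
    cap = config.contacts.min_bonded_path
    local = covalent_distances(bonds, heavy, cap)
    coords = structure.coords()[heavy]
    tree = cKDTree(coords)
    pairs = []
    for a, b in sorted(tree.query_pairs(cutoff)):
        i, j = heavy[a], heavy[b]
        if i > j:
            i, j = j, i
        d = float(np.linalg.norm(coords[a] - coords[b]))
        pairs.append(NeighborPair(i, j, d, local[i].get(j, cap)))
    return pairs


def geometric_center(structure: ProteinStructure, atom_id: int,
                     config: FeatureConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Mean position of an atom and all of its covalent neighbors."""
    bonds = ensure_bonds(structure, config)
    nbrs = bonds.neighbors(atom_id)
    if not nbrs:
        raise ValueError(f"atom {atom_id} has no covalent neighbors; "
                         "geometric center undefined")
    ids = [atom_id, *sorted(nbrs)]
    return structure.coords()[ids].mean(axis=0)


def hbond_angle(structure: ProteinStructure, donor: int, acceptor: int,
                config: FeatureConfig = DEFAULT_CONFIG) -> float:
    """Donor-centered hydrogen-bond angle proxy, degrees.

    The angle at the donor between the direction to its geometric center
    (a stand-in for the mean substituent/hydrogen direction) and the
    direction to the acceptor.  180 deg means the acceptor sits exactly
    anti to the donor's substituents -- ideal linear geometry; values
    shrink as the acceptor approaches the substituent side.
    """
    d = structure.coords()[donor]
    a = structure.coords()[acceptor]
    v1 = geometric_center(structure, donor, config) - d
    v2 = a - d
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("degenerate geometry: zero-length vector at donor")
    cos = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(cos))


def detect_hbonds(structure: ProteinStructure,
                  config: FeatureConfig = DEFAULT_CONFIG
                  ) -> list[HBondRecord]:
    """Intramolecular hydrogen bonds with geometric quality scores.

    Donor (N/O/S with donor capability per residue template) and acceptor
    (N/O) heavy atoms within ``hbond.d_max``, separated by at least three
    covalent bonds, with donor angle >= ``hbond.alpha_min``.  The score is
    the product of a linear distance ramp (1 at ``d_ideal``, 0 at
    ``d_max``) and a linear angle ramp (0 at ``alpha_min``, 1 at 180 deg).
    """
    hb = config.hbond
    bonds = ensure_bonds(structure, config)
    donors = [i for i, at in enumerate(structure.atoms)
              if at.polarity_class in ("donor", "donor_acceptor")
              and at.element in ("N", "O", "S", "SE")]
    acceptors = [i for i, at in enumerate(structure.atoms)
                 if at.polarity_class in ("acceptor", "donor_acceptor")
                 and at.element in ("N", "O")]
    if not donors or not acceptors:
        return []
    coords = structure.coords()
    acc_tree = cKDTree(coords[acceptors])
    records = []
    for don in donors:
        if not bonds.neighbors(don):
            continue
        for k in acc_tree.query_ball_point(coords[don], hb.d_max):
            acc = acceptors[k]
            if acc == don or _bonded_path_class(bonds, don, acc) < 3:
                continue
            d_da = float(np.linalg.norm(coords[don] - coords[acc]))
            if d_da > hb.d_max:
                continue
            alpha = hbond_angle(structure, don, acc, config)
            if alpha < hb.alpha_min:
                continue
            w_d = min(max((hb.d_max - d_da) / (hb.d_max - hb.d_ideal), 0.0),
                      1.0)
            w_a = min(max((alpha - hb.alpha_min)
                          / (hb.alpha_ideal - hb.alpha_min), 0.0), 1.0)
            records.append(HBondRecord(don, acc, d_da, alpha, w_d * w_a))
    records.sort(key=lambda r: (r.donor_atom, r.acceptor_atom))
    return records


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (Fibonacci)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack((rho * np.cos(theta), rho * np.sin(theta), z))


def _intrinsic_frame(coords: np.ndarray) -> np.ndarray:
    """A molecule-fixed orthonormal frame (principal axes, skew-oriented).

    Sampling directions expressed in this frame co-rotate with the
    molecule, which makes the sampled ASA exactly invariant under rigid
    rotation and translation while staying bit-reproducible.  Axis signs
    follow the third moment of the coordinates along each axis (proteins
    are chiral, so these are generically nonzero).
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    for k in range(3):
        skew = float(np.sum((centered @ vecs[:, k]) ** 3))
        if skew < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 0] = -vecs[:, 0]
    return vecs


def compute_asa(structure: ProteinStructure, probe: float | None = None,
                n_points: int | None = None,
                config: FeatureConfig = DEFAULT_CONFIG) -> AsaResult:
    """Shrake-Rupley accessible surface area with a deterministic point set.

    Each heavy atom's sphere of radius ``r_vdw + probe`` is sampled with a
    golden-spiral point set; a point is accessible when it lies outside
    every neighboring atom's expanded sphere.  Per-residue relative ASA
    divides by the residue's tabulated Gly-X-Gly maximum.
    """
    probe = config.asa.probe if probe is None else probe
    n_points = config.asa.n_points if n_points is None else n_points
    if n_points < config.asa.min_points:
        raise ValueError(
            f"n_points={n_points} below accuracy floor "
            f"{config.asa.min_points}")
    heavy = structure.heavy_atom_ids()
    per_atom = np.zeros(len(structure.atoms))
    if heavy:
        coords = structure.coords()[heavy]
        radii = np.array([structure.atoms[i].vdw_radius or DEFAULT_VDW_RADIUS
                          for i in heavy])
        sphere = golden_spiral_points(n_points) @ _intrinsic_frame(coords).T
        tree = cKDTree(coords)
        reach = 2 * radii.max() + 2 * probe
        for a, i in enumerate(heavy):
            r = radii[a] + probe
            pts = coords[a] + r * sphere
            accessible = np.ones(n_points, dtype=bool)
            for b in tree.query_ball_point(coords[a], reach):
                if b == a:
                    continue
                rb = radii[b] + probe
                if np.linalg.norm(coords[a] - coords[b]) >= r + rb:
                    continue
                d2 = np.sum((pts - coords[b]) ** 2, axis=1)
                if b < a:
                    # boundary points are claimed by the lower-index atom,
                    # so exactly coincident spheres count their surface once
                    accessible &= d2 > rb * rb + 1e-9
                else:
                    accessible &= d2 >= rb * rb - 1e-9
                if not accessible.any():
                    break
            per_atom[i] = accessible.mean() * 4.0 * math.pi * r * r

    n_res = len(structure.residues)
    per_res = np.zeros(n_res)
    rel = np.zeros(n_res)
    for ri, (code, atom_ids) in enumerate(structure.residues):
        per_res[ri] = per_atom[atom_ids].sum()
        max_asa = config.max_asa.get(code)
        rel[ri] = per_res[ri] / max_asa if max_asa else 0.0
    return AsaResult(per_atom_asa=per_atom, total_asa=float(per_atom.sum()),
                     per_residue_asa=per_res, per_residue_relative_asa=rel)
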