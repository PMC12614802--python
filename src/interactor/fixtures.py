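"""Synthetic structures and sequences with analytically known ground truth.

Fixtures exist so that every feature operation can be validated without
downloading real structures: an ideal poly-alanine alpha-helix carries a
known i -> i+4 backbone hydrogen-bond pattern, a packed toy core has
buried residues known by construction, and seeded atom clouds feed the
brute-force contact oracles.  All fixtures are serialized as real PDB
text and re-read through the public parser, so tests exercise the full
input path rather than internal constructors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import (AtomRecord, ProteinStructure, parse_pdb,
                           structure_to_pdb)

__all__ = [
    "FixtureSpec", "make_ideal_helix", "make_toy_core", "make_atom_cloud",
    "make_random_sequence", "generate",
]

# Ideal alpha-helix backbone torsions (degrees) and standard peptide
# internal coordinates (Engh-Huber-style bond lengths/angles).
PHI, PSI, OMEGA = -57.0, -47.0, 180.0
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

# Intra-residue heavy-atom bonds of the poly-alanine template, plus one
# peptide bond per junction: 4 per residue + (n-1).
ALA_TEMPLATE_BONDS = 4


@dataclass
class FixtureSpec:
    """A reproducible fixture request with its ground-truth annotations."""

    kind: str
    parameters: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d given three reference atoms and internal coordinates."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(angle),
                  bond * math.sin(angle) * math.cos(dihedral),
                  bond * math.sin(angle) * math.sin(dihedral)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _helix_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    res: list[dict[str, np.ndarray]] = []
    # seed residue: N at origin, CA along x, C in the xy-plane
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = res[-1]
        n_i = _nerf(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, PSI)
        ca_i = _nerf(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, OMEGA)
        c_i = _nerf(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, PHI)
        res.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl O anti to the following N (dihedral psi + 180); CB tetrahedral
    for i, r in enumerate(res):
        psi = PSI  # last residue keeps the helical psi for O placement
        r["O"] = _nerf(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        r["CB"] = _nerf(r["C"], r["N"], r["CA"], _B_CA_CB, 110.5, 122.5)
    return res


def _structure_from_atoms(atom_specs, chain_id="A", source="fixture"):
    """Round-trip helper: build -> PDB text -> public parser."""
    atoms = []
    residues: dict[int, tuple[str, list[int]]] = {}
    for serial, (name, element, coords, res_idx, code) in \
            enumerate(atom_specs, start=1):
        atoms.append(AtomRecord(
            serial=serial, name=name, element=element,
            coords=np.asarray(coords, dtype=float),
            residue_index=res_idx, residue_code=code, chain_id=chain_id,
            is_sidechain=name not in ("N", "CA", "C", "O", "OXT")))
        residues.setdefault(res_idx, (code, []))[1].append(len(atoms) - 1)
    res_list = [residues[i] for i in sorted(residues)]
    raw = ProteinStructure(chain_id=chain_id, residues=res_list, atoms=atoms,
                           source=source)
    text = structure_to_pdb(raw)
    parsed = parse_pdb(text)[0]
    parsed.source = source
    return parsed


def make_ideal_helix(n_res: int) -> tuple[ProteinStructure, dict]:
    """Ideal poly-alanine alpha-helix with known i -> i+4 hydrogen bonds.

    Returns the structure (via PDB round-trip) and ground truth: the
    expected backbone donor/acceptor residue pairs (N of residue i+4 to
    O of residue i), their count ``n_res - 4``, and the template covalent
    bond count ``4 * n_res + (n_res - 1)``.
    """
    if n_res < 5:
        raise ValueError("an alpha-helix fixture needs at least 5 residues")
    backbone = _helix_backbone(n_res)
    specs = []
    for i, r in enumerate(backbone):
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"),
                              ("O", "O"), ("CB", "C")):
            specs.append((name, element, r[name], i, "A"))
    structure = _structure_from_atoms(specs, source=f"helix{n_res}")
    ground_truth = {
        "expected_hbond_residue_pairs": [(i + 4, i) for i in
                                         range(n_res - 4)],
        "n_expected_hbonds": n_res - 4,
        "n_template_bonds": ALA_TEMPLATE_BONDS * n_res + (n_res - 1),
    }
    return structure, ground_truth


def make_toy_core(n_side: int = 4, spacing: float = 3.5
                  ) -> tuple[ProteinStructure, dict]:
    """A packed cubic block of apolar single-carbon residues.

    ``n_side**3`` alanine-style side-chain carbons sit on a cubic lattice
    whose spacing leaves no gap wide enough for a water probe, so the
    interior cells are buried by construction while the block's corner
    cells face open solvent.  Interior cells are mutually within
    hydrophobic contact range, providing buried apolar pairs with known
    burial for the internal-hydrophobicity features.

    Ground truth (all by lattice construction, independent of any ASA
    code): ``buried_residues`` = interior cells, ``exposed_residues`` =
    corner cells, ``core_pair`` = two adjacent interior cells.
    """
    import itertools

    if n_side < 3:
        raise ValueError("the lattice needs n_side >= 3 to have an interior")
    specs = []
    interior: set[int] = set()
    corners: set[int] = set()
    cells = list(itertools.product(range(n_side), repeat=3))
    for idx, cell in enumerate(cells):
        if all(1 <= c <= n_side - 2 for c in cell):
            interior.add(idx)
        if all(c in (0, n_side - 1) for c in cell):
            corners.add(idx)
        specs.append(("CB", "C", np.asarray(cell, dtype=float) * spacing,
                      idx, "A"))
    structure = _structure_from_atoms(specs, source="toycore")
    pair = sorted(interior)[:2]
    ground_truth = {
        "buried_residues": interior,
        "exposed_residues": corners,
        "core_pair": tuple(pair),
        "n_residues": n_side ** 3,
    }
    return structure, ground_truth


_CLOUD_ATOM_NAMES = {"C": "CB", "N": "ND", "O": "OD", "S": "SD"}


def make_atom_cloud(n: int, box: float = 20.0, seed: int = 0,
                    elements: str = "CNOS") -> ProteinStructure:
    """Seeded uniform atom cloud; each atom is its own single-atom residue.

    Used by the brute-force contact-count oracles.  Element labels are
    drawn uniformly from ``elements``; atoms are parsed as alanine
    side-chain-style atoms so they participate in contact counting.
    """
    if n < 2:
        raise ValueError("an atom cloud needs at least 2 atoms")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n, 3))
    labels = rng.choice(list(elements), size=n)
    specs = [(_CLOUD_ATOM_NAMES.get(el, "CB"), el, coords[i], i, "A")
             for i, el in enumerate(labels)]
    return _structure_from_atoms(specs, source=f"cloud{n}s{seed}")


def make_random_sequence(length: int, alphabet: str = None,
                         seed: int = 0) -> str:
    """Seeded i.i.d. uniform residue sequence over ``alphabet``."""
    from ._chem import ALPHABET

    if length < 1:
        raise ValueError("length must be >= 1")
    alphabet = alphabet or ALPHABET
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(alphabet), size=length))


def generate(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to its maker function."""
    makers = {
        "ideal_helix": make_ideal_helix,
        "toy_core": make_toy_core,
        "atom_cloud": make_atom_cloud,
        "random_sequence": make_random_sequence,
    }
    try:
        maker = makers[spec.kind]
    except KeyError:
        raise ValueError(f"unknown fixture kind {spec.kind!r}") from None
    return maker(**spec.parameters)
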