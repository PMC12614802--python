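"""Structure input: PDB and TRIPOS MOL2 parsing, bond inference, PDB export.

The analysis unit throughout the package is a single chain.  Multi-chain
PDB files are split into one :class:`ProteinStructure` per chain; waters
and non-peptide heteroatoms are dropped; alternate locations are resolved
to the highest-occupancy conformer (ties broken by altloc label).
Covalent bonds come either from a paired MOL2 file, which carries bond
orders and sp2 hybridization, or from distance-based inference with
residue-template sp2 flags when no MOL2 is available.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from scipy.spatial import cKDTree

from . import _chem
from .config import DEFAULT_CONFIG, FeatureConfig

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord", "BondGraph", "ProteinStructure",
    "StructureParseError", "ElementResolutionError", "AtomCountMismatchError",
    "parse_pdb", "parse_mol2", "infer_bonds", "structure_to_pdb",
]


class StructureParseError(ValueError):
    """Input text is not parseable as the expected structure format."""


class ElementResolutionError(StructureParseError):
    """An atom's chemical element could not be resolved."""


class AtomCountMismatchError(StructureParseError):
    """A MOL2 file does not match its paired PDB atom count."""


@dataclass
class AtomRecord:
    """One atom of a protein chain.

    ``residue_index`` is the 0-based ordinal of the residue within the
    chain; coordinates are in Angstrom.  ``vdw_radius`` and
    ``polarity_class`` are assigned by later pipeline stages.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue_index: int
    residue_code: str
    chain_id: str
    is_sidechain: bool
    vdw_radius: float | None = None
    polarity_class: str | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureParseError(
                f"non-finite coordinates for atom serial {self.serial}")


BOND_TYPES = frozenset({"single", "double", "triple", "amide", "aromatic"})


class BondGraph:
    """Covalent-bond graph over atom indices with bond types and sp2 flags."""

    def __init__(self):
        self._adj: dict[int, set[int]] = {}
        self._types: dict[tuple[int, int], str] = {}
        self.sp2: set[int] = set()

    @staticmethod
    def _key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def add_bond(self, i: int, j: int, bond_type: str = "single") -> None:
        if i == j:
            raise ValueError("self-bond rejected")
        if bond_type not in BOND_TYPES:
            raise ValueError(f"unknown bond type {bond_type!r}")
        self._adj.setdefault(i, set()).add(j)
        self._adj.setdefault(j, set()).add(i)
        self._types[self._key(i, j)] = bond_type
        if bond_type in ("double", "aromatic"):
            self.sp2.update((i, j))

    def has_bond(self, i: int, j: int) -> bool:
        return self._key(i, j) in self._types

    def bond_type(self, i: int, j: int) -> str:
        return self._types[self._key(i, j)]

    def neighbors(self, i: int) -> frozenset:
        return frozenset(self._adj.get(i, ()))

    @property
    def edges(self) -> dict[tuple[int, int], str]:
        return dict(self._types)

    def __len__(self) -> int:
        return len(self._types)

    def validate(self, n_atoms: int) -> None:
        for i, j in self._types:
            if not (0 <= i < n_atoms and 0 <= j < n_atoms):
                raise ValueError(f"bond ({i},{j}) references missing atom")
        for i, j in self._types:
            if self._types[self._key(i, j)] in ("double", "aromatic"):
                assert i in self.sp2 and j in self.sp2

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._adj)
        for (i, j), t in self._types.items():
            g.add_edge(i, j, bond_type=t)
        return g


@dataclass
class ProteinStructure:
    """A single protein chain: residues, atoms, bonds and sequence."""

    chain_id: str
    residues: list[tuple[str, list[int]]]
    atoms: list[AtomRecord]
    bonds: BondGraph | None = None
    source: str = ""
    _coords: np.ndarray | None = field(default=None, repr=False)

    @property
    def sequence(self) -> str:
        return "".join(code for code, _ in self.residues)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (cached)."""
        if self._coords is None or len(self._coords) != len(self.atoms):
            self._coords = np.array([a.coords for a in self.atoms])
        return self._coords

    def heavy_atom_ids(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    @property
    def id(self) -> str:
        base = Path(self.source).stem if self.source else "structure"
        return f"{base}_{self.chain_id}"


def _assign_polarity(atoms: list[AtomRecord]) -> None:
    """Donor/acceptor/polar/apolar classes from heavy-atom residue templates."""
    for a in atoms:
        if a.element == "H":
            a.polarity_class = "apolar"
            continue
        code, name = a.residue_code, a.name
        donor = False
        acceptor = False
        if name == "N" and code != "P":
            donor = True
        if name in ("O", "OXT"):
            acceptor = True
        if name in _chem.SIDECHAIN_DONORS.get(code, ()):
            donor = True
        if name in _chem.SIDECHAIN_ACCEPTORS.get(code, ()):
            acceptor = True
        if donor and acceptor:
            a.polarity_class = "donor_acceptor"
        elif donor:
            a.polarity_class = "donor"
        elif acceptor:
            a.polarity_class = "acceptor"
        elif a.element in ("N", "O"):
            a.polarity_class = "polar"
        else:
            a.polarity_class = "apolar"


def _resolve_altloc(residue):
    """Pick one atom per name: highest occupancy, ties to altloc 'A'."""
    by_name: dict[str, list] = {}
    for atom in residue.get_unpacked_list():
        by_name.setdefault(atom.get_name(), []).append(atom)
    chosen = []
    for name, copies in by_name.items():
        copies.sort(key=lambda at: (-(at.get_occupancy() or 0.0),
                                    at.get_altloc() or "A"))
        chosen.append(copies[0])
    return chosen


def parse_pdb(path_or_text: str | Path,
              config: FeatureConfig = DEFAULT_CONFIG) -> list[ProteinStructure]:
    """Parse PDB text or a file path into one structure per chain.

    Waters and non-peptide HETATM records are excluded; modified residues
    with a known 3-to-1 mapping (MSE, SEC, PYL, MVA) are retained.  Chains
    without any recognizable residue are skipped with a warning.
    """
    text, source = _read_input(path_or_text)
    lines = text.splitlines()
    if not any(ln.startswith(("ATOM  ", "ATOM\t", "HETATM")) for ln in lines):
        bad = next((ln for ln in lines if ln.strip()), "<empty file>")
        raise StructureParseError(
            f"no ATOM records found; first line: {bad[:60]!r}")

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        model = parser.get_structure("s", io.StringIO(text))[0]

    structures = []
    for chain in model:
        residues = []
        for res in chain:
            het, resseq, icode = res.get_id()
            resname = res.get_resname().strip()
            if resname == "HOH" or resname not in _chem.THREE_TO_ONE:
                continue
            residues.append(((resseq, icode), resname, res))
        if not residues:
            logger.warning("chain %s has no standard residues; skipped",
                           chain.get_id())
            continue
        residues.sort(key=lambda item: item[0])

        atoms: list[AtomRecord] = []
        res_list: list[tuple[str, list[int]]] = []
        for res_idx, (_, resname, res) in enumerate(residues):
            code = _chem.THREE_TO_ONE[resname]
            atom_ids = []
            for atom in _resolve_altloc(res):
                element = (atom.element or "").strip().upper()
                if element in ("", "X"):
                    element = _chem.element_from_atom_name(
                        atom.get_fullname()) or ""
                if not element:
                    raise ElementResolutionError(
                        f"cannot resolve element for atom "
                        f"{atom.get_fullname()!r} in residue {resname}")
                atom_ids.append(len(atoms))
                atoms.append(AtomRecord(
                    serial=atom.get_serial_number() or len(atoms) + 1,
                    name=atom.get_name(),
                    element=element,
                    coords=atom.get_coord(),
                    residue_index=res_idx,
                    residue_code=code,
                    chain_id=chain.get_id(),
                    is_sidechain=atom.get_name() not in _chem.BACKBONE_ATOMS,
                ))
            res_list.append((code, atom_ids))
        _assign_polarity(atoms)
        structures.append(ProteinStructure(
            chain_id=chain.get_id(), residues=res_list, atoms=atoms,
            source=source))
    if not structures:
        raise StructureParseError("no chain with standard residues found")
    return structures


def _read_input(path_or_text: str | Path) -> tuple[str, str]:
    if isinstance(path_or_text, Path):
        return path_or_text.read_text(), str(path_or_text)
    if "\n" not in path_or_text and Path(path_or_text).exists():
        return Path(path_or_text).read_text(), path_or_text
    return path_or_text, ""


_MOL2_BOND_TYPES = {"1": "single", "2": "double", "3": "triple",
                    "am": "amide", "ar": "aromatic"}
# SYBYL atom types implying trigonal-planar (sp2) hybridization.
_SP2_SYBYL = {"C.2", "C.ar", "C.cat", "N.2", "N.ar", "N.am", "N.pl3", "O.2",
              "O.co2"}


def parse_mol2(path_or_text: str | Path,
               expected_n_atoms: int | None = None) -> BondGraph:
    """Parse a TRIPOS MOL2 file into a covalent :class:`BondGraph`.

    Atom ids in the returned graph are 0-based, in MOL2 atom-record order;
    when ``expected_n_atoms`` (from the paired PDB chain) differs from the
    MOL2 atom count an :class:`AtomCountMismatchError` is raised, since
    positional indexing against the PDB atoms would be unsafe.
    """
    text, _ = _read_input(path_or_text)
    section = None
    sybyl_types: dict[int, str] = {}
    graph = BondGraph()
    n_atoms = 0
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[len("@<TRIPOS>"):].upper()
            continue
        if not line or line.startswith("#"):
            continue
        if section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise StructureParseError(f"malformed MOL2 atom line: {line!r}")
            idx = int(parts[0]) - 1
            sybyl_types[idx] = parts[5]
            n_atoms += 1
        elif section == "BOND":
            parts = line.split()
            if len(parts) < 4:
                raise StructureParseError(f"malformed MOL2 bond line: {line!r}")
            i, j = int(parts[1]) - 1, int(parts[2]) - 1
            bond_type = _MOL2_BOND_TYPES.get(parts[3].lower(), "single")
            graph.add_bond(i, j, bond_type)
    if n_atoms == 0:
        raise StructureParseError("MOL2 input has no @<TRIPOS>ATOM section")
    if expected_n_atoms is not None and n_atoms != expected_n_atoms:
        raise AtomCountMismatchError(
            f"MOL2 has {n_atoms} atoms but paired structure has "
            f"{expected_n_atoms}")
    for idx, sybyl in sybyl_types.items():
        if sybyl in _SP2_SYBYL:
            graph.sp2.add(idx)
    graph.validate(n_atoms)
    return graph


def infer_bonds(structure: ProteinStructure,
                config: FeatureConfig = DEFAULT_CONFIG) -> BondGraph:
    """Distance-based covalent bond inference for MOL2-less inputs.

    A heavy-atom pair is bonded when its distance is at most the covalent
    radius sum plus a tolerance.  All inferred bonds are typed single; sp2
    flags come from residue templates (backbone carbonyl/amide plane and
    side-chain aromatic, amide, guanidinium and carboxylate groups).
    """
    graph = BondGraph()
    heavy = structure.heavy_atom_ids()
    if len(heavy) >= 2:
        coords = structure.coords()[heavy]
        radii = np.array([
            config.covalent_radii.get(structure.atoms[i].element,
                                      _chem.DEFAULT_COVALENT_RADIUS)
            for i in heavy])
        max_reach = 2 * radii.max() + config.covalent_tolerance
        tree = cKDTree(coords)
        for a, b in tree.query_pairs(max_reach):
            d = float(np.linalg.norm(coords[a] - coords[b]))
            if d <= radii[a] + radii[b] + config.covalent_tolerance:
                graph.add_bond(heavy[a], heavy[b], "single")
    for idx, atom in enumerate(structure.atoms):
        if atom.element == "H":
            continue
        if atom.name in ("C", "O", "N"):
            graph.sp2.add(idx)
        elif atom.name in _chem.SIDECHAIN_SP2.get(atom.residue_code, ()):
            graph.sp2.add(idx)
    return graph


def structure_to_pdb(structure: ProteinStructure) -> str:
    """Serialize a structure as minimal PDB ATOM records (chain, TER, END)."""
    lines = []
    one_to_three = {v: k for k, v in _chem.THREE_TO_ONE.items()
                    if k != "MSE"}
    for i, atom in enumerate(structure.atoms, start=1):
        resname = one_to_three.get(atom.residue_code, "UNK")
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        x, y, z = atom.coords
        lines.append(
            f"ATOM  {i:5d} {name}{'':1s}{resname:>3s} "
            f"{structure.chain_id:1s}{atom.residue_index + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {atom.element:>2s}")
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
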