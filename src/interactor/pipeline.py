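"""Extraction orchestration: directory -> labeled feature table -> TSV.

One row per chain; columns are the fixed-order feature blocks
(11 interaction features, 8 CPAASC class frequencies, then the dense
26 / 676 / 17,576 mono-/di-/tripeptide frequency blocks).  Failures on
individual files are logged and recorded in the run manifest rather than
aborting the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._chem import CPAASC_ORDER
from .config import DEFAULT_CONFIG, FeatureConfig
from .interactions import INTERACTION_FEATURE_NAMES, interaction_vector
from .sequence import all_kmers, cpaasc_frequencies, kmer_frequencies
from .structure_io import parse_mol2, parse_pdb

logger = logging.getLogger(__name__)

__all__ = ["FeatureTable", "feature_columns", "extract_features",
           "extract_all", "attach_labels"]

CPAASC_COLUMNS = tuple(f"cpaasc_{name}" for name in CPAASC_ORDER)


def feature_columns(config: FeatureConfig = DEFAULT_CONFIG) -> list[str]:
    """The fixed, documented column order of every exported table."""
    cols = list(INTERACTION_FEATURE_NAMES)
    cols.extend(CPAASC_COLUMNS)
    for k in (1, 2, 3):
        cols.extend(all_kmers(k, config.alphabet))
    return cols


@dataclass
class FeatureTable:
    """Proteins x features matrix with optional class labels.

    ``frame`` holds one row per chain over the full fixed column set;
    ``labels`` maps a subset (or all) of the row ids to class labels.
    """

    frame: pd.DataFrame
    labels: pd.Series | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    def labeled(self) -> tuple[pd.DataFrame, pd.Series]:
        """Rows that carry a label, aligned with their labels."""
        if self.labels is None:
            raise ValueError("table has no labels attached")
        mask = self.labels.notna()
        ids = self.labels.index[mask]
        return self.frame.loc[ids], self.labels.loc[ids]

    def to_tsv(self, path, sparse_kmers: bool = False) -> None:
        """Write the table as TSV (optionally dropping all-zero k-mer
        columns, useful for the 17,576-column tripeptide block)."""
        frame = self.frame
        if sparse_kmers:
            keep = [c for c in frame.columns
                    if c in INTERACTION_FEATURE_NAMES
                    or c in CPAASC_COLUMNS
                    or frame[c].to_numpy().any()]
            frame = frame[keep]
        out = frame.copy()
        if self.labels is not None:
            out.insert(0, "label", self.labels.reindex(out.index))
        out.to_csv(path, sep="\t", index_label="protein_id",
                   float_format="%.10g")


def extract_features(structure, config: FeatureConfig = DEFAULT_CONFIG
                     ) -> dict[str, float]:
    """All features for one chain as a flat name -> value mapping."""
    row = dict(interaction_vector(structure, config).as_dict())
    seq = structure.sequence
    cpaasc = cpaasc_frequencies(seq, config).freqs
    row.update({f"cpaasc_{name}": cpaasc[name] for name in CPAASC_ORDER})
    for k in (1, 2, 3):
        row.update(kmer_frequencies(seq, k, config).dense(config.alphabet))
    return row


def extract_all(input_dir, config: FeatureConfig = DEFAULT_CONFIG,
                mol2_dir=None, min_residues: int | None = None,
                normalize_by_length: bool = False) -> FeatureTable:
    """Extract features for every PDB file in a directory (one row/chain).

    When ``mol2_dir`` holds a same-stem ``.mol2`` file for a PDB input,
    its covalent bonds and sp2 flags are used; otherwise bonds are
    inferred from distances.  ``normalize_by_length`` divides the
    interaction block (raw counts/sums by default) by the chain's residue
    count.  Per-file failures are logged and recorded in the manifest;
    zero successful rows is a hard error.
    """
    input_dir = Path(input_dir)
    pdb_files = sorted(p for p in input_dir.iterdir()
                       if p.suffix.lower() in (".pdb", ".ent"))
    columns = feature_columns(config)
    rows: dict[str, list[float]] = {}
    statuses: dict[str, str] = {}
    for pdb_path in pdb_files:
        try:
            structures = parse_pdb(pdb_path, config)
            mol2_path = (Path(mol2_dir) / f"{pdb_path.stem}.mol2"
                         if mol2_dir else None)
            for structure in structures:
                if min_residues and len(structure.residues) < min_residues:
                    statuses[structure.id] = (
                        f"skipped: fewer than {min_residues} residues")
                    continue
                if mol2_path and mol2_path.exists() \
                        and len(structures) == 1:
                    structure.bonds = parse_mol2(
                        mol2_path.read_text(), structure.n_atoms)
                row = extract_features(structure, config)
                if normalize_by_length:
                    n_res = len(structure.residues)
                    for name in INTERACTION_FEATURE_NAMES:
                        row[name] /= n_res
                rows[structure.id] = [row[c] for c in columns]
                statuses[structure.id] = "ok"
        except Exception as exc:  # noqa: BLE001 - per-file fault isolation
            logger.warning("failed to extract %s: %s", pdb_path.name, exc)
            statuses[pdb_path.name] = f"error: {exc}"
    if not rows:
        raise RuntimeError(f"no chain in {input_dir} could be processed")
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=columns,
                                   dtype=float)
    frame = frame.sort_index()
    if frame.isna().any().any():
        raise AssertionError("NaN in exported feature table")
    manifest = {
        "toolkit_version": __version__,
        "config_hash": config.hash(),
        "n_files": len(pdb_files),
        "n_rows": len(frame),
        "status": statuses,
    }
    return FeatureTable(frame=frame, manifest=manifest)


def attach_labels(table: FeatureTable, mapping) -> FeatureTable:
    """Attach class labels from a two-column id/label TSV (or mapping).

    Rows without a label are retained with a null label; duplicate ids
    with conflicting labels are an error; zero id overlap is an error.
    """
    if isinstance(mapping, (str, Path)):
        raw = pd.read_csv(mapping, sep=r"\s+", header=None, comment="#",
                          names=["protein_id", "label"], dtype=str)
        pairs = list(raw.itertuples(index=False))
    else:
        pairs = list(dict(mapping).items())
    labels: dict[str, str] = {}
    for pid, label in pairs:
        if pid in labels and labels[pid] != label:
            raise ValueError(
                f"conflicting labels for id {pid!r}: "
                f"{labels[pid]!r} vs {label!r}")
        labels[pid] = label
    series = pd.Series(labels, dtype=object).reindex(table.frame.index)
    if series.notna().sum() == 0:
        raise ValueError("no overlap between table ids and mapping ids")
    n_missing = int(series.isna().sum())
    if n_missing:
        logger.warning("%d rows have no label", n_missing)
    manifest = dict(table.manifest)
    manifest["label_cardinality"] = int(series.dropna().nunique())
    manifest["n_unlabeled"] = n_missing
    return FeatureTable(frame=table.frame, labels=series, manifest=manifest)
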