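"""Extract the full multimodal feature table from a directory of PDB files.

Builds three ideal poly-alanine helices, writes them as PDB files, runs the
extractor, and prints the 11 interaction features for one chain.  In real use,
point ``extract_all`` at a directory of experimental or predicted structures
(optionally with paired MOL2 files carrying covalent bonds).
"""

import tempfile
from pathlib import Path

from interactor import extract_all, make_ideal_helix, structure_to_pdb
from interactor.interactions import INTERACTION_FEATURE_NAMES

with tempfile.TemporaryDirectory() as tmp:
    pdb_dir = Path(tmp)
    for name, n_res in (("helix08", 8), ("helix12", 12), ("helix16", 16)):
        structure, _ = make_ideal_helix(n_res)
        (pdb_dir / f"{name}.pdb").write_text(structure_to_pdb(structure))

    table = extract_all(pdb_dir)

print(f"feature table: {table.frame.shape[0]} chains x "
      f"{table.frame.shape[1]} features")
print("\ninteraction features for helix12_A:")
for name in INTERACTION_FEATURE_NAMES:
    print(f"  {name:<28s} {table.frame.loc['helix12_A', name]:10.3f}")

# Counts are raw pair counts; the hydrogen-bond entry is a sum of geometric
# quality scores in [0, 1] per bond; tensions are kcal/mol-scale sums; ASA
# is in A^2.  A 12-residue helix shows 8 backbone hydrogen bonds' worth of
# score, zero steric clashes, and ASA typical of a fully exposed peptide.
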