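# interactor

Feature engineering from protein three-dimensional structures for
interpretable machine learning.

Most protein feature encodings work from the primary sequence (amino-acid
composition, k-mers) or secondary structure; they cannot see the tertiary
contacts — hydrogen bonds, van der Waals packing, buried hydrophobic cores —
that actually hold a fold together and shape its function. `interactor`
extracts those contacts directly from atomic coordinates and combines them
with classic compositional descriptors, giving classification models a
feature space in which every dimension has a direct physical reading. It is
aimed at structural bioinformaticians profiling protein families, and at
anyone who wants explainable-AI attributions to land on biologically
meaningful features instead of embedding coordinates.

## What it computes

For each protein chain (one chain = one analysis unit) the extractor emits
**18,297 named features** in a fixed column order:

| block | count | description |
|---|---|---|
| interatomic interactions | 11 | contact counts, H-bond scores, hydrophobicity/tension sums, ASA |
| CPAASC | 8 | side-chain chemical-class frequencies (aliphatic, aromatic, polar, ±charge, S, OH, Gly/Pro) |
| monopeptides | 26 | residue frequencies over a 26-symbol alphabet (20 standard + U/O/J rare + B/Z/X) |
| dipeptides | 676 | overlapping 2-mer frequencies |
| tripeptides | 17,576 | overlapping 3-mer frequencies |

Non-bonded heavy-atom pairs are classified into three disjoint distance
bands keyed to the van der Waals radius sum *R* = *r*<sub>i</sub> + *r*<sub>j</sub>:

- **repulsive** (steric clash): *d* < *R*
- **van der Waals contact**: *R* ≤ *d* ≤ *R* + 0.7 Å
- **London dispersion**: *R* + 0.7 Å < *d* ≤ *R* + 3.0 Å

Hydrogen bonds are scored geometrically for every donor–acceptor pair with
*d*<sub>DA</sub> ≤ 3.5 Å and donor angle α ≥ 100°:

&nbsp;&nbsp;&nbsp;&nbsp;score = clamp((3.5 − *d*<sub>DA</sub>)/(3.5 − 2.6), 0, 1) · (α − 100°)/80°

so an ideal bond (2.6 Å, 180°) scores 1. Accessible surface area uses
Shrake–Rupley sampling with a deterministic point set; hydrophobic contacts
are apolar side-chain atom pairs within 4.5 Å, weighted by Kyte–Doolittle
hydropathy, with "internal" variants restricted to buried residues
(relative ASA < 0.20). Details and all tunable thresholds are in
[docs/methods.md](docs/methods.md).

Downstream, the `analysis` module provides mutual-information feature
ranking (k-NN estimator against the class label), an 80/20 train–test
benchmark in which feature selection sees only the training split, and a
grouped-attribution enrichment test: per-protein sums of SHAP-style
attribution values over two feature groups, compared per class with a
two-sided two-sample Kolmogorov–Smirnov test and Benjamini–Hochberg
correction across classes.

## Worked example

```bash
python examples/helix_hydrogen_bonds.py
```

```
expected backbone H-bonds: 6
detected (score > 0.2):    6

donor res -> acceptor res    d(A)   angle(deg)  score
  N   5   ->  O   1        3.09     169.8   0.396
  N   6   ->  O   2        3.09     169.8   0.395
  ...
  N  10   ->  O   6        3.09     169.8   0.395
```

A 10-residue ideal α-helix carries exactly 6 backbone hydrogen bonds —
carbonyl O(*i*) to amide N(*i*+4) — and the detector recovers that ladder:
every donor residue number exceeds its acceptor by 4, at the canonical
~3.1 Å N···O distance. The other examples
(`extract_features.py`, `feature_selection_benchmark.py`,
`attribution_enrichment.py`) walk through directory-scale extraction
(3 chains × 18,297 features), MI ranking (informative features at ~1.1 and
0.9 nats vs ≤ 0.02 for noise, perfect held-out F1 from the top 2), and the
KS enrichment test (D = 0.875, adjusted p < 10⁻¹⁵ for a class whose
interaction group carries extra attribution mass; D = 0.1, p = 0.99 for an
exchangeable one).

Shell use mirrors the library:

```bash
interactor extract --in pdb_dir/ --out features.tsv
interactor labels --table features.tsv --map family_labels.tsv
interactor select --table features.tsv --top-k 100
interactor benchmark --table features.tsv --model hgb --select-k 100
interactor enrich --shap shap.tsv --groups groups.tsv
```

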