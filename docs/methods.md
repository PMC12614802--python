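# Methods

This note documents the models, conventions and numerical choices behind
the feature extractor and the analysis toolkit — what each quantity means,
which thresholds govern it, and what the synthetic test fixtures do and do
not establish about behavior on real structures.

## Analysis unit and structure input

The unit of analysis is a single protein chain. PDB files are parsed with
Biopython and split into one structure per chain; waters and non-peptide
heteroatoms are discarded, while modified residues with a known mapping
(MSE → M, SEC → U, PYL → O, MVA → J) are retained as first-class sequence
symbols. Alternate locations are resolved to the highest-occupancy
conformer, ties broken by altloc label `A` — deterministic and
conventional. Residues are ordered by (residue number, insertion code);
the internal residue index is the resulting 0-based ordinal, reported
1-based in outputs.

N-methylvaline has no official one-letter code; this package assigns it
`J`, the alphabet's only spare letter (elsewhere used for the Ile/Leu
ambiguity code). With the 20 standard residues, U/O/J, and the B/Z/X
ambiguity codes the sequence alphabet has exactly 26 symbols, so the
dense k-mer blocks have 26 / 676 / 17,576 columns. (Some published
inventories list 675 dipeptides; 26² is 676, and the extractor emits the
complete block.)

Covalent bonds come from a paired TRIPOS MOL2 file when available (bond
orders 1/2/3/am/ar mapped to single/double/triple/amide/aromatic; sp²
flags from SYBYL atom types and from double/aromatic bond participation).
A MOL2 whose atom count disagrees with the PDB chain is rejected outright,
because bonds index atoms positionally. Without MOL2, bonds are inferred:
two heavy atoms are bonded when their distance is at most the sum of
single-bond covalent radii plus 0.45 Å; all inferred bonds are typed
single, and sp² flags come from residue templates (backbone carbonyl and
amide plane; side-chain aromatic rings, amides, guanidinium,
carboxylates).

Explicit hydrogens, when present, are parsed but ignored by every
geometric computation; all angle constructions use heavy atoms and
geometric centers, so protonated and unprotonated depositions of the same
structure give identical features (tested).

## Geometric features

**Van der Waals radii** are Bondi-style per-element values (C 1.70,
N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å); unknown elements fall back to
1.70 Å with a warning. All radii, and every threshold below, live in
`interactor.config.FeatureConfig` so alternative parameterizations are
drop-in.

**Non-bonded pair classification.** For a heavy-atom pair at distance *d*
with radius sum *R*, the three contact bands are contiguous and disjoint:
repulsive *d* < *R*; van der Waals *R* ≤ *d* ≤ *R* + 0.7 Å; London
dispersion *R* + 0.7 < *d* ≤ *R* + 3.0 Å. Only the +0.7 Å contact-band
width is fixed by the published description of the vdW feature; the inner
(clash) and outer (dispersion) edges follow the qualitative definitions
and are configurable.

A pair only counts as non-bonded when the two atoms are at least
`min_bonded_path` covalent bonds apart (default 5) or disconnected. The
1-2 and 1-3 separations are pure bond geometry, and the 1-4/1-5
separations are dictated by torsions: an ideal α-helix, built with
standard bond lengths and angles, places dozens of 1-4/1-5 backbone pairs
inside the vdW radius sum. Counting those as "electron-cloud overlap"
would make the clash feature report covalent geometry rather than steric
strain, so the default excludes them; with the threshold at 5 an ideal
helix reports exactly zero repulsive contacts, which is the behavior the
feature's definition intends. The threshold is configurable for users who
want the more permissive convention.

**Hydrogen bonds.** Donor and acceptor atoms are assigned from heavy-atom
residue templates (backbone N donates except proline; backbone O/OXT
accepts; side-chain donors/acceptors per residue), because crystal
structures commonly lack hydrogens. For each donor–acceptor pair with
*d*<sub>DA</sub> ≤ 3.5 Å and covalent separation ≥ 3 bonds, the donor
angle α is measured between the direction from the donor to its geometric
center (the mean position of the donor and its covalent neighbors — a
hydrogen-free proxy for the mean substituent direction) and the direction
to the acceptor; α = 180° means the acceptor sits exactly anti to the
donor's substituents, the ideal linear geometry. Pairs with α ≥ 100° are
scored

    score = clamp((3.5 − d)/(3.5 − 2.6), 0, 1) × clamp((α − 100)/80, 0, 1)

so the score ramps linearly from 0 at the distance/angle cutoffs to 1 at
2.6 Å / 180°, and is monotone in both arguments. The per-protein feature
is the sum of scores. The cutoffs (3.5 Å, 100°) and the linear ramp are
standard geometric criteria; measuring the angle at the donor (rather than
at a modeled hydrogen or at the acceptor) is one defensible convention
among several, chosen because it needs no hydrogen placement model.

**Accessible surface area** is Shrake–Rupley: each heavy atom's sphere of
radius *r*<sub>vdW</sub> + 1.4 Å is sampled at 256 points (configurable;
fewer than 32 is refused as an accuracy floor) and a point is accessible
when outside every neighbor's expanded sphere. The point set is a golden
spiral — deterministic, no seed — expressed in a molecule-intrinsic frame
(principal axes, signs oriented by coordinate skewness) so that the
sampled ASA is exactly invariant under rigid rotation and translation
while remaining bit-reproducible. Boundary points are claimed by the
lower-indexed atom, so degenerate coincident spheres count their shared
surface once. Per-residue relative ASA divides by the residue's maximum
exposure in an extended Gly-X-Gly reference (Tien et al. theoretical
values); a residue is *buried* when relative ASA < 0.20. Agreement with an
independent implementation (biotite) is within a fraction of a percent on
test fixtures, and within 0.2 % of a 10⁶-point Monte-Carlo oracle on the
two-sphere configuration.

**Hydrophobic contacts** are pairs of apolar side-chain heavy atoms —
sulfur/selenium, or carbon with no covalently bound N/O — from distinct
residues within 4.5 Å. The weighted variants add the mean Kyte–Doolittle
hydropathy of the two residues per contact ("total hydrophobicity");
internal variants keep only contacts whose both residues are buried.
Ambiguity codes take the hydropathy shared by (or averaged over) their
members; X is neutral.

**Deformation effect** is a rotatable-bond count: acyclic single bonds
between heavy atoms that each have at least two heavy neighbors, excluding
amide bonds and bonds whose both endpoints are sp² (which excludes the
peptide bond in distance-inferred graphs, where every edge is typed
single). Rotatable bonds are the standard *static* proxy for
conformational flexibility; this feature does not attempt dynamics or
normal-mode analysis, and users should read it as "torsional degrees of
freedom", not as an energy.

**Surface tension features.** Total surface tension is the ASA-weighted
sum of Eisenberg–McLachlan-style atomic solvation parameters (kcal/mol/Å²
per atom class: C +0.016, neutral N/O −0.006, charged O −0.024, charged
N −0.050, S +0.021). Internal tension sums |Kyte–Doolittle| over buried
residues. Both are declared proxies: the original feature definitions are
narrative, so the parameter tables sit in config precisely so alternative
definitions can be swapped in.

The published tool's exact formulas for the hydrogen-bond score, the
deformation effect and the two tension features are not reprinted in its
description; the implementations above are this package's own,
geometrically standard realizations of those narratives, and every
constant involved is exposed in `FeatureConfig`.

## Compositional features

k-mer frequencies (k = 1, 2, 3) use overlapping windows with denominator
L − k + 1, so each dense block sums to 1 for any chain of length ≥ k.
K-mers never span chain boundaries (each chain is an independent unit).
The 8 CPAASC classes are a mutually exclusive partition of the alphabet —
aliphatic-apolar {A V L I J}, aromatic {F W Y}, polar-uncharged
{N Q B Z X}, positive {K R H O}, negative {D E}, sulfur {C M U}, hydroxyl
{S T}, special {G P} — chosen so class frequencies also sum to 1.
Histidine is grouped with the positives and tyrosine with the aromatics;
both assignments are chemically defensible either way and the class map is
configurable. Symbols outside the map are counted under a configured
fallback class with a warning.

## Analysis toolkit

**Mutual information** against the discrete class label uses the k-NN
estimator (k = 3) with seeded jitter for distance tie-breaking
(scikit-learn's `mutual_info_classif`); estimates are clipped at 0 and
ranked with lexicographic tie-breaks so selection is deterministic given a
seed. On synthetic checks the estimator recovers ln 2 within a few tenths
of a percent for a label-identical feature on balanced binary labels and
stays below 0.01 nats for independent noise at n = 5000.

**The benchmark** shuffles and splits 80/20 (stratified when class counts
permit, with re-tries if a class misses the training split), optionally
selects the top-k MI features *using training rows only*, fits any
classifier honoring fit/predict (shipped defaults: histogram gradient
boosting and random forest), and reports accuracy, macro precision,
recall, F1 and Matthews correlation on the held-out rows. Macro averaging
is used for the multiclass metrics. The leakage guard is tested with a
planted probe: a feature that equals the label on held-out rows but is
noise on training rows is never selected.

**Grouped-attribution enrichment** takes a proteins × features attribution
matrix from any explainer (SHAP values in the intended use; the package
deliberately treats the explainer as an exchangeable component behind a
matrix-in/matrix-out interface), a binary feature grouping, and a class
partition. Per class, attributions are summed per protein within each
group; the two summed samples are compared with a two-sided two-sample
Kolmogorov–Smirnov test (`scipy.stats.ks_2samp`) and p-values are
Benjamini–Hochberg adjusted across classes (statsmodels step-up). The
result is invariant to row and column order.

## Synthetic fixtures: what they do and do not show

All tests run on generated inputs with construction-time ground truth:

- **Ideal α-helix** (poly-alanine, φ = −57°, ψ = −47°, ω = 180°, standard
  bond lengths/angles, built by internal-coordinate chaining): the
  i → i+4 backbone hydrogen-bond ladder (n − 4 bonds for n residues) and
  the per-residue template bond count (5n − 1) are known by construction.
- **Toy core**: an n³ cubic lattice of apolar single-carbon residues at
  3.5 Å spacing — below the probe-passage limit — so interior cells are
  buried and corner cells solvent-exposed by construction (face cells are
  genuinely intermediate and carry no claim).
- **Atom clouds**: seeded uniform placements feeding brute-force O(n²)
  contact oracles.
- **Random sequences**: seeded i.i.d. draws for window-count k-mer
  oracles.

Every fixture is serialized to PDB text and re-read through the public
parser, so tests exercise the full input path. What passing these tests
shows: the geometry, counting, scoring and bookkeeping are correct as
specified. What they do not show: fixtures have no side-chain rotamers, no
β-sheets, no missing atoms or occupancy pathologies, and no crystal
contacts, so feature *distributions* on real structures — and any
downstream classification accuracy on real protein families — are outside
what this suite certifies.

Problem sizes used by the test suite and acceptance script (20 clouds up
to 500 atoms, helices of 5–20 residues, 50 random sequences, n = 5000 for
MI limits, 400–500 rows for benchmark checks) were chosen as the smallest
sizes at which the statistical checks are stable.

## Known limitations

- Contact features are raw counts, which scale with chain length; an
  optional length-normalized export is available in the pipeline, off by
  default because raw values are what the fixed definitions specify.
- Donor/acceptor templates are heavy-atom-only; unusual protonation
  states (e.g. His tautomers) are not distinguished.
- Bond inference is distance-based and can, in pathological geometries,
  connect atoms that are merely close; supplying MOL2 bonds avoids this.
- The MI histogram shapes and feature rankings reported for large curated
  corpora depend on those corpora and are not reproduced here; the
  toolkit certifies the machinery, not any dataset-specific value.
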