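"""Compositional sequence descriptors: k-mer and side-chain-class frequencies.

Sequences use a 26-symbol alphabet (20 standard residues, U/O/J for the
rare residues selenocysteine, pyrrolysine and N-methylvaline, and the
B/Z/X ambiguity codes).  K-mer frequencies use overlapping windows with
denominator L - k + 1; each chain is an independent unit, so k-mers never
span chain boundaries.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

from . import _chem
from .config import DEFAULT_CONFIG, FeatureConfig

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionVector", "CPAASCVector",
    "kmer_frequencies", "cpaasc_frequencies", "all_kmers",
    "read_fasta",
]


@dataclass(frozen=True)
class CompositionVector:
    """Sparse k-mer frequency map; absent k-mers are implicitly zero."""

    k: int
    freqs: dict[str, float]

    def dense(self, alphabet: str = _chem.ALPHABET) -> dict[str, float]:
        """All |alphabet|^k frequencies in lexicographic order."""
        return {kmer: self.freqs.get(kmer, 0.0)
                for kmer in all_kmers(self.k, alphabet)}


@dataclass(frozen=True)
class CPAASCVector:
    """Frequencies of the 8 side-chain chemical-property classes."""

    freqs: dict[str, float]


@lru_cache(maxsize=8)
def all_kmers(k: int, alphabet: str = _chem.ALPHABET) -> tuple[str, ...]:
    return tuple("".join(p) for p in itertools.product(alphabet, repeat=k))


def kmer_frequencies(sequence: str, k: int,
                     config: FeatureConfig = DEFAULT_CONFIG
                     ) -> CompositionVector:
    """Overlapping k-mer frequencies, count / (L - k + 1)."""
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    alphabet = set(config.alphabet)
    bad = set(sequence) - alphabet
    if bad:
        raise ValueError(f"sequence contains unsupported symbols {sorted(bad)}")
    n_windows = len(sequence) - k + 1
    if n_windows < 1:
        logger.warning("sequence of length %d has no windows for k=%d",
                       len(sequence), k)
        return CompositionVector(k=k, freqs={})
    counts: dict[str, int] = {}
    for i in range(n_windows):
        kmer = sequence[i:i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return CompositionVector(
        k=k, freqs={kmer: c / n_windows for kmer, c in counts.items()})


@lru_cache(maxsize=4)
def _class_of_symbol(fallback: str) -> dict[str, str]:
    mapping = {}
    for cls in _chem.CPAASC_ORDER:
        for sym in _chem.CPAASC_CLASSES[cls]:
            mapping[sym] = cls
    return mapping


def cpaasc_frequencies(sequence: str,
                       config: FeatureConfig = DEFAULT_CONFIG) -> CPAASCVector:
    """Frequencies of the 8 mutually exclusive side-chain classes.

    Every residue is assigned to exactly one class, so for a nonempty
    sequence the frequencies sum to 1.  Symbols outside the class map are
    counted under the configured fallback class with a warning.
    """
    if not sequence:
        raise ValueError("empty sequence")
    class_map = {sym: cls for cls, members in config.cpaasc_classes.items()
                 for sym in members}
    counts = {cls: 0 for cls in _chem.CPAASC_ORDER}
    for sym in sequence:
        cls = class_map.get(sym)
        if cls is None:
            logger.warning("symbol %r not in CPAASC class map; counted as %s",
                           sym, config.cpaasc_fallback)
            cls = config.cpaasc_fallback
        counts[cls] += 1
    length = len(sequence)
    return CPAASCVector(freqs={cls: c / length for cls, c in counts.items()})


def read_fasta(path_or_text) -> dict[str, str]:
    """Read FASTA into an id -> sequence map (sequence-only mode)."""
    import io
    from pathlib import Path

    from Bio import SeqIO

    if isinstance(path_or_text, Path) or (
            "\n" not in str(path_or_text) and Path(path_or_text).exists()):
        handle = open(path_or_text)
    else:
        handle = io.StringIO(str(path_or_text))
    with handle:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(handle, "fasta")}
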