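"""Universal genetic code tables over the 61 sense codons.

Classical codon substitution models (GY94/MG94 style) are defined on
the 61 sense codons of the universal code: substitutions to or from stop
codons are excluded, and only codon pairs differing at a single nucleotide
position exchange probability flux directly.  This module precomputes, once,
the combinatorial structure those models need:

* the ordered sense-codon alphabet and its index,
* per-codon amino-acid translations,
* boolean 61 x 61 matrices marking single-nucleotide neighbours, whether the
  single change is a transition (A<->G, C<->T), and whether it is synonymous.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # the universal code

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

#: The 61 sense codons, lexicographically ordered over A<C<G<T.
SENSE_CODONS: tuple[str, ...] = tuple(
    c
    for c in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)

N_CODONS = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: Amino acid encoded by each sense codon, aligned with ``SENSE_CODONS``.
CODON_AA: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    pair = {a, b}
    return pair <= _PURINES or pair <= _PYRIMIDINES


def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    synonymous = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = is_transition(*diffs[0])
            synonymous[i, j] = CODON_AA[i] == CODON_AA[j]
    return single, transition, synonymous


#: SINGLE_CHANGE[i, j]: codons i and j differ at exactly one position.
#: IS_TRANSITION[i, j]: that single change is a transition (only meaningful
#: where SINGLE_CHANGE holds).  IS_SYNONYMOUS[i, j]: codons i and j encode the
#: same amino acid.
SINGLE_CHANGE, IS_TRANSITION, IS_SYNONYMOUS = _pair_tables()


def translate_codon(codon: str) -> str:
    """Translate one codon; ``---`` maps to the gap character ``-``."""
    if codon == "---":
        return "-"
    if codon in CODON_INDEX:
        return CODON_AA[CODON_INDEX[codon]]
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no amino-acid translation")
    raise ValueError(f"unrecognized codon {codon!r}")
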