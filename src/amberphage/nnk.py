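"""Combinatorics of NNK site-saturation libraries.

An NNK codon draws bases N = {A,C,G,T} at positions 1-2 and K = {G,T} at
position 3, giving 32 codons that cover all 20 amino acids plus exactly one
stop codon, the amber codon TAG (TAA and TGA both end in A and are excluded
by K).  A library of L independent NNK positions therefore contains at least
one in-frame amber codon with probability 1 - (31/32)^L; for the heptapeptide
case L = 7 this is 19.9%.

Probabilities are computed as exact rationals and rendered as floats only on
output, so downstream tests need no ad hoc tolerances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

DNA_BASES = frozenset("ACGT")

#: Amber stop codon; repurposed by amber suppression to encode an ncAA.
AMBER_CODON = "TAG"

#: Symbol used for the amber outcome in peptides (the ncAA position).
AMBER_SYMBOL = "X"

#: Symbol for non-amber (ochre/opal) stops, which NNK cannot produce.
STOP_SYMBOL = "*"

# Standard genetic code (NCBI translation table 1), stops as '*'.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

AMINO_ACIDS = tuple(sorted(set(GENETIC_CODE.values()) - {"*"}))

#: Row order used by all positional matrices: 20 amino acids + amber.
OUTCOME_ORDER = AMINO_ACIDS + (AMBER_SYMBOL,)


@dataclass(frozen=True)
class DegenerateCodonScheme:
    """A degenerate codon: one ordered base set per codon position."""

    base_sets: tuple[frozenset[str], frozenset[str], frozenset[str]]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.base_sets) != 3:
            raise ValueError("a codon scheme needs exactly three base sets")
        for s in self.base_sets:
            if not s:
                raise ValueError("base sets must be non-empty")
            bad = set(s) - DNA_BASES
            if bad:
                raise ValueError(f"invalid base symbol(s): {sorted(bad)}")


def scheme_from_string(code: str) -> DegenerateCodonScheme:
    """Build a scheme from a 3-letter IUPAC degenerate codon such as 'NNK'."""
    iupac = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    code = code.upper()
    if len(code) != 3 or any(c not in iupac for c in code):
        raise ValueError(f"not a 3-letter IUPAC degenerate codon: {code!r}")
    return DegenerateCodonScheme(
        tuple(frozenset(iupac[c]) for c in code), name=code
    )


#: The NNK scheme used throughout: N-N-K = {ACGT},{ACGT},{GT}.
NNK = scheme_from_string("NNK")


def expand_scheme(scheme: DegenerateCodonScheme) -> list[str]:
    """All distinct codons of a degenerate scheme, lexicographically sorted."""
    return sorted(
        "".join(bases) for bases in itertools.product(*map(sorted, scheme.base_sets))
    )


@dataclass
class NnkOutcomeTable:
    """Per-outcome degeneracy and probability for a degenerate codon scheme.

    Outcomes are single letters: the 20 amino acids, 'X' for the amber codon
    TAG, and '*' only if the scheme produces a non-amber stop (NNK does not).
    """

    scheme: DegenerateCodonScheme
    degeneracy: dict[str, int]
    probability: dict[str, Fraction]
    codons_by_outcome: dict[str, list[str]] = field(repr=False, default_factory=dict)

    @property
    def total_codons(self) -> int:
        return sum(self.degeneracy.values())

    @property
    def has_non_amber_stop(self) -> bool:
        return STOP_SYMBOL in self.degeneracy

    @property
    def amber_probability(self) -> Fraction:
        return self.probability.get(AMBER_SYMBOL, Fraction(0))

    @property
    def sense_codon_count(self) -> int:
        return sum(
            n for sym, n in self.degeneracy.items()
            if sym not in (AMBER_SYMBOL, STOP_SYMBOL)
        )


def outcome_probabilities(scheme: DegenerateCodonScheme = NNK) -> NnkOutcomeTable:
    """Translate every codon of the scheme and tally outcome probabilities.

    TAG maps to the amber outcome 'X'; any other stop codon maps to '*' and
    is flagged via ``has_non_amber_stop``.
    """
    codons = expand_scheme(scheme)
    degeneracy: dict[str, int] = {}
    by_outcome: dict[str, list[str]] = {}
    for codon in codons:
        aa = AMBER_SYMBOL if codon == AMBER_CODON else GENETIC_CODE[codon]
        degeneracy[aa] = degeneracy.get(aa, 0) + 1
        by_outcome.setdefault(aa, []).append(codon)
    total = len(codons)
    probability = {aa: Fraction(n, total) for aa, n in degeneracy.items()}
    return NnkOutcomeTable(scheme, degeneracy, probability, by_outcome)


def prob_at_least_one_amber(
    num_positions: int, scheme: DegenerateCodonScheme = NNK
) -> float:
    """P(>=1 amber codon) over i.i.d. uniform draws from the scheme.

    Closed form 1 - (1 - p)^L with p the scheme's amber probability,
    evaluated in exact rational arithmetic before conversion to float.
    """
    if num_positions < 0:
        raise ValueError("num_positions must be >= 0")
    p = outcome_probabilities(scheme).amber_probability
    return float(1 - (1 - p) ** num_positions)


def expected_abundance_matrix(
    num_positions: int, scheme: DegenerateCodonScheme = NNK
) -> pd.DataFrame:
    """Theoretical outcome-by-position abundance matrix under i.i.d. draws.

    Rows are outcomes (20 amino acids + 'X', plus '*' if the scheme has a
    non-amber stop); columns are 1-based positions.  Every column is the
    scheme's outcome probability vector.
    """
    if num_positions < 1:
        raise ValueError("num_positions must be >= 1")
    table = outcome_probabilities(scheme)
    rows = [o for o in OUTCOME_ORDER if o in table.probability]
    if table.has_non_amber_stop:
        rows.append(STOP_SYMBOL)
    col = [float(table.probability[o]) for o in rows]
    return pd.DataFrame(
        {pos: col for pos in range(1, num_positions + 1)}, index=rows
    )
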