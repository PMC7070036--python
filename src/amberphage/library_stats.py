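"""Composition statistics of spliced library inserts.

Given the 21-nt inserts that pass QC, this module checks NNK validity
(third base of every codon in {G,T}, no N), translates inserts with the
amber codon rendered as 'X', and builds the positional matrices used to
judge library quality: per-position TAG occurrence percentages, the
outcome-by-position abundance matrix (count at position / total sequences),
and the relative deviation from the theoretical i.i.d. NNK expectation,
(observed - expected) / expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nnk import (
    AMBER_CODON,
    AMBER_SYMBOL,
    GENETIC_CODE,
    NNK,
    OUTCOME_ORDER,
    expand_scheme,
    expected_abundance_matrix,
)


@dataclass
class InsertSet:
    """A set of fixed-length nucleotide inserts (3 nt per randomized position)."""

    inserts: list[str]
    n_positions: int = 7

    def __post_init__(self) -> None:
        want = 3 * self.n_positions
        for ins in self.inserts:
            if len(ins) != want:
                raise ValueError(
                    f"insert length {len(ins)} != 3 x {self.n_positions}"
                )

    def __len__(self) -> int:
        return len(self.inserts)


def codons_of(insert: str) -> list[str]:
    if len(insert) % 3:
        raise ValueError("insert length not divisible by 3")
    return [insert[i : i + 3] for i in range(0, len(insert), 3)]


def validate_nnk(insert: str) -> tuple[bool, list[int]]:
    """NNK validity: every codon's third base in {G,T} and no N anywhere.

    Returns (is_valid, 1-based offending codon positions).
    """
    offending = []
    for pos, codon in enumerate(codons_of(insert), start=1):
        if codon[2] not in "GT" or "N" in codon:
            offending.append(pos)
    return not offending, offending


def translate_insert(insert: str) -> str:
    """Standard-code translation with TAG -> 'X' and TAA/TGA -> '*'."""
    if "N" in insert:
        raise ValueError("cannot translate insert containing N")
    return "".join(
        AMBER_SYMBOL if c == AMBER_CODON else GENETIC_CODE[c]
        for c in codons_of(insert)
    )


def has_amber(insert: str) -> bool:
    return AMBER_CODON in codons_of(insert)


def amber_content(insert_set: InsertSet) -> float:
    """Fraction of inserts carrying >=1 in-frame TAG codon."""
    if not insert_set.inserts:
        raise ValueError("empty insert set")
    return sum(has_amber(i) for i in insert_set.inserts) / len(insert_set)


@dataclass
class PositionalStats:
    """Positional composition matrices for a set of NNK inserts.

    All matrices have 1-based positions as columns.  ``codon_counts`` rows
    are the 32 NNK codons; ``outcome_abundance`` and ``deviation`` rows are
    the 21 outcomes (20 amino acids + 'X').  Inserts failing NNK validation
    are excluded from the matrices and reported via ``nnk_violation_rate``.
    """

    codon_counts: pd.DataFrame
    outcome_abundance: pd.DataFrame
    tag_percent: pd.Series
    deviation: pd.DataFrame
    n_total: int
    n_valid: int
    undefined_outcomes: list[str] = field(default_factory=list)

    @property
    def nnk_violation_rate(self) -> float:
        return 0.0 if self.n_total == 0 else 1 - self.n_valid / self.n_total


def positional_stats(
    insert_set: InsertSet, expected: pd.DataFrame | None = None
) -> PositionalStats:
    """Count codons per position and compare with the theoretical expectation.

    ``expected`` defaults to the i.i.d. NNK expectation for the set's number
    of positions; a zero expected entry with nonzero observation yields NaN
    in the deviation matrix and is flagged in ``undefined_outcomes``.
    """
    npos = insert_set.n_positions
    if expected is None:
        expected = expected_abundance_matrix(npos, NNK)
    positions = list(range(1, npos + 1))
    nnk_codons = expand_scheme(NNK)
    codon_idx = {c: i for i, c in enumerate(nnk_codons)}

    counts = np.zeros((len(nnk_codons), npos), dtype=np.int64)
    n_valid = 0
    for insert in insert_set.inserts:
        ok, _ = validate_nnk(insert)
        if not ok:
            continue
        n_valid += 1
        for pos, codon in enumerate(codons_of(insert)):
            counts[codon_idx[codon], pos] += 1

    codon_counts = pd.DataFrame(counts, index=nnk_codons, columns=positions)

    outcomes = [o for o in OUTCOME_ORDER]
    abundance = pd.DataFrame(0.0, index=outcomes, columns=positions)
    if n_valid:
        for codon in nnk_codons:
            sym = AMBER_SYMBOL if codon == AMBER_CODON else GENETIC_CODE[codon]
            abundance.loc[sym] += codon_counts.loc[codon] / n_valid

    tag_percent = 100.0 * abundance.loc[AMBER_SYMBOL]
    tag_percent.name = "tag_percent"

    exp = expected.reindex(index=outcomes, columns=positions).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        deviation = (abundance - exp) / exp
    undefined = sorted(
        set(deviation.index[((exp == 0) & (abundance > 0)).any(axis=1)])
    )
    deviation[exp == 0] = np.nan

    return PositionalStats(
        codon_counts=codon_counts,
        outcome_abundance=abundance,
        tag_percent=tag_percent,
        deviation=deviation,
        n_total=len(insert_set),
        n_valid=n_valid,
        undefined_outcomes=undefined,
    )


def summary(insert_set: InsertSet) -> dict:
    """Headline numbers: totals, NNK violation rate, amber content.

    Amber content is reported with both denominators — all inserts and
    NNK-valid inserts (the headline figure).
    """
    valid = [i for i in insert_set.inserts if validate_nnk(i)[0]]
    out = {
        "n_total": len(insert_set),
        "n_nnk_valid": len(valid),
        "nnk_violation_rate": 1 - len(valid) / len(insert_set) if insert_set.inserts else 0.0,
        "amber_content_all": amber_content(insert_set) if insert_set.inserts else None,
        "amber_content_nnk_valid": (
            amber_content(InsertSet(valid, insert_set.n_positions)) if valid else None
        ),
    }
    return out


def plot_abundance_heatmap(matrix: pd.DataFrame, path: str, title: str = "") -> None:
    """Write a simple outcome-by-position heat map (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.9 * len(matrix.columns) + 2, 6))
    im = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    ax.set_xlabel("position")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
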