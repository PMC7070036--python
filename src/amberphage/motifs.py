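"""Anchor-relative analysis of selected clone peptide sequences.

Selected clones are 7-mer peptides over the 20 amino acids plus 'X', the
symbol for the amber-encoded noncanonical residue that anchors binding to
the target's active site.  Positions are numbered relative to the anchor:
-1 is immediately N-terminal to X, +1 immediately C-terminal, and so on.
This module computes anchor-relative residue frequencies, consensus-motif
match fractions (e.g. C-T-[V/F]-X-[V/I]), and residue-class fractions, each
as a descriptive fraction with a Wilson 95% confidence interval where a
report is produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .nnk import AMBER_SYMBOL, AMINO_ACIDS

VALID_RESIDUES = frozenset(AMINO_ACIDS) | {AMBER_SYMBOL}


@dataclass
class CloneSet:
    """Peptides from a selection round plus free-form metadata."""

    peptides: list[str]
    metadata: dict = field(default_factory=dict)
    require_amber: bool = True

    def __post_init__(self) -> None:
        for pep in self.peptides:
            bad = set(pep) - VALID_RESIDUES
            if bad:
                raise ValueError(f"invalid residue(s) {sorted(bad)} in {pep!r}")
            if self.require_amber and AMBER_SYMBOL not in pep:
                raise ValueError(f"clone {pep!r} has no amber residue 'X'")

    def __len__(self) -> int:
        return len(self.peptides)


@dataclass(frozen=True)
class MotifPattern:
    """Offset -> allowed-residue-set map relative to the anchor at offset 0."""

    offsets: tuple[tuple[int, frozenset[str]], ...]

    def __post_init__(self) -> None:
        d = dict(self.offsets)
        if d.get(0) != frozenset({AMBER_SYMBOL}):
            raise ValueError("offset 0 must map to the anchor set {'X'}")
        for off, residues in d.items():
            if not residues or (set(residues) - VALID_RESIDUES):
                raise ValueError(f"bad residue set at offset {off}")

    @classmethod
    def from_dict(cls, mapping: dict[int, str | set[str]]) -> "MotifPattern":
        return cls(
            tuple(
                sorted(
                    (int(off), frozenset(res))
                    for off, res in mapping.items()
                )
            )
        )

    def as_dict(self) -> dict[int, frozenset[str]]:
        return dict(self.offsets)


def parse_motif(spec: str) -> MotifPattern:
    """Parse the compact motif syntax, e.g. ``"C T [VF] X [VI]"``.

    Tokens are single residues or bracketed alternatives; exactly one token
    must be the anchor ``X``; offsets are assigned relative to it.
    """
    tokens = spec.split()
    sets: list[frozenset[str]] = []
    anchor_idx = None
    for i, tok in enumerate(tokens):
        if tok.startswith("[") and tok.endswith("]"):
            residues = frozenset(tok[1:-1])
        else:
            residues = frozenset(tok)
        if residues == frozenset({AMBER_SYMBOL}):
            if anchor_idx is not None:
                raise ValueError("motif must contain exactly one anchor X")
            anchor_idx = i
        sets.append(residues)
    if anchor_idx is None:
        raise ValueError("motif must contain the anchor X")
    return MotifPattern.from_dict(
        {i - anchor_idx: s for i, s in enumerate(sets)}
    )


def _leftmost_anchor(peptide: str) -> int:
    return peptide.index(AMBER_SYMBOL)


def anchor_relative_frequencies(
    clones: CloneSet, offset: int
) -> tuple[dict[str, float], int, int]:
    """Residue frequencies at a fixed offset from the leftmost anchor.

    Clones whose anchor+offset falls outside the peptide are excluded from
    the denominator.  Returns (residue -> fraction, n_included, n_excluded).
    """
    if offset == 0:
        raise ValueError("offset 0 is the anchor itself")
    counts: dict[str, int] = {}
    included = excluded = 0
    for pep in clones.peptides:
        idx = _leftmost_anchor(pep) + offset
        if 0 <= idx < len(pep):
            included += 1
            counts[pep[idx]] = counts.get(pep[idx], 0) + 1
        else:
            excluded += 1
    freqs = {r: c / included for r, c in counts.items()} if included else {}
    return freqs, included, excluded


def motif_fraction(
    clones: CloneSet, pattern: MotifPattern
) -> tuple[float, list[int]]:
    """Fraction of clones matching the motif at *any* anchor placement.

    A clone matches iff for some occurrence of 'X' every pattern offset lands
    inside the peptide and carries an allowed residue.  Returns the fraction
    over all clones and the matching clone indices.
    """
    offsets = pattern.as_dict()
    matching = [
        i for i, pep in enumerate(clones.peptides) if _matches(pep, offsets)
    ]
    frac = len(matching) / len(clones) if len(clones) else 0.0
    return frac, matching


def _matches(peptide: str, offsets: dict[int, frozenset[str]]) -> bool:
    for anchor, res in enumerate(peptide):
        if res != AMBER_SYMBOL:
            continue
        ok = True
        for off, allowed in offsets.items():
            idx = anchor + off
            if not (0 <= idx < len(peptide)) or peptide[idx] not in allowed:
                ok = False
                break
        if ok:
            return True
    return False


def residue_class_fraction(
    clones: CloneSet, offset: int, residue_class: set[str] | frozenset[str]
) -> float:
    """Fraction of denominator-included clones with an allowed residue at the offset."""
    freqs, included, _ = anchor_relative_frequencies(clones, offset)
    if not included:
        return 0.0
    return sum(f for r, f in freqs.items() if r in residue_class)


def consensus_report(clones: CloneSet, offsets: list[int]) -> pd.DataFrame:
    """Ranked residue table per offset with Wilson 95% intervals.

    Rows are sorted by offset, then descending frequency, ties alphabetically.
    """
    if not len(clones):
        raise ValueError("empty clone set")
    rows = []
    for off in offsets:
        freqs, included, excluded = anchor_relative_frequencies(clones, off)
        ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
        for residue, frac in ranked:
            count = round(frac * included)
            lo, hi = proportion_confint(count, included, alpha=0.05, method="wilson")
            rows.append(
                {
                    "offset": off,
                    "residue": residue,
                    "count": count,
                    "n_included": included,
                    "n_excluded": excluded,
                    "fraction": frac,
                    "ci95_low": lo,
                    "ci95_high": hi,
                }
            )
    return pd.DataFrame(rows)


#: Consensus motif reported for the SIRT2 selection: Cys-Thr-[Val/Phe]-X-[Val/Ile].
SIRT2_CONSENSUS_MOTIF = parse_motif("C T [VF] X [VI]")

#: Aliphatic residue class enriched immediately C-terminal to the anchor.
ALIPHATIC_PLUS_ONE = frozenset("IVLA")


def load_sirt2_demo_clones() -> CloneSet:
    """Load the bundled synthetic SIRT2 round-3 demonstration clone set.

    This is a *synthetic* 20-clone set, not the experimentally sequenced
    clones: it was constructed to reproduce the selection's reported summary
    statistics — 5/20 clones (25%) carry the consensus motif
    Cys-Thr-[Val/Phe]-X-[Val/Ile], more than half carry Ile/Val/Leu/Ala
    immediately C-terminal to the anchor, and the -1/+3 positions are
    enriched for Val/Leu/Phe and Ser/Thr respectively.  Use it for worked
    examples and pipeline checks, not as experimental data.
    """
    text = (
        resources.files("amberphage.data")
        .joinpath("sirt2_round3_clones_synthetic.txt")
        .read_text()
    )
    peptides = [
        line.split("\t")[0].strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return CloneSet(peptides, metadata={"target": "SIRT2", "round": 3, "synthetic": True})
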