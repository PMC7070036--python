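"""Independent reference implementations used as test oracles.

These deliberately re-derive results with naive brute force (full offset
scans, exhaustive enumeration, deterministic mean-field recursions) and
share no code with the package's implementation paths they check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

_CODE = {
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

NNK_CODONS = ["".join(c) for c in itertools.product("ACGT", "ACGT", "GT")]


def enumerate_amber_fraction(num_positions: int) -> Fraction:
    """Exact amber-containing fraction by exhaustive enumeration of 32^L strings."""
    if num_positions == 0:
        return Fraction(0)
    with_amber = 0
    total = 0
    for combo in itertools.product(NNK_CODONS, repeat=num_positions):
        total += 1
        if "TAG" in combo:
            with_amber += 1
    return Fraction(with_amber, total)


def nnk_aa_degeneracy() -> dict[str, int]:
    """Outcome degeneracies by direct enumeration (amber kept as 'X')."""
    out: dict[str, int] = {}
    for codon in NNK_CODONS:
        sym = "X" if codon == "TAG" else _CODE[codon]
        out[sym] = out.get(sym, 0) + 1
    return out


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def _expected_error(qual) -> float:
    return sum(10 ** (-q / 10) for q in qual)


def _best_offset(seq: str, anchor: str):
    best = None
    for off in range(len(seq) - len(anchor) + 1):
        mm = sum(
            a != b for a, b in zip(seq[off : off + len(anchor)], anchor)
        )
        if best is None or mm < best[1]:
            best = (off, mm)
    return best


def _splice(seq: str, cfg) -> str | None:
    composite = cfg.upstream_anchor + cfg.spacer
    best = _best_offset(seq, composite)
    if best is None or best[1] > cfg.max_anchor_mismatches:
        return None
    start = best[0] + len(composite)
    insert = seq[start : start + cfg.library_len]
    if len(insert) < cfg.library_len:
        return None
    tail = seq[start + cfg.library_len : start + cfg.library_len + len(cfg.downstream_anchor)]
    if not tail:
        return None
    mm = sum(a != b for a, b in zip(tail, cfg.downstream_anchor[: len(tail)]))
    if mm > cfg.max_anchor_mismatches:
        return None
    return insert


def reference_disposition(pair, cfg) -> str:
    """Full per-pair disposition by the reference pipeline."""
    if len(pair.fwd_seq) < cfg.fwd_trunc_len or len(pair.rev_seq) < cfg.rev_trunc_len:
        return "fail_length"
    fs = pair.fwd_seq[: cfg.fwd_trunc_len]
    fq = pair.fwd_qual[: cfg.fwd_trunc_len]
    rs = pair.rev_seq[: cfg.rev_trunc_len]
    rq = pair.rev_qual[: cfg.rev_trunc_len]
    if _expected_error(fq) > cfg.max_expected_error or _expected_error(rq) > cfg.max_expected_error:
        return "fail_expected_error"
    fwd_ins = _splice(fs, cfg)
    if fwd_ins is None:
        return "fail_anchor_fwd"
    rev_ins = _splice(_revcomp(rs), cfg)
    if rev_ins is None:
        return "fail_anchor_rev"
    if fwd_ins != rev_ins or "N" in fwd_ins:
        return "fail_pair_mismatch"
    return "kept"


def mean_field_selection(cfg) -> list[float]:
    """Deterministic expectation of the selection recursion.

    Returns the pre-selection susceptible fraction at each round under the
    same update rules as the stochastic simulator, with expectations in
    place of sampling.
    """
    frac = dict(cfg.initial_fractions)
    out = []
    for _ in range(cfg.rounds):
        susc = {
            "sense_functional": frac["sense_functional"] * (1 - cfg.immunity_efficiency),
            "amber": frac["amber"],
            "deleterious": frac["deleterious"],
        }
        out.append(sum(susc.values()))
        surv = {c: susc[c] * cfg.infection_probability for c in susc}
        if cfg.passage_removes_deleterious:
            surv["deleterious"] = 0.0
        total = sum(surv.values())
        if total == 0:
            frac = {c: 0.0 for c in surv}
        else:
            frac = {c: v / total for c, v in surv.items()}
    return out
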