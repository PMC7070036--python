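"""Paired-end amplicon QC: truncation, expected-error filter, anchor splicing.

The pipeline mirrors a deep-sequencing validation of a 7-codon NNK library
cloned between two fixed primer regions.  Per read pair:

1. truncate the forward mate to 120 nt and the reverse mate to 95 nt
   (mates shorter than their truncation length are rejected);
2. discard a pair if either truncated mate has expected error
   E = sum(10^(-Q/10)) above 1;
3. locate the upstream primer region + 3-nt spacer as one composite anchor
   (Hamming search over all offsets, <=1 mismatch pooled over the composite),
   splice out the next 21 nt as the library insert, and require the
   downstream primer region (clipped to the read end) to match with <=1
   mismatch; the reverse mate is reverse-complemented first so both mates go
   through the same splicing code path;
4. require the two mates' inserts to agree exactly (any mismatch in the
   library region discards the pair).

Every rejection is tallied under exactly one reason, so the disposition
tally always sums to the number of input pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from . import io as apio

#: Rejection reasons, in the order they are applied.
DISPOSITIONS = (
    "kept",
    "fail_length",
    "fail_expected_error",
    "fail_anchor_fwd",
    "fail_anchor_rev",
    "fail_pair_mismatch",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadPair:
    """One raw paired-end read: sequences plus Phred quality integers."""

    id: str
    fwd_seq: str
    fwd_qual: list[int]
    rev_seq: str
    rev_qual: list[int]

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual):
            raise ValueError(f"{self.id}: forward seq/qual length mismatch")
        if len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"{self.id}: reverse seq/qual length mismatch")


@dataclass
class QcConfig:
    """Filtering and splicing parameters.

    Defaults reproduce the published analysis of the (NNK)7 amplicon:
    120/95 nt truncation, expected-error ceiling 1.0, upstream anchor =
    forward primer, downstream anchor = reverse complement of the reverse
    primer, 21-nt library region, and a 1-mismatch budget per flanking
    region (the constant GCC spacer between the forward primer and the first
    NNK codon shares the upstream budget).
    """

    fwd_trunc_len: int = 120
    rev_trunc_len: int = 95
    max_expected_error: float = 1.0
    upstream_anchor: str = "GCCCAGCCGGCCATG"
    spacer: str = "GCC"
    downstream_anchor: str = "GCGGCGAAAGCGGCCG"
    library_len: int = 21
    max_anchor_mismatches: int = 1
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if self.library_len % 3:
            raise ValueError("library_len must be divisible by 3")
        if not self.upstream_anchor or not self.downstream_anchor:
            raise ValueError("anchors must be non-empty")
        if self.max_anchor_mismatches < 0:
            raise ValueError("mismatch budget must be >= 0")

    @property
    def composite_upstream(self) -> str:
        return self.upstream_anchor + self.spacer


@dataclass
class KeptInsert:
    id: str
    insert: str
    upstream_mm: int
    downstream_mm: int


@dataclass
class QcResult:
    """Kept inserts plus the per-reason disposition tally."""

    kept_inserts: list[KeptInsert] = field(default_factory=list)
    disposition_tally: dict[str, int] = field(
        default_factory=lambda: {d: 0 for d in DISPOSITIONS}
    )

    @property
    def n_pairs(self) -> int:
        return sum(self.disposition_tally.values())

    @property
    def inserts(self) -> list[str]:
        return [k.insert for k in self.kept_inserts]


def expected_error(qual: list[int]) -> float:
    """Expected number of errors of a read: sum of 10^(-Q/10) over bases."""
    if any(q < 0 for q in qual):
        raise ValueError("negative Phred value")
    return sum(10.0 ** (-q / 10.0) for q in qual)


def truncate_and_filter(pair: ReadPair, cfg: QcConfig) -> tuple[ReadPair | None, str | None]:
    """Apply truncation and the expected-error filter.

    Returns (truncated pair, None) on success or (None, reason) on rejection.
    """
    if len(pair.fwd_seq) < cfg.fwd_trunc_len or len(pair.rev_seq) < cfg.rev_trunc_len:
        return None, "fail_length"
    trimmed = replace(
        pair,
        fwd_seq=pair.fwd_seq[: cfg.fwd_trunc_len],
        fwd_qual=pair.fwd_qual[: cfg.fwd_trunc_len],
        rev_seq=pair.rev_seq[: cfg.rev_trunc_len],
        rev_qual=pair.rev_qual[: cfg.rev_trunc_len],
    )
    if (
        expected_error(trimmed.fwd_qual) > cfg.max_expected_error
        or expected_error(trimmed.rev_qual) > cfg.max_expected_error
    ):
        return None, "fail_expected_error"
    return trimmed, None


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N never matches."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def find_anchor(seq: str, anchor: str, max_mm: int) -> tuple[int, int] | None:
    """Best gapless anchor placement: (offset, mismatches) or None.

    Scans every offset, keeps the minimal-mismatch offset (leftmost on ties),
    and returns None if the minimum exceeds ``max_mm``.  An anchor longer
    than the sequence cannot match.
    """
    if not anchor:
        raise ValueError("anchor must be non-empty")
    n, m = len(seq), len(anchor)
    if m > n:
        return None
    # Exact occurrence is always minimal and str.find is leftmost.
    pos = seq.find(anchor)
    if pos >= 0:
        return pos, 0
    best_pos, best_mm = -1, m + 1
    for off in range(n - m + 1):
        mm = 0
        window = seq[off : off + m]
        for x, y in zip(window, anchor):
            if x != y:
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_pos, best_mm = off, mm
            if best_mm == 0:
                break
    if best_mm <= max_mm:
        return best_pos, best_mm
    return None


def splice_library(seq: str, cfg: QcConfig) -> tuple[str, int, int] | None:
    """Splice the library insert out of a coding-strand read.

    Returns (insert, upstream_mm, downstream_mm) or None if either flanking
    region exceeds its mismatch budget or the read is too short.
    """
    composite = cfg.composite_upstream
    hit = find_anchor(seq, composite, cfg.max_anchor_mismatches)
    if hit is None:
        return None
    pos, up_mm = hit
    start = pos + len(composite)
    insert = seq[start : start + cfg.library_len]
    if len(insert) < cfg.library_len:
        return None
    down_start = start + cfg.library_len
    observed = seq[down_start : down_start + len(cfg.downstream_anchor)]
    if not observed:  # downstream anchor entirely absent -> aberrant read
        return None
    down_mm = hamming(observed, cfg.downstream_anchor[: len(observed)])
    if down_mm > cfg.max_anchor_mismatches:
        return None
    return insert, up_mm, down_mm


def merge_pair(fwd_insert: str, rev_insert_rc: str) -> str | None:
    """Zero-tolerance agreement of the two mates' library regions.

    Both arguments must already be in coding orientation.  Any disagreement
    (including any N) rejects the pair.
    """
    if len(fwd_insert) != len(rev_insert_rc):
        raise ValueError("insert length mismatch")
    if fwd_insert == rev_insert_rc and "N" not in fwd_insert:
        return fwd_insert
    return None


def process_pair(pair: ReadPair, cfg: QcConfig) -> tuple[str, KeptInsert | None]:
    """Full disposition of one pair: (reason, kept-insert-or-None)."""
    trimmed, reason = truncate_and_filter(pair, cfg)
    if trimmed is None:
        return reason, None
    fwd_hit = splice_library(trimmed.fwd_seq, cfg)
    if fwd_hit is None:
        return "fail_anchor_fwd", None
    rev_hit = splice_library(reverse_complement(trimmed.rev_seq), cfg)
    if rev_hit is None:
        return "fail_anchor_rev", None
    consensus = merge_pair(fwd_hit[0], rev_hit[0])
    if consensus is None:
        return "fail_pair_mismatch", None
    return "kept", KeptInsert(pair.id, consensus, fwd_hit[1], fwd_hit[2])


def run_qc_pairs(pairs, cfg: QcConfig | None = None) -> QcResult:
    """Run the QC pipeline over an iterable of :class:`ReadPair`."""
    cfg = cfg or QcConfig()
    result = QcResult()
    for i, pair in enumerate(pairs):
        reason, kept = process_pair(pair, cfg)
        result.disposition_tally[reason] += 1
        if kept is not None:
            result.kept_inserts.append(kept)
        if (i + 1) % 10_000 == 0:
            apio.logger.info("processed %d pairs", i + 1)
    return result


def iter_read_pairs(fwd_fastq: str | Path, rev_fastq: str | Path, phred_offset: int = 33):
    """Pair up two FASTQ files record-by-record, erroring on unpaired tails."""
    fwd = apio.read_fastq(fwd_fastq, phred_offset)
    rev = apio.read_fastq(rev_fastq, phred_offset)
    idx = 0
    while True:
        f = next(fwd, None)
        r = next(rev, None)
        if f is None and r is None:
            return
        if f is None or r is None:
            which = "forward" if f is None else "reverse"
            raise ValueError(f"{which} file exhausted at record {idx + 1}: unpaired input")
        yield ReadPair(f[0], f[1], f[2], r[1], r[2])
        idx += 1


def run_qc(fwd_fastq: str | Path, rev_fastq: str | Path, cfg: QcConfig | None = None) -> QcResult:
    """Run the QC pipeline on a pair of (possibly gzipped) FASTQ files."""
    cfg = cfg or QcConfig()
    return run_qc_pairs(iter_read_pairs(fwd_fastq, rev_fastq, cfg.phred_offset), cfg)
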