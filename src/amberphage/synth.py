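"""Synthetic-data generators for every pipeline input.

Two families of generators:

* NNK amplicon libraries — 21-nt inserts drawn codon-wise from the NNK
  distribution (optionally biased), embedded in the fixed amplicon layout
  (upstream primer + GCC spacer + insert + downstream primer), read out as a
  2 x 150 nt pair with i.i.d. per-base substitution errors and a configurable
  Phred quality model.  The error model is substitution-only: the QC pipeline
  is Hamming-based and substitutions dominate short-amplicon MiSeq data.
* Clone sets with planted motifs — peptide 7-mers with an exact number of
  motif-matching clones planted among background clones whose residues follow
  the NNK amino-acid marginal (so chance-match rates are realistic);
  background clones are resampled away from the motif, making the planted
  match fraction exact by construction.

Insert composition modes:

* ``naive_nnk`` — plain i.i.d. NNK draws (amber content = 1-(31/32)^7);
* ``amber_obligate`` — rejection-sampled until >=1 TAG;
* ``mixture`` — amber-obligate with probability ``amber_weight``, otherwise
  amber-free (rejection-sampled until no TAG), so the amber content of the
  generated library equals ``amber_weight`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as apio
from .motifs import AMBER_SYMBOL, CloneSet, MotifPattern
from .nnk import AMBER_CODON, NNK, expand_scheme, outcome_probabilities
from .qc import QcConfig, ReadPair, reverse_complement

COMPOSITIONS = ("naive_nnk", "amber_obligate", "mixture")


@dataclass
class QualityModel:
    """Phred quality generator: constant Q, or per-position Normal(mean, sd)."""

    kind: str = "constant"  # "constant" | "normal"
    q: int = 30
    mean: float = 30.0
    sd: float = 0.0
    q_min: int = 2
    q_max: int = 41

    def sample(self, length: int, rng: np.random.Generator) -> list[int]:
        if self.kind == "constant":
            return [self.q] * length
        if self.kind == "normal":
            vals = rng.normal(self.mean, self.sd, size=length)
            return np.clip(np.rint(vals), self.q_min, self.q_max).astype(int).tolist()
        raise ValueError(f"unknown quality model kind {self.kind!r}")


@dataclass
class LibrarySynthConfig:
    """Amplicon-library generator settings.

    Defaults emulate the sequencing validation of the amber-enriched
    heptapeptide library: 20,000 pairs of a 93% amber / 7% amber-free
    mixture, 2 x 150 nt reads, 0.1% per-base substitution rate, constant
    Q30 qualities, and the published amplicon layout.
    """

    n_pairs: int = 20_000
    composition: str = "mixture"
    amber_weight: float = 0.93
    codon_bias: dict[str, float] | None = None
    substitution_rate: float = 0.001
    quality_model: QualityModel = field(default_factory=QualityModel)
    read_lengths: tuple[int, int] = (150, 150)
    layout: QcConfig = field(default_factory=QcConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.composition not in COMPOSITIONS:
            raise ValueError(f"composition must be one of {COMPOSITIONS}")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if not 0.0 <= self.amber_weight <= 1.0:
            raise ValueError("amber_weight must be in [0, 1]")
        core = (
            len(self.layout.composite_upstream)
            + self.layout.library_len
            + len(self.layout.downstream_anchor)
        )
        if min(self.read_lengths) < core - len(self.layout.downstream_anchor) + 1:
            raise ValueError("read length too short for anchor + spacer + library span")


def _codon_distribution(cfg: LibrarySynthConfig) -> tuple[list[str], np.ndarray]:
    codons = expand_scheme(NNK)
    if cfg.codon_bias is None:
        weights = np.ones(len(codons))
    else:
        unknown = set(cfg.codon_bias) - set(codons)
        if unknown:
            raise ValueError(f"codon_bias contains non-NNK codons: {sorted(unknown)}")
        weights = np.array([cfg.codon_bias.get(c, 0.0) for c in codons], dtype=float)
        if weights.sum() <= 0:
            raise ValueError("codon_bias weights must sum to > 0")
    return codons, weights / weights.sum()


def sample_insert(cfg: LibrarySynthConfig, rng: np.random.Generator) -> str:
    """Draw one 21-nt insert according to the configured composition."""
    codons, probs = _codon_distribution(cfg)
    n = cfg.layout.library_len // 3

    def draw() -> str:
        idx = rng.choice(len(codons), size=n, p=probs)
        return "".join(codons[i] for i in idx)

    if cfg.composition == "naive_nnk":
        return draw()
    want_amber = cfg.composition == "amber_obligate" or (
        cfg.composition == "mixture" and rng.random() < cfg.amber_weight
    )
    while True:
        insert = draw()
        codon_list = [insert[i : i + 3] for i in range(0, len(insert), 3)]
        if (AMBER_CODON in codon_list) == want_amber:
            return insert


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_read_pair(
    insert: str, cfg: LibrarySynthConfig, rng: np.random.Generator, pair_id: str = "read"
) -> ReadPair:
    """Build the amplicon around an insert and read it out as a pair.

    The amplicon core is upstream anchor + spacer + insert + downstream
    anchor; reads longer than the core run into random padding (emulating
    sequencing past the amplicon into adapters).  The reverse mate is the
    reverse complement of the core read from the downstream end.
    """
    lay = cfg.layout
    core = lay.composite_upstream + insert + lay.downstream_anchor
    fwd_len, rev_len = cfg.read_lengths
    bases = "ACGT"

    def pad(n: int) -> str:
        return "".join(bases[i] for i in rng.integers(0, 4, size=max(n, 0)))

    fwd_template = (core + pad(fwd_len - len(core)))[:fwd_len]
    rev_template = (reverse_complement(core) + pad(rev_len - len(core)))[:rev_len]
    fwd_seq = _apply_substitutions(fwd_template, cfg.substitution_rate, rng)
    rev_seq = _apply_substitutions(rev_template, cfg.substitution_rate, rng)
    return ReadPair(
        id=pair_id,
        fwd_seq=fwd_seq,
        fwd_qual=cfg.quality_model.sample(fwd_len, rng),
        rev_seq=rev_seq,
        rev_qual=cfg.quality_model.sample(rev_len, rng),
    )


def generate_library(
    cfg: LibrarySynthConfig,
) -> tuple[list[ReadPair], list[tuple[str, str]]]:
    """Generate read pairs plus the (id, true insert) truth table."""
    rng = np.random.default_rng(cfg.seed)
    pairs: list[ReadPair] = []
    truth: list[tuple[str, str]] = []
    for i in range(cfg.n_pairs):
        insert = sample_insert(cfg, rng)
        rid = f"synthpair_{i:06d}"
        pairs.append(simulate_read_pair(insert, cfg, rng, pair_id=rid))
        truth.append((rid, insert))
    return pairs, truth


def write_library(cfg: LibrarySynthConfig, outdir: str | Path, gzip_fastq: bool = True) -> dict:
    """Write R1/R2 FASTQ and a truth TSV; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs, truth = generate_library(cfg)
    ext = ".fastq.gz" if gzip_fastq else ".fastq"
    r1 = outdir / f"synth_R1{ext}"
    r2 = outdir / f"synth_R2{ext}"
    apio.write_fastq(r1, ((p.id, p.fwd_seq, p.fwd_qual) for p in pairs))
    apio.write_fastq(r2, ((p.id, p.rev_seq, p.rev_qual) for p in pairs))
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("pair_id\ttrue_insert\n")
        for rid, insert in truth:
            fh.write(f"{rid}\t{insert}\n")
    return {"r1": str(r1), "r2": str(r2), "truth": str(truth_path)}


@dataclass
class CloneSynthConfig:
    """Planted-motif clone-set generator settings."""

    n_clones: int = 20
    motif: MotifPattern | None = None
    match_fraction: float = 0.25
    peptide_length: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.match_fraction <= 1.0:
            raise ValueError("match_fraction must be in [0, 1]")


def _aa_marginal() -> tuple[list[str], np.ndarray]:
    """NNK sense-codon amino-acid marginal (realistic background residues)."""
    table = outcome_probabilities(NNK)
    aas = [a for a in table.degeneracy if a != AMBER_SYMBOL]
    weights = np.array([table.degeneracy[a] for a in aas], dtype=float)
    return aas, weights / weights.sum()


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def sample_clone_set(cfg: CloneSynthConfig) -> CloneSet:
    """Generate an amber-obligate clone set with an exact planted match count.

    Exactly round(n_clones * match_fraction) clones (half-up rounding) match
    the motif; the rest carry a uniformly placed anchor and NNK-marginal
    background residues, resampled if they happen to match the motif, so the
    realized match fraction equals the planted one exactly.  Clone order is
    shuffled; planted indices are recorded in the metadata.
    """
    from .motifs import _matches  # reuse the single matching definition

    motif = cfg.motif
    if motif is None:
        from .motifs import SIRT2_CONSENSUS_MOTIF

        motif = SIRT2_CONSENSUS_MOTIF
    offsets = motif.as_dict()
    L = cfg.peptide_length
    lo, hi = min(offsets), max(offsets)
    valid_anchors = [a for a in range(L) if a + lo >= 0 and a + hi < L]
    if not valid_anchors:
        raise ValueError("motif does not fit in the peptide length")

    rng = np.random.default_rng(cfg.seed)
    aas, probs = _aa_marginal()
    n_match = _round_half_up(cfg.n_clones * cfg.match_fraction)

    def background_residue() -> str:
        return aas[rng.choice(len(aas), p=probs)]

    def planted_clone() -> str:
        anchor = valid_anchors[rng.integers(len(valid_anchors))]
        pep = [""] * L
        for off, allowed in offsets.items():
            pool = sorted(allowed)
            pep[anchor + off] = pool[rng.integers(len(pool))]
        for i in range(L):
            if not pep[i]:
                pep[i] = background_residue()
        return "".join(pep)

    def background_clone() -> str:
        while True:
            anchor = int(rng.integers(L))
            pep = [
                AMBER_SYMBOL if i == anchor else background_residue()
                for i in range(L)
            ]
            s = "".join(pep)
            if not _matches(s, offsets):
                return s

    peptides = [planted_clone() for _ in range(n_match)]
    peptides += [background_clone() for _ in range(cfg.n_clones - n_match)]
    planted = [True] * n_match + [False] * (cfg.n_clones - n_match)
    order = rng.permutation(cfg.n_clones)
    peptides = [peptides[i] for i in order]
    planted = [planted[i] for i in order]
    return CloneSet(
        peptides,
        metadata={
            "planted": planted,
            "n_planted": n_match,
            "chance_matches": 0,
            "seed": cfg.seed,
        },
    )
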