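import numpy as np
import pytest

from amberphage.qc import QcConfig, ReadPair
from amberphage.synth import LibrarySynthConfig, generate_library


@pytest.fixture
def qc_config() -> QcConfig:
    return QcConfig()


def perfect_pair(insert: str, cfg: QcConfig, pair_id: str = "p0", q: int = 40) -> ReadPair:
    """Error-free read pair around an insert, deterministic padding."""
    core = cfg.composite_upstream + insert + cfg.downstream_anchor
    pad = ("ACGT" * 50)
    fwd = (core + pad)[:150]
    rev_full = _revcomp(core) + pad
    rev = rev_full[:150]
    return ReadPair(pair_id, fwd, [q] * 150, rev, [q] * 150)


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


@pytest.fixture
def small_library():
    """50 error-free pairs plus the truth table (fast fixture for oracles)."""
    cfg = LibrarySynthConfig(
        n_pairs=50, composition="naive_nnk", substitution_rate=0.0, seed=11
    )
    pairs, truth = generate_library(cfg)
    return pairs, truth, cfg


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
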