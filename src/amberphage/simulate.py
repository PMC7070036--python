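"""Stochastic simulator of superinfection-immunity-based amber enrichment.

The population is partitioned into three clone classes carried by
phagemid-transformed cells:

* ``sense_functional`` — all-sense library clones that express functional
  pIII; pIII saturates the TolA receptor, so these cells are immune to
  superinfection with probability ``immunity_efficiency``;
* ``amber`` — clones with >=1 in-frame amber codon; translation terminates
  before pIII in a non-suppressing host, leaving the cell susceptible;
* ``deleterious`` — clones whose mutations abolish functional pIII; equally
  susceptible, and the reason a suppressor-host passage step exists.

One selection round is: superinfect with a kanamycin-marked helper phage
(each susceptible cell is infected with probability
``infection_probability``), grow on kanamycin so only infected cells
survive, then passage through an amber-suppressing host with a
pIII-deficient helper, which (optionally) removes deleterious clones because
they alone cannot produce particles there.  Sampling is cell-level binomial/
multinomial on class counts; all randomness flows from a seeded generator
with one child stream per round.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nnk import NNK, prob_at_least_one_amber

CLASSES = ("sense_functional", "amber", "deleterious")


def default_initial_fractions(deleterious: float = 0.05) -> dict[str, float]:
    """Naive-library composition: amber fraction from the NNK closed form."""
    amber = prob_at_least_one_amber(7, NNK)
    return {
        "sense_functional": 1.0 - amber - deleterious,
        "amber": amber,
        "deleterious": deleterious,
    }


@dataclass
class SimConfig:
    population_size: int = 1_000_000
    initial_fractions: dict[str, float] = field(default_factory=default_initial_fractions)
    immunity_efficiency: float = 1.0
    infection_probability: float = 0.99
    passage_removes_deleterious: bool = True
    rounds: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("immunity_efficiency", "infection_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if set(self.initial_fractions) != set(CLASSES):
            raise ValueError(f"initial_fractions must have keys {CLASSES}")
        total = sum(self.initial_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial fractions sum to {total}, not 1")

    @staticmethod
    def infection_probability_from_moi(moi: float, adsorption_efficiency: float = 1.0) -> float:
        """Poisson infection model: P(infected) = 1 - exp(-MOI * eta)."""
        return 1.0 - float(np.exp(-moi * adsorption_efficiency))


@dataclass
class PopulationState:
    counts: dict[str, int]
    round_index: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def extinct(self) -> bool:
        return self.total == 0

    def fractions(self) -> dict[str, float]:
        t = self.total
        return {c: (n / t if t else 0.0) for c, n in self.counts.items()}


@dataclass
class RoundReport:
    round_index: int
    susceptible_fraction: float
    post_selection_fractions: dict[str, float]
    extinct: bool = False


def initial_state(cfg: SimConfig, rng: np.random.Generator) -> PopulationState:
    counts = rng.multinomial(
        cfg.population_size, [cfg.initial_fractions[c] for c in CLASSES]
    )
    return PopulationState(dict(zip(CLASSES, counts.tolist())), round_index=0)


def superinfection_round(
    state: PopulationState, cfg: SimConfig, rng: np.random.Generator
) -> tuple[RoundReport, PopulationState]:
    """Superinfection + kanamycin selection.

    Sense-functional cells are susceptible with probability
    1 - immunity_efficiency; amber and deleterious cells with probability 1.
    A susceptible cell survives kanamycin iff it was actually superinfected.
    """
    n = state.counts
    susceptible = {
        "sense_functional": int(
            rng.binomial(n["sense_functional"], 1.0 - cfg.immunity_efficiency)
        ),
        "amber": n["amber"],
        "deleterious": n["deleterious"],
    }
    total = state.total
    susc_frac = sum(susceptible.values()) / total if total else 0.0
    survivors = {
        c: int(rng.binomial(susceptible[c], cfg.infection_probability))
        for c in CLASSES
    }
    new_state = PopulationState(survivors, round_index=state.round_index + 1)
    report = RoundReport(
        round_index=new_state.round_index,
        susceptible_fraction=susc_frac,
        post_selection_fractions=new_state.fractions(),
        extinct=new_state.extinct,
    )
    return report, new_state


def passage_round(
    state: PopulationState, cfg: SimConfig, rng: np.random.Generator
) -> PopulationState:
    """Suppressor-host passage with a pIII-deficient helper.

    If configured, deleterious clones produce no particles and drop out;
    the surviving classes are renormalized to the configured population size
    by multinomial resampling (amplification bottleneck).
    """
    counts = dict(state.counts)
    if cfg.passage_removes_deleterious:
        counts["deleterious"] = 0
    total = sum(counts.values())
    if total == 0:
        return PopulationState({c: 0 for c in CLASSES}, round_index=state.round_index)
    probs = [counts[c] / total for c in CLASSES]
    resampled = rng.multinomial(cfg.population_size, probs)
    return PopulationState(
        dict(zip(CLASSES, resampled.tolist())), round_index=state.round_index
    )


def run_selection(cfg: SimConfig) -> list[RoundReport]:
    """Run ``cfg.rounds`` alternating superinfection and passage rounds.

    Deterministic for a fixed seed: each round consumes its own child stream
    of the seeded generator.  On extinction the remaining rounds are reported
    as extinct with susceptible fraction 0.
    """
    if cfg.rounds < 1:
        raise ValueError("rounds must be >= 1")
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.rounds + 1)
    rng0 = np.random.Generator(np.random.PCG64(streams[0]))
    state = initial_state(cfg, rng0)
    reports: list[RoundReport] = []
    for r in range(cfg.rounds):
        rng = np.random.Generator(np.random.PCG64(streams[r + 1]))
        if state.extinct:
            reports.append(
                RoundReport(r + 1, 0.0, state.fractions(), extinct=True)
            )
            continue
        report, state = superinfection_round(state, cfg, rng)
        reports.append(report)
        if not state.extinct:
            state = passage_round(state, cfg, rng)
    return reports


def susceptibility_trajectory(cfg: SimConfig) -> list[float]:
    """Pre-selection susceptible fraction at the start of each round."""
    return [rep.susceptible_fraction for rep in run_selection(cfg)]


def mean_round2_susceptibility(cfg: SimConfig, seeds: list[int] | None = None) -> float:
    """Mean round-2 pre-selection susceptible fraction across replicate seeds."""
    seeds = seeds if seeds is not None else list(range(20))
    vals = []
    for s in seeds:
        reports = run_selection(replace(cfg, seed=int(s)))
        if len(reports) < 2:
            raise ValueError("need rounds >= 2 for round-2 susceptibility")
        vals.append(reports[1].susceptible_fraction)
    return float(np.mean(vals))
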