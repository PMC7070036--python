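# Methods

## NNK combinatorics

An NNK codon draws its first two bases uniformly from {A,C,G,T} and its
third from {G,T}. The 32-codon expansion contains every amino acid (with
degeneracies between 1 and 3) and exactly one stop codon, TAG; TAA and TGA
end in A and cannot occur. Treating the L randomized positions as i.i.d.
uniform draws over the 32 codons, the amber-content probability is
1 − (31/32)^L; for L = 7 this is 0.19928 (19.9% to three significant
figures). Uniformity per position is an assumption: real libraries show
codon bias (the generator can emulate it via per-codon weights), and the
deviation statistic below is designed to expose exactly such bias.

All probabilities are computed with `fractions.Fraction` and converted to
floats only at the API boundary, so equality tests on derived quantities
need no tolerances. Scheme expansion deduplicates and sorts codons, giving
deterministic row ordering in every downstream matrix. The amber outcome is
written `X` (the position of the noncanonical amino acid in peptides); a
non-amber stop, which only non-NNK schemes can produce, is written `*` and
flagged.

## Amplicon QC

The QC pipeline reproduces a paired-end (2 × 150 nt) validation of the
21-nt library region embedded between two fixed primer regions:

1. **Truncation** — forward mates to 120 nt, reverse to 95 nt. Mates
   shorter than their truncation length are rejected (`fail_length`); this
   keeps quality vectors fixed-length and is the conventional behaviour of
   truncation filters.
2. **Expected-error filter** — a pair is dropped if either truncated mate
   has E = Σ 10^(−Qᵢ/10) > 1 (`fail_expected_error`).
3. **Splicing** — the upstream primer region (15 nt) and the constant
   3-nt `GCC` spacer that precedes the first NNK codon are searched as one
   18-nt composite anchor at every gapless offset; the placement with the
   fewest mismatches wins, leftmost on ties, and must have ≤1 mismatch
   pooled over the composite. The next 21 nt are the insert. The
   downstream anchor (reverse complement of the reverse primer, clipped to
   the bases remaining in the read) must then match with ≤1 mismatch; a
   wholly absent downstream anchor rejects the read, since the truncated
   reads always span the short amplicon. The reverse mate is
   reverse-complemented before splicing so one code path serves both
   mates. The mismatch budget is per flanking region, not pooled across
   regions (configurable via `max_anchor_mismatches`).
4. **Merging** — the two mates' inserts must agree at every position; any
   disagreement, or any N, rejects the pair (`fail_pair_mismatch`). N
   counts as a mismatch everywhere.

Each pair receives exactly one disposition, so the tally always sums to
the input pair count — a property tested on every fixture. Indel-tolerant
alignment, adapter trimming and denoising are out of scope: the search is
purely Hamming-based.

## Composition statistics

Inserts failing NNK validity (any codon whose third base is not G/T, or
any N) are excluded from the positional matrices and reported as
`nnk_violation_rate`. Translation uses the standard genetic code with
TAG → `X`. The abundance matrix is count-at-position / total valid
sequences (21 outcomes × positions, columns summing to 1); `tag_percent`
is 100 × the `X` row; the deviation matrix is
(observed − expected)/expected against the i.i.d. NNK expectation — also
for amber-enriched libraries, where the large positive `X` deviations are
the point of the display. A zero expected entry (impossible under NNK)
would be reported as NaN and flagged rather than raised. The amber-content
fraction is reported against both denominators (all merged inserts and
NNK-valid inserts), with the NNK-valid figure as the headline, since the
choice is not determined by the statistic's definition.

## Selection motif analysis

Peptides are anchored at `X`. Frequency tables use the *leftmost* `X` of
multi-amber clones (frequencies need a unique anchor); motif matching is
existential over all `X` occurrences (a clone matches if any placement
satisfies every offset). Clones whose anchor+offset falls outside the
peptide are excluded from that offset's denominator and the exclusion
count is reported — no padding convention is invented. Reported fractions
are descriptive, accompanied by Wilson 95% intervals
(`statsmodels.stats.proportion`); no multiple-testing machinery is
applied, matching the descriptive use of these numbers. Motif syntax:
`"C T [VF] X [VI]"` — one token per position, brackets for alternatives,
exactly one anchor token `X`.

The bundled `sirt2_round3_clones_synthetic.txt` is a synthetic 20-clone
stand-in constructed to match reported selection summary statistics
(5/20 consensus-motif clones; 12/20 with I/V/L/A at +1; V/L/F enriched at
−1 and S/T at +3). It demonstrates the analysis; it is not experimental
data.

## Selection simulator

The population is three clone classes: `sense_functional` (expresses
pIII, superinfection-immune with probability `immunity_efficiency`),
`amber` (susceptible with probability 1), and `deleterious` (no
functional pIII, susceptible with probability 1). A selection round is:

- **Superinfection + kanamycin** — each susceptible cell is infected with
  probability `infection_probability` (derivable from MOI m and adsorption
  efficiency η as 1 − e^(−mη)); only infected cells survive kanamycin.
  The pre-selection susceptible fraction is the round's reported statistic.
- **Suppressor-host passage** — with a pIII-deficient helper, only
  amber-containing clones produce particles in a suppressing host, so the
  deleterious class is removed (configurable); the survivors are
  multinomially resampled back to the configured population size.

Sampling is cell-level binomial/multinomial on class counts rather than
ODEs, because the quantities of interest are population fractions at
discrete round boundaries; each round consumes its own child stream of the
seeded generator, so trajectories are reproducible and rounds are
statistically independent given the state. Extinction (no survivors) is
an explicit reported state, not an error. Defaults: population 10⁶,
initial amber fraction 1 − (31/32)⁷ ≈ 0.199 (the naive-library prior),
deleterious fraction 0.05 (such clones are observed after one selection
round but their abundance is not quantified; the value is configurable),
immunity 1.0, infection probability 0.99, two rounds. Growth-rate
advantages of sense clones during overnight amplification are *not*
modelled; the simulator addresses the selection arithmetic, not growth
competition, which is why the round-1 susceptible fraction tracks the
19.9% prior rather than an experimentally depressed value.

## Synthetic data

The library generator draws each insert codon-wise from the (optionally
biased) NNK distribution, in three compositions: `naive_nnk` (plain
draws), `amber_obligate` (rejection-sampled until ≥1 TAG), and `mixture`,
defined as amber-obligate with probability `amber_weight` and amber-free
otherwise — so the library's amber content equals `amber_weight` directly,
which is the property the recovery tests exercise. Reads are built from
the amplicon core (upstream anchor + spacer + insert + downstream anchor,
55 nt) padded with random bases to the read length, emulating sequencing
through the short amplicon into downstream sequence; substitution errors
are i.i.d. per base (no indels — the QC is Hamming-based and substitutions
dominate short-amplicon MiSeq error), and qualities come from a constant-Q
or per-position Normal model, independent of the planted errors. Defaults
emulate the sequencing validation of the enriched library: 20,000 pairs,
93% amber weight, 0.1% substitution rate, constant Q30, 2 × 150 nt.

The clone-set generator plants exactly ⌊n·f + 0.5⌉ motif-matching clones
(half-up rounding); background clones place one `X` uniformly and draw the
remaining residues from the NNK sense amino-acid marginal (realistic
chance-match rates), and are resampled if they happen to match the motif,
so the realized match fraction equals the planted fraction exactly.

What the generators do **not** emulate: PCR chimeras, correlated or
per-cycle error profiles, quality/error coupling, indels, and clone
fitness differences. Passing the recovery tests therefore shows the
pipeline's correctness under a clean substitution-error model, not
robustness to every artefact of real sequencing runs.

## Problem sizes and numerical choices

Unit and property tests run at n = 300–30,000 draws with tolerances of
3 binomial standard errors computed from the actual n; the enumeration
oracle for the amber closed form is exhaustive (exact rational arithmetic)
up to L = 4 (32⁴ ≈ 10⁶ strings). The pipeline recovery check uses the
generator defaults (20,000 pairs per amber weight). The simulator
cross-check against the deterministic mean-field recursion averages 30
replicate trajectories and uses 3× the empirical standard error, since
later rounds compound sampling noise. Anchors tie-break leftmost;
matrices index outcomes as rows and 1-based positions as columns; TSV
percentages are rounded to one decimal, JSON carries full precision.

## Known limitations

- The 1-mismatch primer budget is applied per flanking region; reads with
  one mismatch in each flank pass, which a total-budget reading would
  reject. The choice is configurable and flagged for sensitivity analysis.
- The simulator has no growth-competition term, so it cannot reproduce
  sense-clone takeover during repeated propagation without selection.
- The demonstration clone set is synthetic (see above); analyses of it
  validate the code paths, not the biology.
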