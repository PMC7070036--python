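# amberphage

Statistics and sequencing analysis for **amber-obligate NNK phage-display
libraries** — peptide libraries built from degenerate NNK codons in which
every clone carries at least one in-frame amber codon (TAG), so that an
amber-suppression system can install a noncanonical amino acid (rendered
`X` in peptides) at a random position of every displayed peptide.

The package is aimed at groups who build and validate such libraries and
run affinity selections with them. It covers:

- **NNK combinatorics** (`amberphage.nnk`). The NNK codon (N = A/C/G/T at
  positions 1–2, K = G/T at position 3) expands to 32 codons: 31 sense
  codons covering all 20 amino acids plus the single stop TAG. For a
  library of *L* i.i.d. NNK positions the amber-content probability is

  P(≥1 TAG) = 1 − (31/32)^L,

  which for the heptapeptide case *L* = 7 gives 19.9%. Probabilities are
  exact rationals internally.
- **Paired-end amplicon QC** (`amberphage.qc`). Deep-sequencing validation
  of the library region: truncate forward/reverse reads to 120/95 nt,
  discard reads with expected error Σ 10^(−Q/10) > 1, anchor the fixed
  primer regions flanking the 21-nt library insert (Hamming search, ≤1
  mismatch per flanking region; the constant `GCC` spacer shares the
  upstream budget), splice the insert from both mates, and keep a pair
  only if the two inserts agree exactly.
- **Library composition statistics** (`amberphage.library_stats`). NNK
  validity, translation with TAG → `X`, amber-content fraction,
  per-position TAG occurrence percentages, outcome-by-position abundance
  (count at position / total sequences), and relative deviation from the
  theoretical randomization, (observed − expected) / expected.
- **Selection motif analysis** (`amberphage.motifs`). Anchor-relative
  residue frequencies (positions numbered −1, +1, +3, … from the `X`
  anchor), consensus-motif match fractions such as `C T [VF] X [VI]`, and
  residue-class fractions, each with Wilson 95% intervals in reports.
- **Selection simulator** (`amberphage.simulate`). A stochastic model of
  superinfection-immunity-based enrichment: cells carrying sense-only
  clones express pIII and resist superinfection by a kanamycin-marked
  helper phage, so kanamycin selection enriches amber-containing (and
  deleterious) clones; a suppressor-host passage with a pIII-deficient
  helper then removes the deleterious class.
- **Synthetic data** (`amberphage.synth`). Generators for paired-end NNK
  amplicon FASTQ with controlled amber weight, substitution errors and
  quality profiles, and for clone sets with exactly planted motifs — every
  stage of the pipeline is testable without downloads.

The bundled 20-clone demonstration set
(`amberphage.motifs.load_sirt2_demo_clones`) is **synthetic**: it was
constructed to reproduce the summary statistics reported for a SIRT2
affinity selection (25% consensus-motif fraction, >50% aliphatic residues
at +1), not transcribed from experimental sequences.

## Worked example

Theory — amber content of an (NNK)₇ library:

```bash
$ amberphage theory --positions 7
{
  "P_amber_per_position": 0.03125,
  "P_at_least_one_amber": 0.19927754349191673,
  "sense_codon_count": 31,
  "total_codons": 32,
  ...
}
```

One amber codon in 32 per position; 19.9% of clones carry at least one
amber codon across seven positions.

Synthetic library → QC → composition statistics:

```bash
$ amberphage synth library --out demo/lib --n-pairs 2000 --amber-weight 0.93 --seed 7
$ amberphage qc --fwd demo/lib/synth_R1.fastq.gz --rev demo/lib/synth_R2.fastq.gz --out demo/qc
{
  "fail_anchor_fwd": 1,
  "fail_anchor_rev": 1,
  "fail_expected_error": 0,
  "fail_length": 0,
  "fail_pair_mismatch": 80,
  "kept": 1918
}
$ amberphage stats --inserts demo/qc/kept.fasta --out demo/stats
{
  "amber_content_all": 0.9332638164754953,
  "amber_content_nnk_valid": 0.9332638164754953,
  "n_nnk_valid": 1918,
  "n_total": 1918,
  "nnk_violation_rate": 0.0
}
```

At a 0.1% per-base error rate ~4% of pairs lose their insert to the
zero-tolerance library-region agreement rule; the amber content of the
kept inserts (93.3%) recovers the generator's amber weight (93%).

Motif analysis of the demonstration clones:

```bash
$ amberphage select --clones demo/clones.txt --motif "C T [VF] X [VI]"
# motif_fraction: 0.25  (5 of 20 clones)
# -1 frequencies: V 0.45, F 0.25, L 0.15, A 0.10, S 0.05
```

Two rounds of superinfection-immunity selection (`amberphage simulate
--seed 17`) take the susceptible fraction from 0.250 (the naive
amber + deleterious share) to 1.0 after the suppressor-host passage
removes deleterious clones.

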