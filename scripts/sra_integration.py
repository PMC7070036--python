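#!/usr/bin/env python
"""Integration run of the QC pipeline on the published raw sequencing data.

The amber-obligate heptapeptide library was validated by Illumina MiSeq
paired-end sequencing; the raw reads live in SRA bioproject PRJNA606283
(biosample SAMN14088869).  This script is NOT part of the test suite: it
needs a network download (~hundreds of MB) and is provided so the published
in-frame-amber figure ("at least 93% of ~400,000 filtered reads") can be
reproduced when the data are available locally.

Typical use:

    prefetch PRJNA606283            # or fasterq-dump on the run accession
    fasterq-dump --split-files SRRxxxxxxx -O rawdata/
    python scripts/sra_integration.py rawdata/SRRxxxxxxx_1.fastq rawdata/SRRxxxxxxx_2.fastq

Expected outcome: amber content (NNK-valid denominator) >= 0.93.
"""

from __future__ import annotations

import argparse
import json

from amberphage.library_stats import InsertSet, summary
from amberphage.qc import QcConfig, run_qc


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("r1", help="forward reads FASTQ (plain or gzip)")
    parser.add_argument("r2", help="reverse reads FASTQ (plain or gzip)")
    args = parser.parse_args()

    result = run_qc(args.r1, args.r2, QcConfig())
    report = {
        "disposition_tally": result.disposition_tally,
        **summary(InsertSet(result.inserts)),
    }
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
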