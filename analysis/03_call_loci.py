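#!/usr/bin/env python
"""Call HMO-utilization loci and classify degrader categories.

A locus requires a GH112 gene plus at least one GH136 subunit in the same
genome; GH112 without GH136 marks a secondary degrader. Writes
results/run/loci.json and results/run/degraders.tsv.
"""

import argparse
from pathlib import Path

from hmolocus.homology import read_hits
from hmolocus.io import read_genomes, read_sgb_table
from hmolocus.locus import classify_cohort, detect_loci, write_loci
from hmolocus.prevalence import degrader_summary, write_degrader_summary


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--run", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    genes = read_genomes(args.cohort / "genomes")
    sgb = read_sgb_table(args.cohort / "sgb.tsv")
    hits = read_hits(args.run / "hits.tsv")

    loci = detect_loci(hits, genes)
    write_loci(loci, args.run / "loci.json")
    categories = classify_cohort(hits, sgb["genome_id"])
    summary = degrader_summary(categories, sgb)
    write_degrader_summary(summary, args.run / "degraders.tsv")

    print(f"{len(loci)} loci (GH112 anchor + >=1 GH136 subunit) -> {args.run / 'loci.json'}")
    print("degrader categories per SGB:")
    print(summary.to_string())


if __name__ == "__main__":
    main()
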