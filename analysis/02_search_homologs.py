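#!/usr/bin/env python
"""Screen every gene against the family references at 70% identity.

Reads the cohort from results/cohort/ and writes the family hit table to
results/run/hits.tsv.
"""

import argparse
from pathlib import Path

from hmolocus.homology import read_references, search_homologs, write_hits
from hmolocus.io import read_genomes


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    parser.add_argument("--identity-threshold", type=float, default=70.0)
    args = parser.parse_args()

    genes = read_genomes(args.cohort / "genomes")
    references = read_references(args.cohort / "references.faa")
    hits = search_homologs(genes, references, args.identity_threshold)

    args.out.mkdir(parents=True, exist_ok=True)
    write_hits(hits, args.out / "hits.tsv")
    print(
        f"{len(hits)} hits across {hits['genome_id'].nunique()} genomes "
        f"at >= {args.identity_threshold}% identity -> {args.out / 'hits.tsv'}"
    )
    print(hits["family"].value_counts().to_string())


if __name__ == "__main__":
    main()
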