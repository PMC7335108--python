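#!/usr/bin/env python
"""Family prevalence tables, prevalence ratios and recovery check.

Writes results/run/prevalence.tsv and prints the global GH112:GH136 and
per-SGB ratios, plus agreement between detected categories and the
generator's ground truth.
"""

import argparse
from pathlib import Path

from hmolocus.exceptions import UndefinedRatioError
from hmolocus.homology import read_hits
from hmolocus.io import read_sgb_table
from hmolocus.locus import classify_cohort
from hmolocus.prevalence import prevalence, prevalence_ratio, write_prevalence
from hmolocus.synthetic import read_truth

FAMILIES = ["GH112", "GH136_I", "GH136_II", "GH10"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--run", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    sgb = read_sgb_table(args.cohort / "sgb.tsv")
    hits = read_hits(args.run / "hits.tsv")
    table = prevalence(hits, sgb, FAMILIES)
    write_prevalence(table, args.run / "prevalence.tsv")

    n = len(sgb)
    print(f"prevalence across {n} genomes:")
    for family in FAMILIES + ["GH136"]:
        count = table.count(family)
        print(f"  {family:10s} {count:4d} genomes ({100 * count / n:5.1f}%)")
    try:
        global_ratio = prevalence_ratio(table, "GH112", "GH136")
        print(f"GH112 is {global_ratio:.2f}x as prevalent as GH136 globally")
        for sgb_id in sorted(sgb["sgb_id"].unique()):
            ratio = prevalence_ratio(table, "GH112", "GH136", sgb_id)
            print(f"  {sgb_id}: GH112:GH136 = {ratio:.2f}")
    except UndefinedRatioError as exc:
        print(f"ratio undefined: {exc}")

    truth_path = args.cohort / "truth.json"
    if truth_path.exists():
        truth = read_truth(truth_path)
        categories = classify_cohort(hits, sgb["genome_id"])
        agreement = sum(
            categories[g] == truth.genomes[g].category for g in truth.genomes
        ) / len(truth.genomes)
        print(f"degrader categories match ground truth for {100 * agreement:.1f}% of genomes")


if __name__ == "__main__":
    main()
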