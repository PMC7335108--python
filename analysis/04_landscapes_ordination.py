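#!/usr/bin/env python
"""Extract gene landscapes, compare them by OSA distance, ordinate by PCoA.

Writes landscapes.tsv, distances.tsv, ordination.tsv, eigenvalues.tsv and
representatives.tsv under results/run/, plus a PCoA scatter coloured by
SGB under results/figures/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from hmolocus.compare import (
    distance_matrix,
    pcoa,
    representatives_by_group,
    write_distance_matrix,
    write_ordination,
)
from hmolocus.homology import read_hits
from hmolocus.io import read_genomes, read_sgb_table
from hmolocus.landscape import extract_all_landscapes, write_landscapes
from hmolocus.locus import read_loci, signature_check


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--run", type=Path, default=Path("results/run"))
    parser.add_argument("--figures", type=Path, default=Path("results/figures"))
    parser.add_argument("--window", type=int, default=11)
    args = parser.parse_args()

    genes = read_genomes(args.cohort / "genomes")
    sgb = read_sgb_table(args.cohort / "sgb.tsv")
    hits = read_hits(args.run / "hits.tsv")
    loci = read_loci(args.run / "loci.json")

    landscapes = extract_all_landscapes(genes, loci, hits, n=args.window)
    write_landscapes(landscapes, args.run / "landscapes.tsv")
    n_signature = sum(signature_check(l.tokens) for l in landscapes)
    print(
        f"{len(landscapes)} landscapes (window +/-{args.window}); "
        f"{n_signature} carry the full GH112+GH136+transporter+regulator signature"
    )

    distances = distance_matrix(landscapes)
    write_distance_matrix(distances, args.run / "distances.tsv")
    ordination = pcoa(distances, k=2)
    write_ordination(ordination, args.run / "ordination.tsv", args.run / "eigenvalues.tsv")
    total = ordination.eigenvalues.sum()
    print(
        f"PCoA: top-2 axes carry {100 * ordination.eigenvalues[:2].sum() / total:.1f}% "
        f"of the positive eigenvalue mass; "
        f"{len(ordination.negative_eigenvalues)} negative eigenvalues clamped "
        f"(OSA is non-Euclidean)"
    )

    sgb_of = dict(zip(sgb["genome_id"], sgb["sgb_id"]))
    groups = {l.landscape_id: sgb_of[l.genome_id] for l in landscapes}
    representatives = representatives_by_group(landscapes, groups)
    pd.DataFrame(
        [
            {"sgb_id": s, "landscape_id": l.landscape_id, "tokens": " ".join(l.tokens)}
            for s, l in sorted(representatives.items())
        ]
    ).to_csv(args.run / "representatives.tsv", sep="\t", index=False)
    print("representative landscape per SGB:")
    for s, l in sorted(representatives.items()):
        print(f"  {s}: {' '.join(t for t in l.tokens if t != 'HP')}")

    args.figures.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 5))
    for sgb_id in sorted(set(groups.values())):
        mask = [groups[i] == sgb_id for i in ordination.ids]
        ax.scatter(
            ordination.coordinates[mask, 0],
            ordination.coordinates[mask, 1],
            label=sgb_id,
            alpha=0.7,
            s=25,
        )
    ax.set_xlabel("PCo1")
    ax.set_ylabel("PCo2")
    ax.set_title("PCoA of gene-landscape OSA distances")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(args.figures / "pcoa_landscapes.png", dpi=150)
    print(f"figure -> {args.figures / 'pcoa_landscapes.png'}")


if __name__ == "__main__":
    main()
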