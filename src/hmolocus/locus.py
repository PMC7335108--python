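"""Locus calling and degrader classification.

A genome carries an HMO-utilization locus when it has a GH112
(GNB/LNB phosphorylase) homolog *and* at least one subunit of the GH136
lacto-N-biosidase anywhere in the genome. Each GH112 hit anchors one
locus. Genomes with GH112 but no GH136 subunit are classified as
secondary degraders (they can consume released disaccharides but not
attack the parent glycans); genomes with both are primary degraders.

Co-occurrence is evaluated genome-wide rather than within a window; the
windowed structure of the neighborhood is handled by the landscape module
and by :func:`signature_check`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import pandas as pd

from .exceptions import ConsistencyError, InvalidInputError
from .io import write_json, read_json
from .vocab import ANCHOR_FAMILY, GH136_SUBUNITS

CATEGORIES = ("primary", "secondary", "none")


@dataclass(frozen=True)
class Locus:
    """A GH112-anchored locus satisfying the co-occurrence rule."""

    genome_id: str
    anchor_gene_id: str
    anchor_contig: str
    anchor_start: int
    anchor_end: int
    anchor_identity: float
    members: tuple[tuple[str, str, float], ...]  # (gene_id, family, pct_identity)


def detect_loci(hits: pd.DataFrame, genes: pd.DataFrame) -> list[Locus]:
    """One locus per GH112 hit in genomes that also carry a GH136 subunit.

    Raises
    ------
    ConsistencyError
        If a hit references a gene absent from the gene table.
    """
    if hits.empty:
        return []
    gene_index = genes.set_index(["genome_id", "gene_id"])
    missing = [
        (row.genome_id, row.gene_id)
        for row in hits.itertuples(index=False)
        if (row.genome_id, row.gene_id) not in gene_index.index
    ]
    if missing:
        raise ConsistencyError(f"hits reference unknown genes: {missing[:10]}")

    loci: list[Locus] = []
    for genome_id, genome_hits in hits.groupby("genome_id", sort=True):
        families = set(genome_hits["family"])
        if ANCHOR_FAMILY not in families or not (families & GH136_SUBUNITS):
            continue
        anchors = genome_hits[genome_hits["family"] == ANCHOR_FAMILY]
        for anchor in anchors.itertuples(index=False):
            members = tuple(
                (row.gene_id, row.family, float(row.pct_identity))
                for row in genome_hits.sort_values(["gene_id", "family"]).itertuples(index=False)
                if row.gene_id != anchor.gene_id
            )
            gene = gene_index.loc[(genome_id, anchor.gene_id)]
            loci.append(
                Locus(
                    genome_id=genome_id,
                    anchor_gene_id=anchor.gene_id,
                    anchor_contig=str(gene["contig_id"]),
                    anchor_start=int(gene["start"]),
                    anchor_end=int(gene["end"]),
                    anchor_identity=float(anchor.pct_identity),
                    members=members,
                )
            )
    return loci


def classify_degrader(genome_hits: pd.DataFrame) -> str:
    """Classify one genome as primary, secondary, or none.

    primary: >=1 GH112 hit and >=1 GH136 subunit hit; secondary: GH112
    without any GH136 subunit; none otherwise.
    """
    if genome_hits.empty:
        return "none"
    if genome_hits["genome_id"].nunique() > 1:
        raise InvalidInputError(
            f"classify_degrader expects hits from a single genome, got "
            f"{sorted(genome_hits['genome_id'].unique())}"
        )
    families = set(genome_hits["family"])
    if ANCHOR_FAMILY in families:
        return "primary" if families & GH136_SUBUNITS else "secondary"
    return "none"


def classify_cohort(hits: pd.DataFrame, genome_ids: Iterable[str]) -> dict[str, str]:
    """Degrader category per genome, for every genome in ``genome_ids``."""
    categories = {g: "none" for g in genome_ids}
    if not hits.empty:
        for genome_id, genome_hits in hits.groupby("genome_id", sort=True):
            if genome_id in categories:
                categories[genome_id] = classify_degrader(genome_hits)
    return categories


def signature_check(tokens: Iterable[str]) -> bool:
    """Full degrader-locus signature on a landscape token string.

    True iff the tokens contain at least one GH112, one GH136 subunit, one
    ABC-transporter component (SBP or PP), and one transcriptional
    regulator.
    """
    present = set(tokens)
    return (
        ANCHOR_FAMILY in present
        and bool(present & GH136_SUBUNITS)
        and bool(present & {"SBP", "PP"})
        and "TransR" in present
    )


# ---------------------------------------------------------------------------
# I/O


def write_loci(loci: list[Locus], path) -> None:
    write_json([asdict(l) for l in loci], path)


def read_loci(path) -> list[Locus]:
    return [
        Locus(**{**obj, "members": tuple(tuple(m) for m in obj["members"])})
        for obj in read_json(path)
    ]
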