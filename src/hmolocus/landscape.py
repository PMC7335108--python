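"""Gene-landscape extraction around GH112 anchors.

The neighborhood of each GH112 anchor — by default the 11 genes upstream
and 11 downstream on the anchor's contig — is encoded as a string of
family tokens. Genes with a family hit take that family's token; genes
without a hit are mapped through a keyword table on their product
annotation; everything else becomes OTHER. Windows are
orientation-normalized: a minus-strand anchor has its gene order reversed
so the anchor always reads 5'->3' left-to-right, making plus- and
minus-strand loci directly comparable (and the extraction invariant under
mirroring of the contig).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .exceptions import InvalidInputError
from .vocab import ANCHOR_FAMILY, DEFAULT_KEYWORD_TABLE, OTHER_TOKEN

DEFAULT_WINDOW = 11


@dataclass(frozen=True)
class Landscape:
    """Orientation-normalized token window around one GH112 anchor."""

    genome_id: str
    anchor_gene_id: str
    tokens: tuple[str, ...]
    anchor_index: int
    window: int
    truncated_upstream: bool
    truncated_downstream: bool

    @property
    def landscape_id(self) -> str:
        return f"{self.genome_id}:{self.anchor_gene_id}"


def tokenize(
    gene_id: str,
    product: str,
    gene_hits: pd.DataFrame | None,
    keyword_table: Sequence[tuple[str, str]] = DEFAULT_KEYWORD_TABLE,
) -> str:
    """Token for one gene: family hit first, then product keywords, else OTHER.

    If a gene hits several families, GH112 takes precedence; otherwise the
    highest-identity hit wins (ties to the lexicographically smallest
    family token).
    """
    if gene_hits is not None and len(gene_hits):
        families = set(gene_hits["family"])
        if ANCHOR_FAMILY in families:
            return ANCHOR_FAMILY
        best = gene_hits.sort_values(
            ["pct_identity", "family"], ascending=[False, True], kind="stable"
        ).iloc[0]
        return str(best["family"])
    product_lower = (product or "").lower()
    for keyword, token in keyword_table:
        if keyword in product_lower:
            return token
    return OTHER_TOKEN


def extract_landscape(
    genes: pd.DataFrame,
    genome_id: str,
    anchor_gene_id: str,
    hits: pd.DataFrame,
    n: int = DEFAULT_WINDOW,
    keyword_table: Sequence[tuple[str, str]] = DEFAULT_KEYWORD_TABLE,
) -> Landscape:
    """Extract the +/-n gene token window around a GH112 anchor.

    Genes are taken in coordinate order (ties broken by gene id) on the
    anchor's contig; if the contig ends before n genes are available the
    corresponding truncation flag is set. Minus-strand anchors are
    reversed so upstream/downstream follow the anchor's transcription
    direction.
    """
    if n < 1:
        raise InvalidInputError(f"window must be >= 1, got {n}")
    table = genes[genes["genome_id"] == genome_id]
    anchor_rows = table[table["gene_id"] == anchor_gene_id]
    if anchor_rows.empty:
        raise InvalidInputError(f"anchor gene {anchor_gene_id!r} not found in genome {genome_id!r}")
    anchor = anchor_rows.iloc[0]

    anchor_hits = hits[
        (hits["genome_id"] == genome_id)
        & (hits["gene_id"] == anchor_gene_id)
        & (hits["family"] == ANCHOR_FAMILY)
    ]
    if anchor_hits.empty:
        raise InvalidInputError(
            f"anchor gene {anchor_gene_id!r} has no {ANCHOR_FAMILY} hit"
        )

    contig = table[table["contig_id"] == anchor["contig_id"]].sort_values(
        ["start", "gene_id"], kind="stable"
    )
    gene_ids = contig["gene_id"].tolist()
    idx = gene_ids.index(anchor_gene_id)
    left = max(idx - n, 0)
    right = min(idx + n, len(gene_ids) - 1)
    window_rows = contig.iloc[left : right + 1]
    trunc_left = idx - left < n
    trunc_right = right - idx < n

    genome_hits = hits[hits["genome_id"] == genome_id]
    by_gene = dict(tuple(genome_hits.groupby("gene_id"))) if len(genome_hits) else {}
    tokens = [
        tokenize(row.gene_id, row.product, by_gene.get(row.gene_id), keyword_table)
        for row in window_rows.itertuples(index=False)
    ]
    anchor_index = idx - left

    if anchor["strand"] == "-":
        tokens.reverse()
        anchor_index = len(tokens) - 1 - anchor_index
        trunc_left, trunc_right = trunc_right, trunc_left

    return Landscape(
        genome_id=genome_id,
        anchor_gene_id=anchor_gene_id,
        tokens=tuple(tokens),
        anchor_index=anchor_index,
        window=n,
        truncated_upstream=trunc_left,
        truncated_downstream=trunc_right,
    )


def extract_all_landscapes(
    genes: pd.DataFrame,
    loci,
    hits: pd.DataFrame,
    n: int = DEFAULT_WINDOW,
    keyword_table: Sequence[tuple[str, str]] = DEFAULT_KEYWORD_TABLE,
) -> list[Landscape]:
    return [
        extract_landscape(genes, locus.genome_id, locus.anchor_gene_id, hits, n, keyword_table)
        for locus in loci
    ]


def mirror_contig(genes: pd.DataFrame, genome_id: str, contig_id: str) -> pd.DataFrame:
    """Mirror one contig: reverse coordinates and flip every strand.

    Models re-assembly of the same sequence on the opposite strand; every
    landscape extracted from the mirrored contig must be token-identical
    to the original.
    """
    genes = genes.copy()
    mask = (genes["genome_id"] == genome_id) & (genes["contig_id"] == contig_id)
    sub = genes.loc[mask]
    total = int(sub["end"].max()) + 1
    new_start = total - sub["end"]
    new_end = total - sub["start"]
    genes.loc[mask, "start"] = new_start
    genes.loc[mask, "end"] = new_end
    genes.loc[mask, "strand"] = sub["strand"].map({"+": "-", "-": "+"})
    return genes.sort_values(
        ["genome_id", "contig_id", "start", "gene_id"], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O


def write_landscapes(landscapes: list[Landscape], path) -> None:
    rows = [
        {
            "genome_id": l.genome_id,
            "anchor_id": l.anchor_gene_id,
            "anchor_index": l.anchor_index,
            "window": l.window,
            "tokens": " ".join(l.tokens),
            "truncated_upstream": l.truncated_upstream,
            "truncated_downstream": l.truncated_downstream,
        }
        for l in landscapes
    ]
    pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "anchor_id",
            "anchor_index",
            "window",
            "tokens",
            "truncated_upstream",
            "truncated_downstream",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_landscapes(path) -> list[Landscape]:
    frame = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "anchor_id": str})
    return [
        Landscape(
            genome_id=row.genome_id,
            anchor_gene_id=row.anchor_id,
            tokens=tuple(str(row.tokens).split(" ")),
            anchor_index=int(row.anchor_index),
            window=int(row.window),
            truncated_upstream=bool(row.truncated_upstream),
            truncated_downstream=bool(row.truncated_downstream),
        )
        for row in frame.itertuples(index=False)
    ]
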