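"""Readers and writers for annotated-genome gene tables.

The pipeline's in-memory container is a pandas DataFrame with one row per
gene and columns ``genome_id, contig_id, gene_id, start, end, strand,
product, protein`` (coordinates 1-based inclusive, ``start <= end``).
Genomes arrive either as GFF3 + protein-FASTA pairs (one pair per genome,
``<genome>.gff3`` / ``<genome>.faa``) or as a single consolidated TSV with
the same columns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO

from .exceptions import ParseError

GENE_COLUMNS = [
    "genome_id",
    "contig_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "product",
    "protein",
]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: coordinates, strand, product, optional protein."""

    genome_id: str
    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein: str | None = None

    def validate(self, where: str = "") -> "GeneRecord":
        ctx = f" ({where})" if where else ""
        if self.start < 1 or self.end < 1:
            raise ParseError(f"gene {self.gene_id!r}{ctx}: coordinates must be positive")
        if self.start > self.end:
            raise ParseError(
                f"gene {self.gene_id!r}{ctx}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ParseError(f"gene {self.gene_id!r}{ctx}: unknown strand {self.strand!r}")
        return self


def genes_to_frame(records: Iterable[GeneRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in records], columns=GENE_COLUMNS)
    return sort_gene_table(frame)


def sort_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    return genes.sort_values(
        ["genome_id", "contig_id", "start", "gene_id"], kind="stable"
    ).reset_index(drop=True)


def _check_duplicates(genes: pd.DataFrame, where: str) -> None:
    dup = genes.duplicated(subset=["genome_id", "gene_id"])
    if dup.any():
        names = genes.loc[dup, "gene_id"].unique().tolist()
        raise ParseError(f"duplicate gene ids in {where}: {names}")


# ---------------------------------------------------------------------------
# GFF3 + FASTA


def read_gff3_genome(gff_path, faa_path=None, genome_id: str | None = None) -> pd.DataFrame:
    """Parse one genome's GFF3 (gene features) plus optional protein FASTA."""
    gff_path = Path(gff_path)
    if genome_id is None:
        genome_id = gff_path.stem
    try:
        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise ParseError(f"cannot parse {gff_path}: {exc}") from exc

    proteins: dict[str, str] = {}
    if faa_path is not None and Path(faa_path).exists():
        proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(faa_path), "fasta")}

    records = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        product = feat.attributes.get("product", [""])[0]
        records.append(
            GeneRecord(
                genome_id=genome_id,
                contig_id=feat.seqid,
                gene_id=gene_id,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                product=product,
                protein=proteins.get(gene_id),
            ).validate(where=str(gff_path))
        )
    genes = genes_to_frame(records)
    _check_duplicates(genes, str(gff_path))
    return genes


def write_gff3_genome(genes: pd.DataFrame, gff_path, faa_path=None) -> None:
    """Write one genome as GFF3 (one ``gene`` feature per record) + protein FASTA."""
    genes = sort_gene_table(genes)
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.gene_id};product={row.product}"
            fh.write(
                f"{row.contig_id}\thmolocus\tgene\t{row.start}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )
    if faa_path is not None:
        with open(faa_path, "w") as fh:
            for row in genes.itertuples(index=False):
                if isinstance(row.protein, str) and row.protein:
                    fh.write(f">{row.gene_id}\n{row.protein}\n")


# ---------------------------------------------------------------------------
# Consolidated TSV


def read_gene_tsv(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "gene_id": str, "contig_id": str})
    missing = [c for c in GENE_COLUMNS if c not in genes.columns and c != "protein"]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if "protein" not in genes.columns:
        genes["protein"] = None
    genes["protein"] = genes["protein"].where(genes["protein"].notna(), None)
    genes["product"] = genes["product"].fillna("")
    for idx, row in enumerate(genes.itertuples(index=False)):
        line_no = idx + 2  # 1-based, after the header line
        GeneRecord(
            row.genome_id,
            row.contig_id,
            row.gene_id,
            int(row.start),
            int(row.end),
            row.strand,
            row.product,
        ).validate(where=f"{path} line {line_no}")
    genes = sort_gene_table(genes[GENE_COLUMNS])
    _check_duplicates(genes, str(path))
    return genes


def write_gene_tsv(genes: pd.DataFrame, path) -> None:
    sort_gene_table(genes)[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Directory-level entry point


def read_genomes(path) -> pd.DataFrame:
    """Read a cohort of genomes into one gene table.

    ``path`` may be a directory of ``<genome>.gff3`` / ``<genome>.faa``
    pairs, a single ``.tsv`` file, or a directory containing
    ``genes.tsv``.
    """
    path = Path(path)
    if path.is_file():
        return read_gene_tsv(path)
    tsv = path / "genes.tsv"
    gffs = sorted(path.glob("*.gff3"))
    if gffs:
        tables = [read_gff3_genome(g, g.with_suffix(".faa")) for g in gffs]
        genes = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=GENE_COLUMNS)
        return sort_gene_table(genes)
    if tsv.exists():
        return read_gene_tsv(tsv)
    raise ParseError(f"{path}: no GFF3 files and no genes.tsv found")


# ---------------------------------------------------------------------------
# SGB assignments and misc artifacts


def read_sgb_table(path) -> pd.DataFrame:
    sgb = pd.read_csv(path, sep="\t", dtype=str)
    if not {"genome_id", "sgb_id"} <= set(sgb.columns):
        raise ParseError(f"{path}: SGB table needs columns genome_id, sgb_id")
    return sgb.sort_values("genome_id", kind="stable").reset_index(drop=True)


def write_sgb_table(sgb: pd.DataFrame, path) -> None:
    sgb.sort_values("genome_id", kind="stable").to_csv(path, sep="\t", index=False)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
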