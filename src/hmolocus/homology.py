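"""Percent-identity homolog search against labelled family references.

The screening step assigns annotated genes to reference families
(GH112, GH136 subunits, GH10 xylanase, locus-accessory families) whenever
the best global-alignment identity against any reference of that family
reaches a threshold (70% by default across the pipeline). Identity is
defined on an optimal global alignment under a fixed scoring scheme
(match +1, mismatch 0, linear gap -1) as

    identity = 100 * identical columns / total alignment columns

with gap columns counted in the denominator. The definition is symmetric
by construction: the pair is canonicalised before alignment.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align, SeqIO

from .exceptions import InvalidInputError, InvalidParameterError
from .vocab import FAMILY_TOKENS

#: Labels of the reference genomes family references are drawn from.
REFERENCE_GENOME_LABELS: tuple[str, ...] = ("L1-82", "A2-183", "A2-194")

HIT_COLUMNS = ["genome_id", "gene_id", "family", "ref_id", "pct_identity"]


@dataclass(frozen=True)
class FamilyReference:
    """One reference protein with its family token and genome of origin."""

    ref_id: str
    family: str
    genome_label: str
    sequence: str

    def __post_init__(self) -> None:
        if self.family not in FAMILY_TOKENS:
            raise InvalidParameterError(
                f"unknown family token {self.family!r}; expected one of {FAMILY_TOKENS}"
            )
        if not self.sequence:
            raise InvalidInputError(f"reference {self.ref_id!r} has an empty sequence")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="global")
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _aligner()


@functools.lru_cache(maxsize=200_000)
def _identity_cached(a: str, b: str) -> float:
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


def percent_identity(a: str, b: str) -> float:
    """Percent identity of an optimal global alignment of two proteins.

    Identical columns over total alignment columns (gaps included), in
    [0, 100]. Symmetric in its arguments.

    Raises
    ------
    InvalidInputError
        If either sequence is empty.
    """
    if not a or not b:
        raise InvalidInputError("percent_identity requires two non-empty sequences")
    if a > b:  # canonical order guarantees symmetry
        a, b = b, a
    return _identity_cached(a, b)


def _identity_upper_bound(a: str, b: str, score: float) -> float:
    # For the optimal alignment: identity = 2M / (la+lb+M-S), increasing in
    # the match count M <= min(la, lb). Exact bound; used only to skip
    # traceback for hopeless pairs.
    m = min(len(a), len(b))
    return 100.0 * 2.0 * m / (len(a) + len(b) + m - score)


def search_homologs(
    genes: pd.DataFrame,
    references: Sequence[FamilyReference],
    threshold: float = 70.0,
) -> pd.DataFrame:
    """Assign genes to families by best percent identity >= ``threshold``.

    Parameters
    ----------
    genes
        Gene table with at least ``genome_id``, ``gene_id`` and ``protein``
        columns (see :mod:`hmolocus.io`). Rows without a protein sequence
        are skipped.
    references
        Family references; a gene may hit several distinct families but at
        most once per family (the best identity, ties between references
        broken by lexicographically smallest ``ref_id``).
    threshold
        Identity cut-off in (0, 100].

    Returns
    -------
    pandas.DataFrame
        Hit table with columns ``genome_id, gene_id, family, ref_id,
        pct_identity``, sorted for reproducibility.
    """
    if not references:
        raise InvalidParameterError("reference set is empty")
    if not 0 < threshold <= 100:
        raise InvalidParameterError(f"threshold must be in (0, 100], got {threshold}")

    by_family: dict[str, list[FamilyReference]] = {}
    for ref in references:
        by_family.setdefault(ref.family, []).append(ref)
    for refs in by_family.values():
        refs.sort(key=lambda r: r.ref_id)

    rows: list[tuple[str, str, str, str, float]] = []
    cols = genes[["genome_id", "gene_id", "protein"]].itertuples(index=False)
    for genome_id, gene_id, protein in cols:
        if not isinstance(protein, str) or not protein:
            continue
        for family in sorted(by_family):
            best: tuple[float, str] | None = None
            for ref in by_family[family]:
                score = _ALIGNER.score(protein, ref.sequence)
                if _identity_upper_bound(protein, ref.sequence, score) < threshold:
                    continue
                ident = percent_identity(protein, ref.sequence)
                if best is None or ident > best[0]:
                    best = (ident, ref.ref_id)
            if best is not None and best[0] >= threshold:
                rows.append((genome_id, gene_id, family, best[1], best[0]))

    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return hits.sort_values(["genome_id", "gene_id", "family"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# I/O


def write_hits(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def read_hits(path) -> pd.DataFrame:
    hits = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "gene_id": str})
    missing = set(HIT_COLUMNS) - set(hits.columns)
    if missing:
        raise InvalidInputError(f"hit table {path} lacks columns {sorted(missing)}")
    return hits


def read_references(path) -> list[FamilyReference]:
    """Read a reference FASTA with headers ``>refid|FAMILY|genome_label``."""
    refs = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 3:
            raise InvalidInputError(
                f"reference header {record.id!r} is not of the form refid|FAMILY|genome_label"
            )
        refs.append(FamilyReference(parts[0], parts[1], parts[2], str(record.seq)))
    if not refs:
        raise InvalidInputError(f"no references found in {path}")
    return refs


def write_references(references: Iterable[FamilyReference], path) -> None:
    with open(path, "w") as fh:
        for ref in references:
            fh.write(f">{ref.ref_id}|{ref.family}|{ref.genome_label}\n{ref.sequence}\n")
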