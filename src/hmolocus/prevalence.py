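"""Family prevalence tables and degrader-category summaries.

Prevalence is a genome-level statistic: a genome contributes at most one
count to a family regardless of how many paralogs it carries. Counts are
reported globally and per SGB, alongside fractions of the SGB cohort
sizes; paralog (gene-level) counts are emitted in a secondary column for
transparency. The "GH136" aggregate family means genomes carrying at
least one of the two subunits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import ConsistencyError, InvalidParameterError, UndefinedRatioError
from .locus import CATEGORIES
from .vocab import GH136_SUBUNITS

GH136_AGGREGATE = "GH136"


@dataclass
class PrevalenceTable:
    """Genome-level family presence with global and per-SGB summaries."""

    presence: pd.DataFrame  # genomes x families, boolean
    sgb_of: pd.Series  # genome_id -> sgb_id
    gene_counts: pd.DataFrame  # genomes x families, paralog counts
    families: list[str]

    @property
    def sgb_sizes(self) -> pd.Series:
        return self.sgb_of.value_counts().sort_index()

    def _family_presence(self, family: str) -> pd.Series:
        if family == GH136_AGGREGATE:
            return self.presence[sorted(GH136_SUBUNITS)].any(axis=1)
        if family not in self.presence.columns:
            raise InvalidParameterError(f"unknown family {family!r}")
        return self.presence[family]

    def count(self, family: str, scope: str = "global") -> int:
        """Genomes carrying >=1 hit of ``family``, globally or in one SGB."""
        present = self._family_presence(family)
        if scope == "global":
            return int(present.sum())
        return int(present[self.sgb_of == scope].sum())

    def to_frame(self) -> pd.DataFrame:
        """Family x {global, SGB...} counts and fractions, plus gene counts."""
        sizes = self.sgb_sizes
        rows = []
        for family in self.families + [GH136_AGGREGATE]:
            present = self._family_presence(family)
            row = {
                "family": family,
                "global_count": int(present.sum()),
                "global_fraction": float(present.mean()) if len(present) else 0.0,
                "global_gene_count": (
                    int(self.gene_counts[sorted(GH136_SUBUNITS)].to_numpy().sum())
                    if family == GH136_AGGREGATE
                    else int(self.gene_counts[family].sum())
                ),
            }
            for sgb, size in sizes.items():
                in_sgb = present[self.sgb_of == sgb]
                row[f"{sgb}_count"] = int(in_sgb.sum())
                row[f"{sgb}_fraction"] = float(in_sgb.sum() / size) if size else 0.0
            rows.append(row)
        return pd.DataFrame(rows)


def prevalence(
    hits: pd.DataFrame, sgb: pd.DataFrame, families: Sequence[str]
) -> PrevalenceTable:
    """Genome-level prevalence of each family, globally and per SGB.

    Every genome in the SGB assignment table contributes to cohort sizes,
    hits or not. Hit genomes missing from the assignment table raise a
    :class:`ConsistencyError` naming the offenders.
    """
    sgb_of = pd.Series(
        sgb["sgb_id"].to_numpy(), index=sgb["genome_id"].to_numpy(), name="sgb_id"
    ).sort_index()
    if not hits.empty:
        unknown = sorted(set(hits["genome_id"]) - set(sgb_of.index))
        if unknown:
            raise ConsistencyError(f"genomes without SGB assignment: {unknown}")

    families = list(families)
    genomes = list(sgb_of.index)
    presence = pd.DataFrame(False, index=genomes, columns=families)
    gene_counts = pd.DataFrame(0, index=genomes, columns=families)
    if not hits.empty:
        counted = (
            hits[hits["family"].isin(families)]
            .groupby(["genome_id", "family"])
            .size()
            .unstack(fill_value=0)
        )
        for family in counted.columns:
            gene_counts.loc[counted.index, family] = counted[family]
        presence = gene_counts > 0
    return PrevalenceTable(
        presence=presence, sgb_of=sgb_of, gene_counts=gene_counts, families=families
    )


def prevalence_ratio(
    table: PrevalenceTable, family_a: str, family_b: str, scope: str = "global"
) -> float:
    """Ratio of genome counts of two families within a scope.

    ``scope`` is ``"global"`` or an SGB id. ``"GH136"`` means genomes with
    at least one subunit.
    """
    count_b = table.count(family_b, scope)
    if count_b == 0:
        raise UndefinedRatioError(
            f"prevalence ratio {family_a}/{family_b} undefined in scope {scope!r}: "
            f"no genome carries {family_b}"
        )
    return table.count(family_a, scope) / count_b


def degrader_summary(categories: Mapping[str, str], sgb: pd.DataFrame) -> pd.DataFrame:
    """Per-SGB contingency counts of primary/secondary/none degrader genomes.

    Rows (one per SGB) sum to the SGB cohort sizes; genomes absent from
    ``categories`` count as ``none``.
    """
    sgb_of = dict(zip(sgb["genome_id"], sgb["sgb_id"]))
    counts: dict[str, dict[str, int]] = {}
    for genome_id, sgb_id in sorted(sgb_of.items()):
        row = counts.setdefault(sgb_id, {c: 0 for c in CATEGORIES})
        row[categories.get(genome_id, "none")] += 1
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=list(CATEGORIES))
    frame.index.name = "sgb_id"
    return frame.sort_index()


def write_prevalence(table: PrevalenceTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_degrader_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t")
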