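"""Synthetic SGB-structured cohorts with planted HMO-utilization loci.

The study this pipeline models screened thousands of reconstructed
*Roseburia* genomes, binned into species-level genome bins (SGBs), for
loci combining a GH112 phosphorylase with GH136 lacto-N-biosidase
subunits and ABC-transporter genes. That genome set is not redistributable
at desk scale, so this module generates cohorts with the same statistical
structure and a known ground truth:

* genomes grouped into SGBs, each SGB carrying a locus template modelled
  on the two canonical gene orders (a GH136-centred locus and a
  fucosidase-extended variant);
* planted locus genes mutated to a controlled percent identity against
  synthetic family references;
* controlled fractions of GH112-only ("secondary degrader") genomes and
  genomes without any locus;
* random locus strand and optional one-step neighborhood rearrangements
  (gene deletion, HP insertion, adjacent swap);
* background genes drawn as uniform-random proteins, which sit far below
  any homology threshold with overwhelming probability.

Everything is driven by a single root seed through indexed
``numpy.random.SeedSequence`` substreams, so identical designs reproduce
byte-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvalidParameterError
from .homology import FamilyReference, percent_identity, write_references
from .io import GENE_COLUMNS, genes_to_frame, GeneRecord, write_gff3_genome, write_sgb_table, write_json, read_json
from .vocab import ANCHOR_FAMILY, GH136_SUBUNITS

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed seed for the synthetic reference set. References stand in for the
#: fixed external reference sequences of the screen, not for per-run
#: randomness, so they are the same in every cohort.
REFERENCE_SEED = 136_112

#: Canonical locus templates (5'->3' reading order). The first mirrors the
#: GH136-centred locus (regulator, ABC transporter, GH136 subunits, GH112
#: anchor, histidine kinase); the second the fucosidase-extended variant
#: with GH29 and GH95 genes.
TEMPLATE_GH136 = ("TransR", "SBP", "PP", "PP", "HP", "GH136_I", "GH136_II", "GH112", "HisK")
TEMPLATE_FUCOSYL = (
    "TransR", "SBP", "PP", "PP", "HP", "GH29", "GH95", "GH136_I", "GH136_II", "GH112", "HisK",
)

PRODUCT_STRINGS = {
    "GH112": "glycoside hydrolase family 112 GNB/LNB phosphorylase",
    "GH136_I": "glycoside hydrolase family 136 lacto-N-biosidase subunit I",
    "GH136_II": "glycoside hydrolase family 136 lacto-N-biosidase subunit II",
    "GH10": "glycoside hydrolase family 10 endo-1,4-beta-xylanase",
    "GH29": "glycoside hydrolase family 29 alpha-L-fucosidase",
    "GH95": "glycoside hydrolase family 95 alpha-L-fucosidase",
    "GH42": "glycoside hydrolase family 42 beta-galactosidase",
    "GH36": "glycoside hydrolase family 36 alpha-galactosidase",
    "GH98": "glycoside hydrolase family 98 endo-beta-galactosidase",
    "SBP": "ABC transporter solute binding protein",
    "PP": "ABC transporter permease protein",
    "TransR": "transcriptional regulator",
    "HisK": "histidine kinase sensory protein",
    "HP": "hypothetical protein",
}

_REFERENCE_LENGTHS = {
    "GH112": 320,
    "GH136_I": 340,
    "GH136_II": 260,
    "GH10": 300,
    "GH29": 290,
    "GH95": 310,
    "SBP": 280,
    "PP": 230,
    "TransR": 180,
    "HisK": 250,
}

#: Families with one reference per reference genome (the screen's core
#: CAZyme families); accessory families get a single reference.
_MULTI_REF_FAMILIES = ("GH112", "GH136_I", "GH136_II", "GH10")
_SINGLE_REF_FAMILIES = ("GH29", "GH95", "SBP", "PP", "TransR", "HisK")

INTERGENIC_GAP = 50


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length))


def mutate_to_identity(reference: str, target_identity: float, seed: int) -> str:
    """Mutate a reference protein to a controlled percent identity.

    Substitutes seeded random positions until
    :func:`hmolocus.homology.percent_identity` against the reference lands
    within +/-3 percentage points of ``target_identity``. Deterministic for
    a given ``(reference, target_identity, seed)``.

    Raises
    ------
    InvalidParameterError
        If ``target_identity`` is outside (0, 100], or the target is
        unreachable by substitution (below the random-alignment identity
        floor).
    InvalidInputError
        If the reference is shorter than 20 residues.
    """
    if not 0 < target_identity <= 100:
        raise InvalidParameterError(
            f"target_identity must be in (0, 100], got {target_identity}"
        )
    if len(reference) < 20:
        raise InvalidInputError("reference must be at least 20 residues long")
    if target_identity == 100:
        return reference

    rng = np.random.default_rng(seed)
    length = len(reference)
    order = rng.permutation(length)  # mutation order, fixed by the seed
    replacements = [
        AMINO_ACIDS[(AMINO_ACIDS.index(reference[p]) + 1 + int(r)) % len(AMINO_ACIDS)]
        for p, r in zip(order, rng.integers(0, len(AMINO_ACIDS) - 1, size=length))
    ]

    def build(k: int) -> str:
        seq = list(reference)
        for p, repl in zip(order[:k], replacements[:k]):
            seq[p] = repl
        return "".join(seq)

    k = round(length * (1 - target_identity / 100))
    for _ in range(2 * length):
        candidate = build(k)
        ident = percent_identity(reference, candidate)
        if abs(ident - target_identity) <= 3:
            return candidate
        if ident > target_identity and k < length:
            k += 1
        elif ident < target_identity and k > 0:
            k -= 1
        else:
            break
    raise InvalidParameterError(
        f"cannot reach {target_identity}% identity by substitution of a "
        f"length-{length} reference"
    )


def default_references() -> list[FamilyReference]:
    """Synthetic reference proteins standing in for the screen's references.

    One reference per reference-genome label for the core CAZyme families
    (within-family references at ~85% mutual identity), one for each
    accessory family. Fixed across runs (seeded by ``REFERENCE_SEED``).
    """
    from .homology import REFERENCE_GENOME_LABELS

    rng = np.random.default_rng(REFERENCE_SEED)
    refs: list[FamilyReference] = []
    for family in _MULTI_REF_FAMILIES + _SINGLE_REF_FAMILIES:
        base = _random_protein(rng, _REFERENCE_LENGTHS[family])
        labels = (
            REFERENCE_GENOME_LABELS if family in _MULTI_REF_FAMILIES else REFERENCE_GENOME_LABELS[:1]
        )
        for i, label in enumerate(labels):
            seq = base if i == 0 else mutate_to_identity(base, 85, seed=int(rng.integers(2**31)))
            refs.append(FamilyReference(f"{family}_{label}", family, label, seq))
    return refs


# ---------------------------------------------------------------------------
# Cohort design and ground truth


@dataclass
class CohortDesign:
    """Parameters of a synthetic cohort.

    Defaults describe the study conditions the generator emulates: five
    SGBs of 24 genomes (120 total), planted identities uniform in
    [80, 95]%, 15% GH112-only genomes, 10% genomes without a locus, a 0.3
    per-locus rearrangement probability, and 30 background genes per
    genome (enough to fill an 11-gene window on both sides of the locus).
    """

    n_sgbs: int = 5
    genomes_per_sgb: int | Sequence[int] = 24
    locus_template_per_sgb: Sequence[Sequence[str]] | None = None
    identity_range: tuple[float, float] = (80.0, 95.0)
    frac_gh112_only: float = 0.15
    frac_no_locus: float = 0.10
    n_background_genes: int = 30
    rearrangement_rate: float = 0.3
    seed: int = 0

    def resolved_genomes_per_sgb(self) -> list[int]:
        if isinstance(self.genomes_per_sgb, int):
            return [self.genomes_per_sgb] * self.n_sgbs
        return list(self.genomes_per_sgb)

    def resolved_templates(self) -> list[tuple[str, ...]]:
        if self.locus_template_per_sgb is None:
            base = (TEMPLATE_GH136, TEMPLATE_FUCOSYL)
            return [base[i % 2] for i in range(self.n_sgbs)]
        return [tuple(t) for t in self.locus_template_per_sgb]

    def validate(self) -> "CohortDesign":
        if self.n_sgbs < 1:
            raise InvalidParameterError("n_sgbs must be positive")
        per_sgb = self.resolved_genomes_per_sgb()
        if len(per_sgb) != self.n_sgbs or any(n < 0 for n in per_sgb):
            raise InvalidParameterError("genomes_per_sgb must give a non-negative count per SGB")
        lo, hi = self.identity_range
        if not (0 < lo <= hi <= 100):
            raise InvalidParameterError(f"identity_range must lie in (0, 100], got {self.identity_range}")
        for frac, name in ((self.frac_gh112_only, "frac_gh112_only"), (self.frac_no_locus, "frac_no_locus")):
            if not 0 <= frac <= 1:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {frac}")
        if self.frac_gh112_only + self.frac_no_locus > 1:
            raise InvalidParameterError("frac_gh112_only + frac_no_locus must not exceed 1")
        if not 0 <= self.rearrangement_rate <= 1:
            raise InvalidParameterError("rearrangement_rate must be in [0, 1]")
        if self.n_background_genes < 0:
            raise InvalidParameterError("n_background_genes must be non-negative")
        templates = self.resolved_templates()
        if len(templates) != self.n_sgbs:
            raise InvalidParameterError("one locus template per SGB is required")
        for t in templates:
            if list(t).count(ANCHOR_FAMILY) != 1:
                raise InvalidParameterError(
                    f"every locus template must contain exactly one {ANCHOR_FAMILY} token: {t}"
                )
        if int(self.seed) < 0:
            raise InvalidParameterError("seed must be a non-negative integer")
        return self


@dataclass
class GenomeTruth:
    """What was planted in one genome."""

    genome_id: str
    sgb_id: str
    category: str  # primary | secondary | none
    locus_strand: str | None
    planted_tokens: list[str]  # locus genes in 5'->3' reading order; [] if none
    anchor_gene_id: str | None
    identities: dict[str, dict]  # gene_id -> {family, target_identity, identity}
    n_background_before: int  # background genes upstream of the locus in contig order
    n_background_after: int


@dataclass
class GroundTruth:
    genomes: dict[str, GenomeTruth] = field(default_factory=dict)

    def category_counts(self) -> dict[str, int]:
        counts = {"primary": 0, "secondary": 0, "none": 0}
        for g in self.genomes.values():
            counts[g.category] += 1
        return counts

    def categories(self) -> dict[str, str]:
        return {gid: g.category for gid, g in self.genomes.items()}

    def anchors(self) -> set[tuple[str, str]]:
        """(genome_id, anchor_gene_id) pairs for genomes that satisfy the locus rule."""
        return {
            (g.genome_id, g.anchor_gene_id)
            for g in self.genomes.values()
            if g.category == "primary" and g.anchor_gene_id is not None
        }

    def to_json(self) -> dict:
        return {gid: asdict(g) for gid, g in sorted(self.genomes.items())}

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruth":
        return cls(genomes={gid: GenomeTruth(**g) for gid, g in obj.items()})


def expected_landscape(truth: GenomeTruth, n: int = 11) -> list[str]:
    """Token window the landscape extractor should recover for a planted locus.

    Background genes tokenize to HP (their product is "hypothetical
    protein"), so the expected window is the planted locus padded with HP
    on both sides, oriented 5'->3' along the anchor strand.
    """
    if not truth.planted_tokens:
        raise InvalidInputError(f"genome {truth.genome_id} has no planted locus")
    tokens = list(truth.planted_tokens)
    ai = tokens.index(ANCHOR_FAMILY)
    if truth.locus_strand == "+":
        avail_up, avail_down = truth.n_background_before, truth.n_background_after
    else:
        avail_up, avail_down = truth.n_background_after, truth.n_background_before
    pad_up = min(max(n - ai, 0), avail_up)
    pad_down = min(max(n - (len(tokens) - 1 - ai), 0), avail_down)
    return ["HP"] * pad_up + tokens + ["HP"] * pad_down


# ---------------------------------------------------------------------------
# Cohort simulation


def _apply_rearrangement(template: list[str], rng: np.random.Generator) -> list[str]:
    anchor = template.index(ANCHOR_FAMILY)
    op = int(rng.integers(3))
    if op == 0 and len(template) > 1:  # delete one non-anchor gene
        candidates = [i for i in range(len(template)) if i != anchor]
        del template[int(rng.choice(candidates))]
    elif op == 1:  # insert one HP gene
        pos = int(rng.integers(len(template) + 1))
        template.insert(pos, "HP")
    elif op == 2:  # swap two adjacent non-anchor genes
        pairs = [
            i for i in range(len(template) - 1) if anchor not in (i, i + 1)
        ]
        if pairs:
            i = int(rng.choice(pairs))
            template[i], template[i + 1] = template[i + 1], template[i]
    return template


def simulate_cohort(
    design: CohortDesign,
    references: Sequence[FamilyReference] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a cohort of annotated genomes with planted loci.

    Returns the consolidated gene table, the genome->SGB assignment table
    and the :class:`GroundTruth`. Identical ``design`` (including its seed)
    reproduces identical outputs.
    """
    design.validate()
    if references is None:
        references = default_references()
    primary_ref = {}
    for ref in sorted(references, key=lambda r: r.ref_id):
        primary_ref.setdefault(ref.family, ref)

    per_sgb = design.resolved_genomes_per_sgb()
    templates = design.resolved_templates()
    seed = int(design.seed)

    records: list[GeneRecord] = []
    sgb_rows: list[tuple[str, str]] = []
    truth = GroundTruth()

    for s in range(design.n_sgbs):
        sgb_id = f"SGB_{s + 1:02d}"
        n = per_sgb[s]
        n_secondary = math.floor(design.frac_gh112_only * n)
        n_none = math.floor(design.frac_no_locus * n)
        categories = (
            ["secondary"] * n_secondary
            + ["none"] * n_none
            + ["primary"] * (n - n_secondary - n_none)
        )
        rng_sgb = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(s,)))
        rng_sgb.shuffle(categories)

        for j in range(n):
            genome_id = f"{sgb_id}_g{j + 1:03d}"
            sgb_rows.append((genome_id, sgb_id))
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(s, j)))
            category = categories[j]

            locus_tokens: list[str] = []
            locus_strand: str | None = None
            if category != "none":
                locus_tokens = list(templates[s])
                if category == "secondary":
                    locus_tokens = [t for t in locus_tokens if t not in GH136_SUBUNITS]
                if rng.random() < design.rearrangement_rate:
                    locus_tokens = _apply_rearrangement(locus_tokens, rng)
                locus_strand = "+" if rng.random() < 0.5 else "-"

            bg_total = design.n_background_genes
            bg_before = bg_total // 2 if locus_tokens else bg_total
            bg_after = bg_total - bg_before if locus_tokens else 0

            # contig order: background, locus (reversed if '-' strand), background
            contig_plan: list[tuple[str, str | None]] = [("HP_BG", None)] * bg_before
            if locus_tokens:
                ordered = locus_tokens if locus_strand == "+" else list(reversed(locus_tokens))
                contig_plan += [(tok, locus_strand) for tok in ordered]
                contig_plan += [("HP_BG", None)] * bg_after

            identities: dict[str, dict] = {}
            anchor_gene_id: str | None = None
            pos = 1
            lo, hi = design.identity_range
            for i, (tok, strand) in enumerate(contig_plan):
                gene_id = f"{genome_id}_{i + 1:04d}"
                if tok == "HP_BG":
                    protein = _random_protein(rng, int(rng.integers(150, 401)))
                    product = "hypothetical protein"
                    gene_strand = "+" if rng.random() < 0.5 else "-"
                elif tok == "HP":
                    protein = _random_protein(rng, int(rng.integers(150, 401)))
                    product = PRODUCT_STRINGS["HP"]
                    gene_strand = strand
                else:
                    target = float(rng.uniform(lo, hi))
                    ref = primary_ref[tok]
                    protein = mutate_to_identity(
                        ref.sequence, target, seed=int(rng.integers(2**31 - 1))
                    )
                    identities[gene_id] = {
                        "family": tok,
                        "target_identity": target,
                        "identity": percent_identity(ref.sequence, protein),
                    }
                    product = PRODUCT_STRINGS[tok]
                    gene_strand = strand
                    if tok == ANCHOR_FAMILY:
                        anchor_gene_id = gene_id
                end = pos + 3 * len(protein) + 2
                records.append(
                    GeneRecord(
                        genome_id=genome_id,
                        contig_id=f"{genome_id}_c1",
                        gene_id=gene_id,
                        start=pos,
                        end=end,
                        strand=gene_strand,
                        product=product,
                        protein=protein,
                    )
                )
                pos = end + INTERGENIC_GAP + 1

            truth.genomes[genome_id] = GenomeTruth(
                genome_id=genome_id,
                sgb_id=sgb_id,
                category=category,
                locus_strand=locus_strand,
                planted_tokens=locus_tokens,
                anchor_gene_id=anchor_gene_id,
                identities=identities,
                n_background_before=bg_before if locus_tokens else bg_total,
                n_background_after=bg_after,
            )

    genes = genes_to_frame(records) if records else pd.DataFrame(columns=GENE_COLUMNS)
    sgb = pd.DataFrame(sgb_rows, columns=["genome_id", "sgb_id"])
    return genes, sgb, truth


# ---------------------------------------------------------------------------
# On-disk cohort


def write_cohort(
    genes: pd.DataFrame,
    sgb: pd.DataFrame,
    truth: GroundTruth,
    references: Sequence[FamilyReference],
    outdir,
) -> None:
    """Write per-genome GFF3 + protein FASTA, SGB TSV, truth JSON, references."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_dir = outdir / "genomes"
    genome_dir.mkdir(exist_ok=True)
    for genome_id, table in genes.groupby("genome_id", sort=True):
        write_gff3_genome(
            table, genome_dir / f"{genome_id}.gff3", genome_dir / f"{genome_id}.faa"
        )
    write_sgb_table(sgb, outdir / "sgb.tsv")
    write_json(truth.to_json(), outdir / "truth.json")
    write_references(sorted(references, key=lambda r: r.ref_id), outdir / "references.faa")


def read_truth(path) -> GroundTruth:
    return GroundTruth.from_json(read_json(path))
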