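"""End-to-end pipeline driver: search -> loci -> landscapes -> compare -> report.

Given annotated genomes, family references and an SGB assignment table,
the pipeline screens every gene against the references at an identity
threshold, calls GH112-anchored loci by the GH112+GH136 co-occurrence
rule, extracts orientation-normalized gene landscapes, computes the OSA
distance matrix and its principal-coordinates ordination, selects a
representative landscape per SGB, and writes prevalence and
degrader-category tables plus a run manifest. Outputs are deterministic
functions of (inputs, config): the manifest carries no timestamps.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compare import (
    distance_matrix,
    pcoa,
    representatives_by_group,
    write_distance_matrix,
    write_ordination,
)
from .exceptions import HmolocusError
from .homology import read_references, search_homologs, write_hits
from .io import file_digest, read_genomes, read_sgb_table, write_json
from .landscape import DEFAULT_WINDOW, extract_all_landscapes, write_landscapes
from .locus import classify_cohort, detect_loci, signature_check, write_loci
from .prevalence import (
    GH136_AGGREGATE,
    degrader_summary,
    prevalence,
    prevalence_ratio,
    write_degrader_summary,
    write_prevalence,
)
from .vocab import DEFAULT_KEYWORD_TABLE

logger = logging.getLogger("hmolocus")

DEFAULT_FAMILIES = ["GH112", "GH136_I", "GH136_II", "GH10"]


@dataclass
class PipelineConfig:
    """Parameters and paths of one pipeline run."""

    genomes: str = ""
    references: str = ""
    sgb: str = ""
    out: str = "results"
    identity_threshold: float = 70.0
    window: int = DEFAULT_WINDOW
    axes: int = 2
    families: list[str] = field(default_factory=lambda: list(DEFAULT_FAMILIES))
    include_other: bool = True
    keyword_table: list[list[str]] = field(
        default_factory=lambda: [list(pair) for pair in DEFAULT_KEYWORD_TABLE]
    )
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not 0 < self.identity_threshold <= 100:
            raise HmolocusError(
                f"identity_threshold must be in (0, 100], got {self.identity_threshold}"
            )
        if self.window < 1:
            raise HmolocusError(f"window must be >= 1, got {self.window}")
        if self.axes < 1:
            raise HmolocusError(f"axes must be >= 1, got {self.axes}")
        return self

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise HmolocusError(f"unknown config keys in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data).validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except HmolocusError as exc:
                raise HmolocusError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all artifacts under ``config.out``.

    Returns the report bundle (also written as ``report.json``).
    """
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    keyword_table = [tuple(p) for p in config.keyword_table]

    logger.info("reading inputs from %s", config.genomes)
    genes = _stage("read_genomes")(read_genomes)(config.genomes)
    references = _stage("read_references")(read_references)(config.references)
    sgb = _stage("read_sgb")(read_sgb_table)(config.sgb)
    logger.info("%d genes in %d genomes", len(genes), genes["genome_id"].nunique())

    hits = _stage("search")(search_homologs)(genes, references, config.identity_threshold)
    write_hits(hits, outdir / "hits.tsv")
    logger.info("%d family hits at threshold %.1f", len(hits), config.identity_threshold)

    loci = _stage("loci")(detect_loci)(hits, genes)
    write_loci(loci, outdir / "loci.json")
    categories = classify_cohort(hits, sgb["genome_id"])
    logger.info("%d loci detected", len(loci))

    landscapes = _stage("landscape")(extract_all_landscapes)(
        genes, loci, hits, config.window, keyword_table
    )
    write_landscapes(landscapes, outdir / "landscapes.tsv")

    sgb_of = dict(zip(sgb["genome_id"], sgb["sgb_id"]))
    representatives: dict = {}
    n_signature = 0
    if landscapes:
        distances = _stage("compare")(distance_matrix)(landscapes, config.include_other)
        write_distance_matrix(distances, outdir / "distances.tsv")
        k = min(config.axes, len(landscapes) - 1)
        if k >= 1:
            ordination = pcoa(distances, k)
            write_ordination(
                ordination, outdir / "ordination.tsv", outdir / "eigenvalues.tsv"
            )
        else:
            _write_empty_ordination(outdir)
        groups = {l.landscape_id: sgb_of[l.genome_id] for l in landscapes}
        representatives = representatives_by_group(landscapes, groups)
        n_signature = sum(signature_check(l.tokens) for l in landscapes)
    else:
        pd.DataFrame(columns=["landscape_id"]).to_csv(
            outdir / "distances.tsv", sep="\t", index=False
        )
        _write_empty_ordination(outdir)
    _write_representatives(representatives, outdir / "representatives.tsv")

    table = _stage("report")(prevalence)(hits, sgb, config.families)
    write_prevalence(table, outdir / "prevalence.tsv")
    summary = degrader_summary(categories, sgb)
    write_degrader_summary(summary, outdir / "degraders.tsv")

    ratios = {}
    for a, b in (("GH112", GH136_AGGREGATE), ("GH112", "GH10"), (GH136_AGGREGATE, "GH10")):
        try:
            ratios[f"{a}_vs_{b}"] = prevalence_ratio(table, a, b)
        except HmolocusError:
            ratios[f"{a}_vs_{b}"] = None

    report = {
        "n_genomes": int(len(sgb)),
        "n_sgbs": int(sgb["sgb_id"].nunique()),
        "n_hits": int(len(hits)),
        "n_loci": len(loci),
        "n_landscapes": len(landscapes),
        "n_landscapes_with_full_signature": int(n_signature),
        "category_counts": {
            c: int(sum(1 for v in categories.values() if v == c))
            for c in ("primary", "secondary", "none")
        },
        "prevalence_global": {
            f: int(table.count(f)) for f in config.families + [GH136_AGGREGATE]
        },
        "prevalence_ratios_global": ratios,
        "representatives": {
            sgb_id: " ".join(l.tokens) for sgb_id, l in sorted(representatives.items())
        },
    }
    write_json(report, outdir / "report.json")

    manifest = {
        "tool": "hmolocus",
        "version": __version__,
        "config": config.to_dict(),
        "input_digests": _input_digests(config),
        "outputs": sorted(
            p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    write_json(manifest, outdir / "manifest.json")
    return report


def _write_empty_ordination(outdir: Path) -> None:
    pd.DataFrame(columns=["landscape_id", "axis1"]).to_csv(
        outdir / "ordination.tsv", sep="\t", index=False
    )
    pd.DataFrame(columns=["rank", "eigenvalue"]).to_csv(
        outdir / "eigenvalues.tsv", sep="\t", index=False
    )


def _write_representatives(representatives: dict, path) -> None:
    rows = [
        {
            "sgb_id": sgb_id,
            "landscape_id": l.landscape_id,
            "tokens": " ".join(l.tokens),
        }
        for sgb_id, l in sorted(representatives.items())
    ]
    pd.DataFrame(rows, columns=["sgb_id", "landscape_id", "tokens"]).to_csv(
        path, sep="\t", index=False
    )


def _input_digests(config: PipelineConfig) -> dict:
    digests = {}
    for label, raw in (
        ("genomes", config.genomes),
        ("references", config.references),
        ("sgb", config.sgb),
    ):
        path = Path(raw)
        if path.is_file():
            digests[label] = file_digest(path)
        elif path.is_dir():
            digests[label] = {
                p.name: file_digest(p) for p in sorted(path.rglob("*")) if p.is_file()
            }
    return digests
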