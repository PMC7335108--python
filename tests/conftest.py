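import pandas as pd
import pytest
from hypothesis import settings

from hmolocus.homology import search_homologs
from hmolocus.synthetic import CohortDesign, default_references, simulate_cohort

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def references():
    return default_references()


@pytest.fixture(scope="session")
def small_cohort(references):
    """2 SGBs x 10 genomes: one GH136-type and one fucosidase-type SGB."""
    design = CohortDesign(n_sgbs=2, genomes_per_sgb=10, seed=42)
    genes, sgb, truth = simulate_cohort(design, references)
    return design, genes, sgb, truth


@pytest.fixture(scope="session")
def small_cohort_hits(small_cohort, references):
    _, genes, _, _ = small_cohort
    return search_homologs(genes, references, threshold=70.0)


def truth_hits(truth) -> pd.DataFrame:
    """Hit table reconstructed from ground truth (bypasses alignment)."""
    rows = [
        (g.genome_id, gene_id, info["family"], f"{info['family']}_L1-82", info["identity"])
        for g in truth.genomes.values()
        for gene_id, info in sorted(g.identities.items())
    ]
    return pd.DataFrame(
        rows, columns=["genome_id", "gene_id", "family", "ref_id", "pct_identity"]
    )
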