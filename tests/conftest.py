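import numpy as np
import pytest

from exonde.design import SampleDesign
from exonde.model import ExonDEModel
from exonde.quantify import build_expression_matrix
from exonde.regions import ExonRecord
from exonde.simdata import ScenarioConfig, plan_truth, region_meta, simulate_counts

SEED = 20250919 % (2**31)


@pytest.fixture(scope="session")
def planted_run():
    """A small planted-effect scenario fit end to end (shared across tests)."""
    config = ScenarioConfig.planted_scenario(n_genes=120)
    truth = plan_truth(config, seed=SEED)
    design = SampleDesign.balanced(4)
    counts, coverage = simulate_counts(truth, design, seed=SEED + 1)
    expr = build_expression_matrix(
        counts, coverage, region_meta(truth), design,
        library_size=design.library_size,
    )
    results = ExonDEModel(expr).fit()
    return {
        "config": config,
        "truth": truth,
        "design": design,
        "counts": counts,
        "coverage": coverage,
        "expr": expr,
        "results": results,
    }


def random_annotation(rng: np.random.Generator, max_genes=5, max_exons=10, max_coord=2000):
    """A random small exon annotation for oracle comparisons."""
    n_genes = rng.integers(1, max_genes + 1)
    exons = []
    for g in range(n_genes):
        gene = f"G{g + 1}"
        for k in range(rng.integers(1, max_exons + 1)):
            start = int(rng.integers(1, max_coord))
            length = int(rng.integers(1, 120))
            exons.append(
                ExonRecord(
                    exon_id=f"{gene}.e{k + 1}",
                    gene_id=gene,
                    chrom="chr1",
                    start=start,
                    end=min(start + length, max_coord),
                )
            )
    return exons
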