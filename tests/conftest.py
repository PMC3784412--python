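import numpy as np
import pandas as pd
import pytest

from chromnest import simulate as sim
from chromnest.expression import ExpressionMatrix
from chromnest.genome import Gene, GenomeAnnotation, GenomicInterval


def make_gene(gid, chrom, start, end, probed=True):
    return Gene(gid, gid.capitalize(), GenomicInterval(chrom, start, end), "+", probed)


def make_matrix(values: dict[str, list[float]], tissue_reps=None) -> ExpressionMatrix:
    """Build a matrix from gene -> profile; calls all Present.

    tissue_reps: list of (tissue, n_reps); defaults to one tissue covering all
    samples.
    """
    df = pd.DataFrame(values).T
    n = df.shape[1]
    if tissue_reps is None:
        tissue_reps = [("t1", n)]
    rows = []
    for tissue, reps in tissue_reps:
        for r in range(1, reps + 1):
            rows.append(
                {"sample_id": f"{tissue}.r{r}", "tissue": tissue,
                 "timepoint": "na", "replicate": r}
            )
    samples = pd.DataFrame(rows)
    assert len(samples) == n
    df.columns = samples["sample_id"]
    calls = pd.DataFrame("P", index=df.index, columns=df.columns)
    return ExpressionMatrix(values=df, calls=calls, samples=samples)


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted bundle shared across tests (800 genes, 2 chromosomes)."""
    return sim.simulate_bundle(seed=11, n_genes=800, n_chroms=2, n_plants=6)


@pytest.fixture
def toy_annotation():
    genes = [
        make_gene("a1", "chr1", 1_000, 5_000),
        make_gene("a2", "chr1", 10_000, 12_000),
        make_gene("a3", "chr1", 20_000, 30_000),
        make_gene("a4", "chr1", 40_000, 41_000),
        make_gene("b1", "chr2", 2_000, 3_000),
        make_gene("b2", "chr2", 8_000, 9_500),
    ]
    return GenomeAnnotation(genes, {"chr1": 100_000, "chr2": 50_000})
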