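import numpy as np
import pytest

from sctwas.epifeatures import GeneAnnotation
from sctwas.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_ds():
    """Two-cell-type dataset with one planted CT0-specific causal gene."""
    cfg = SimulationConfig(
        n_individuals=80, n_genes=60, n_cell_types=2, snps_per_gene=10,
        maf_range=(0.1, 0.5), ld_decay=0.3, n_causal_tracks=8,
        nonlinear_fraction=0.2, nb_dispersion=0.2, gwas_n=800,
        causal_genes=[("G0007", "CT0", 1.0)], seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_genes(small_ds):
    return [GeneAnnotation(r.gene_id, r.chromosome, int(r.tss), r.strand)
            for r in small_ds.truth.genes.itertuples(index=False)]


def make_variants(n, rng=None, prefix="rs", chrom="chr1", start=1000):
    """Variant metadata frame shaped like the simulator's output."""
    import pandas as pd

    pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    rows = [(f"{prefix}{i}", chrom, start + i * 100, *pairs[i % 4], 0.3, "G")
            for i in range(n)]
    return pd.DataFrame(rows, columns=["variant_id", "chromosome", "position",
                                       "ref", "alt", "maf", "gene_id"])
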