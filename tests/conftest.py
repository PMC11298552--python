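import numpy as np
import pandas as pd
import pytest

from methylvar import SimConfig, generate_dataset
from methylvar.methylation_quant import (assign_cpgs_to_features, filter_cpgs,
                                         weighted_gene_methylation)


SMALL_CONFIG = SimConfig(
    n_genes=150, cpgs_per_gene=(4, 10), n_intergenic_cpgs=100,
    n_dmg_coordinated=8, n_dmg_sparse=8, n_fc_only=5, n_nc_only=6,
    n_planted_deg=10, n_divergent_snp_genes=5, rna_reps=(6, 6, 6, 6),
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small paired WGBS + RNA-seq simulation shared across tests."""
    return generate_dataset(SMALL_CONFIG, seed=7)


@pytest.fixture(scope="session")
def small_quant(small_dataset):
    """Filtered matrix, mapping and gene methylation table for the fixture."""
    ds = small_dataset
    filt = filter_cpgs(ds.methylome, 10)
    genes = ds.genes.assign(feature_class="gene_body")
    mapping = assign_cpgs_to_features(filt, genes)
    gmt = weighted_gene_methylation(filt, mapping)
    return filt, mapping, gmt


def make_matrix(sites, meth, total, samples):
    """Convenience builder for hand-written CpG matrices."""
    from methylvar import CpGMatrix

    sites = pd.DataFrame(sites, columns=["contig", "pos", "strand"])
    return CpGMatrix(sites, np.asarray(meth), np.asarray(total), samples)
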