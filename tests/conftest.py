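import numpy as np
import pandas as pd
import pytest

from neurocycle.io_formats import DEFAULT_ZT_GRIDS, ExpressionMatrix, GeneModel, SampleMeta

LNV_ZTS = np.array([2.0, 6.0, 10.0, 14.0, 18.0, 22.0])
DN1_ZTS = np.array([3.0, 7.0, 11.0, 15.0, 19.0, 23.0])


def build_matrix(values_by_group: dict, gene_ids=None) -> ExpressionMatrix:
    """ExpressionMatrix from {group: (n_genes, 12) array}, samples ordered
    (replicate_set, zt) on the standard grids."""
    samples, cols = [], []
    n_genes = None
    for group, arr in values_by_group.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        n_genes = arr.shape[0] if n_genes is None else n_genes
        zts = DEFAULT_ZT_GRIDS.get(group, tuple(LNV_ZTS))
        k = 0
        for rep in (1, 2):
            for zt in zts:
                samples.append(SampleMeta(f"{group}_r{rep}_zt{zt:g}", group, rep, zt))
                cols.append(arr[:, k])
                k += 1
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    values = pd.DataFrame(
        np.column_stack(cols),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[s.sample_id for s in samples],
    )
    return ExpressionMatrix(values, samples)


@pytest.fixture
def lnv_zts12():
    """Sample ZTs of one group's 12 samples, replicate-set-major order."""
    return np.concatenate([LNV_ZTS, LNV_ZTS])


@pytest.fixture
def dn1_zts12():
    return np.concatenate([DN1_ZTS, DN1_ZTS])


@pytest.fixture
def plus_gene():
    """Single-exon + strand transcript chr2L:100-400."""
    return GeneModel("plus1", "chr2L", "+", (((100, 400),),))


@pytest.fixture
def minus_gene():
    return GeneModel("minus1", "chr2L", "-", (((100, 400),),))


@pytest.fixture
def spliced_gene():
    """Two-exon + strand gene; terminal 300-bp window spans the intron."""
    return GeneModel("spliced1", "chr3R", "+", (((1000, 1200), (1500, 1700)),))
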