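import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ductal_sc.datatypes import CountMatrix


def make_count_matrix(dense, sample_of=None, genes=None, barcodes=None):
    dense = np.asarray(dense)
    g, n = dense.shape
    genes = genes or [f"g{i}" for i in range(g)]
    barcodes = barcodes or [f"b{i}" for i in range(n)]
    if sample_of is None:
        sample_of = np.full(n, "s1", dtype=object)
    return CountMatrix(genes=genes, barcodes=barcodes,
                       X=sp.csr_matrix(dense), sample_of=np.asarray(sample_of, dtype=object))


def read_table(rows):
    """Build a read table from (barcode, gene, umi, reads) tuples."""
    return pd.DataFrame(rows, columns=["barcode", "gene", "umi", "reads"])


@pytest.fixture(scope="session")
def six_type_truth_and_counts():
    """Default six-type simulated sample shared by the slower tests."""
    from ductal_sc.synthetic import SimConfig, generate_droplets, generate_truth

    cfg = SimConfig(seed=5)
    truth = generate_truth(cfg)
    _, counts = generate_droplets(truth, cfg, with_reads=False)
    return cfg, truth, counts
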