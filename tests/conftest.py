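import logging

import numpy as np
import pandas as pd
import pytest

from crosscontrast.counts_io import compute_size_factors
from crosscontrast.simdata import SimConfig, generate_dataset

logging.disable(logging.WARNING)

#: compact version of the study design for unit tests
SMALL_GROUPS = {"HD_BA9": 12, "C_BA9": 16, "HD+_BA9": 3, "HD+_CAU": 2,
                "C_CAU": 2, "GTEx_BA9": 20, "GTEx_CAU": 24}


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared across tests (read-only)."""
    config = SimConfig(group_sizes=dict(SMALL_GROUPS), n_genes=300, seed=11)
    counts, meta, truth = generate_dataset(config)
    return {"config": config, "counts": counts, "meta": meta, "truth": truth,
            "size_factors": compute_size_factors(counts)}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_de_table(gene_ids, l2fc, se, n_total, pvalue=None):
    """Assemble a DE table from raw columns (test helper)."""
    l2fc = np.asarray(l2fc, float)
    se = np.asarray(se, float)
    if pvalue is None:
        from scipy import stats
        pvalue = 2 * stats.norm.sf(np.abs(l2fc / se))
    from crosscontrast.diffexp import bh_adjust
    with np.errstate(divide="ignore"):
        stat = np.where(se > 0, l2fc / np.where(se > 0, se, 1.0), np.inf)
    return pd.DataFrame({
        "baseMean": np.full(len(gene_ids), 100.0),
        "log2FoldChange": l2fc,
        "lfcSE": se,
        "stat": stat,
        "pvalue": pvalue,
        "padj": bh_adjust(pvalue),
        "n_total": n_total,
    }, index=pd.Index(gene_ids, name="gene_id"))
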