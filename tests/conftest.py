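import numpy as np
import pandas as pd
import pytest

import pdcrx


@pytest.fixture(scope="session")
def small_cfg() -> pdcrx.SimConfig:
    return pdcrx.SimConfig(
        n_cells=60, n_drugs=12, n_genes=30, n_classes=4, fingerprint_len=64, seed=123
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return pdcrx.generate_pdc_cohort(small_cfg)


@pytest.fixture()
def make_variants():
    """Factory for small variant tables: rows of (sample, chrom, pos, ref, alt[, gene])."""

    def _make(rows):
        cols = ["sample_id", "chrom", "pos", "ref", "alt", "gene"]
        rows = [tuple(r) + ("",) * (6 - len(r)) for r in rows]
        return pd.DataFrame(rows, columns=cols)

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
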