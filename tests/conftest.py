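import numpy as np
import pandas as pd
import pytest

from lofscreen import (
    GeneSet,
    build_lof_geneset,
    design_library,
    gen_gene_universe,
    gen_screen_counts,
)
from lofscreen.simulate import SimulationConfig


@pytest.fixture(scope="session")
def fullscale_universe():
    """1,555 genes, 4 flagged misannotated/non-coding, all others above the MAF cut."""
    cfg = SimulationConfig(seed=7, n_genes=1555, frac_set=1.0, frac_flagged=4 / 1555)
    table, bed = gen_gene_universe(cfg)
    return table, bed


@pytest.fixture(scope="session")
def fullscale_set(fullscale_universe):
    table, _ = fullscale_universe
    return build_lof_geneset(table)


@pytest.fixture(scope="session")
def fullscale_manifest(fullscale_set):
    return design_library(fullscale_set, seed=7)


@pytest.fixture(scope="session")
def small_universe():
    cfg = SimulationConfig(seed=2, n_genes=400, n_traits=30)
    table, bed = gen_gene_universe(cfg)
    return cfg, table, bed


@pytest.fixture()
def tiny_gene_table():
    """Ten genes with MAF = 0.0001 * k for k = 1..10."""
    k = np.arange(1, 11)
    return pd.DataFrame(
        {
            "symbol": [f"g{i}" for i in k],
            "chrom": "chr1",
            "start": (k - 1) * 1000,
            "end": (k - 1) * 1000 + 500,
            "strand": "+",
            "plof_maf": 0.0001 * k,
            "coding": True,
            "misannotated": False,
        }
    )


@pytest.fixture()
def small_screen():
    """A 20-gene two-set screen with three spiked essential genes."""
    genes = GeneSet("tiny", [f"G{i:03d}" for i in range(1, 21)])
    manifest = design_library(genes, n_ntc=10, n_safeharbor=5, seed=5)
    cfg = SimulationConfig(seed=6, n_essential=3, baseline_mean=300.0)
    counts, sheet, truth = gen_screen_counts(manifest, cfg)
    return manifest, cfg, counts, sheet, truth
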