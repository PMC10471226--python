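import logging

import numpy as np
import pandas as pd
import pytest

from homeovar.simulate import SimConfig, simulate_study

logging.getLogger("homeovar").setLevel(logging.ERROR)


@pytest.fixture
def pair_frame() -> pd.DataFrame:
    """A 3-chromosome, 12-pair homoeolog map with chrom_pair attached."""
    rows = []
    k = 0
    for c in range(3):
        for o in range(4):
            rows.append(
                (f"p{k:03d}", f"BoC{c+1}g{o}", f"BrA{c+1}g{o}",
                 f"C{c+1}", f"A{c+1}", o)
            )
            k += 1
    df = pd.DataFrame(
        rows,
        columns=["pair_id", "gene_C", "gene_A", "chrom_C", "chrom_A",
                 "order_index"],
    )
    df["chrom_pair"] = df["chrom_C"] + "/" + df["chrom_A"]
    return df


@pytest.fixture(scope="session")
def small_study():
    """A compact but realistically proportioned simulated study.

    Eight lines at generations 1 and 10 (16 samples), six chromosome
    pairs of 2,000 genes, with enough GO terms for the class comparisons
    to be well populated.
    """
    cfg = SimConfig(
        n_chromosome_pairs=6, pairs_per_chromosome=2000, n_lines=8,
        generations=(1, 10), n_go_per_class=60, genes_per_go=40,
        he_rate_per_generation=3.0, seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
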