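import numpy as np
import pandas as pd
import pytest

from mutrate import synthetic
from mutrate.tabulate import build_count_table


@pytest.fixture(scope="session")
def tiny_ds():
    """Small but fully featured synthetic dataset shared across tests."""
    cfg = synthetic.SyntheticConfig(genome_length=20_000, n_cancer_types=2,
                                    samples_per_cancer_type=3, seed=42)
    return synthetic.synthesize(cfg)


@pytest.fixture(scope="session")
def tiny_annotated(tiny_ds):
    return tiny_ds.annotated_mutations()


@pytest.fixture(scope="session")
def tiny_table(tiny_ds, tiny_annotated):
    return build_count_table(tiny_ds.sites, tiny_annotated, tiny_ds.samples,
                             covariates=["conservation"])


def make_single_row_table(strand, counts, sample="s1", cancer="c1"):
    """One-combination count table for closed-form checks.

    ``counts`` are (alt1, alt2, alt3, no-mutation) in the block's outcome
    order, e.g. (C>A, C>G, C>T, C>C) for strand "C".
    """
    from mutrate.tabulate import CountTable
    alt_bases = {"C": ["A", "G", "T"], "T": ["A", "C", "G"]}[strand]
    row = {"strand_class": strand, "sample": sample, "cancer_type": cancer}
    for b, c in zip(alt_bases, counts[:3]):
        row[f"n_{b}"] = float(c)
    row[f"n_{strand}"] = float(counts[3])
    df = pd.DataFrame([row])[["strand_class", "sample", "cancer_type",
                              "n_A", "n_C", "n_G", "n_T"]]
    return CountTable(df, ["strand_class"])
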