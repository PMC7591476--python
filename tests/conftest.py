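import numpy as np
import pandas as pd
import pytest

from cancerfeat import SynthConfig, generate_dataset, run_pipeline


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(n_genes=400, n_chromosomes=4, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def pipeline_result():
    """One medium pipeline run shared by integration-level tests."""
    return run_pipeline(SynthConfig(n_genes=1500, seed=5), compare_weights=True)


@pytest.fixture
def tiny_genes():
    """Three hand-placed genes on two chromosomes."""
    df = pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC"],
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [1_000, 10_000, 5_000],
            "end": [2_000, 15_000, 6_000],
            "strand": ["+", "-", "+"],
        }
    )
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    df["terminator"] = np.where(df["strand"] == "+", df["end"], df["start"])
    return df
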