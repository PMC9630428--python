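import numpy as np
import pandas as pd
import pytest

from transmeta import simulate, sumstats


@pytest.fixture()
def toy_table():
    """Three well-formed markers for one trait."""
    return pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3"],
            "CHR": ["1", "1", "2"],
            "BP": [1000, 2000, 3000],
            "A1": ["A", "C", "T"],
            "A2": ["G", "T", "G"],
            "BETA": [0.10, -0.05, 0.02],
            "SE": [0.02, 0.03, 0.04],
            "P": [5.733e-7, 0.09558, 0.6171],
            "EAF": [0.30, 0.60, 0.10],
            "N": [10000, 10000, 10000],
        }
    )


@pytest.fixture(scope="session")
def sim_pair():
    """One default paired-sumstats draw with planted loci of every type."""
    cfg = simulate.default_config(seed=20221)
    t1, t2, truth = simulate.simulate_pair_sumstats(cfg)
    return t1, t2, truth


@pytest.fixture(scope="session")
def harmonized_pair(sim_pair):
    t1, t2, truth = sim_pair
    pairs, drops = sumstats.harmonize(t1, t2)
    return pairs, truth


def write_table(df: pd.DataFrame, path) -> str:
    df.to_csv(path, sep="\t", index=False)
    return str(path)
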